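"""Random-forest classifier over DWT feature vectors.

A thin, deterministic wrapper around scikit-learn's
``RandomForestClassifier`` with its default hyperparameters (100 trees,
Gini impurity, sqrt(d) features per split, bootstrap resampling, trees
grown to purity), which is the configuration the warning system uses.

The probability contract needed downstream for one-vs-rest ROC analysis is
soft voting: ``predict_proba`` averages per-tree leaf class-frequency
vectors, and ``predict`` takes the argmax with ties broken toward the
lowest class code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .errors import ConfigError, ValidationError
from .dwt_features import FeatureVector
from .signal_model import StateLabel

__all__ = ["ForestConfig", "TrainedForest", "train_forest", "predict_proba", "predict"]


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters; defaults mirror scikit-learn's."""

    n_trees: int = 100
    max_features: str = "sqrt"
    split_criterion: str = "gini"
    bootstrap: bool = True
    min_samples_split: int = 2
    max_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ConfigError("n_trees must be >= 1")
        if self.split_criterion != "gini":
            raise ConfigError("only the 'gini' split criterion is supported")
        if self.max_features != "sqrt":
            raise ConfigError("only max_features='sqrt' is supported")


@dataclass
class TrainedForest:
    """A fitted ensemble plus the config and class ordering it was fit with."""

    estimator: RandomForestClassifier
    classes: List[StateLabel]
    config: ForestConfig
    n_features: int


def _as_matrix(features) -> np.ndarray:
    if len(features) and isinstance(features[0], FeatureVector):
        features = [f.values for f in features]
    X = np.asarray(features, dtype=np.float64)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    return X


def train_forest(
    features: Sequence,
    labels: Sequence | None = None,
    cfg: ForestConfig | None = None,
) -> TrainedForest:
    """Fit a seeded random forest.

    ``features`` may be a list of :class:`FeatureVector` (labels taken from
    them) or a 2-D array with an explicit ``labels`` sequence.  Deterministic
    given ``(data, cfg.seed)``.
    """
    cfg = cfg or ForestConfig()
    if labels is None:
        if not (len(features) and isinstance(features[0], FeatureVector)):
            raise ValidationError("labels required unless FeatureVectors are given")
        labels = [f.label for f in features]
    X = _as_matrix(features)
    y = np.asarray([int(StateLabel.from_any(l)) for l in labels])
    if len(X) == 0:
        raise ValidationError("empty training set")
    if len(X) != len(y):
        raise ValidationError("features and labels differ in length")
    estimator = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        criterion=cfg.split_criterion,
        max_features=cfg.max_features,
        bootstrap=cfg.bootstrap,
        min_samples_split=cfg.min_samples_split,
        max_depth=cfg.max_depth,
        random_state=cfg.seed,
        n_jobs=1,
    )
    estimator.fit(X, y)
    return TrainedForest(
        estimator=estimator,
        classes=[StateLabel(int(c)) for c in estimator.classes_],
        config=cfg,
        n_features=X.shape[1],
    )


def predict_proba(model: TrainedForest, features) -> np.ndarray:
    """Per-class probability rows (soft vote over trees), summing to 1.

    Columns follow ``model.classes`` (ascending class code).
    """
    X = _as_matrix(features)
    if X.shape[1] != model.n_features:
        raise ValidationError(
            f"feature dimension {X.shape[1]} does not match the trained "
            f"dimension {model.n_features}"
        )
    return model.estimator.predict_proba(X)


def predict(model: TrainedForest, features) -> np.ndarray:
    """Hard labels: argmax of :func:`predict_proba`, ties to lowest code."""
    proba = predict_proba(model, features)
    codes = np.asarray([int(c) for c in model.classes])
    return codes[np.argmax(proba, axis=1)]
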