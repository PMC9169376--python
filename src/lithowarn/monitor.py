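"""Streaming front end: sliding-window classification of an incoming trace.

Windows of the model's training timestep (default 50 samples = 500 ms) are
classified in arrival order as soon as they complete — no lookahead — so an
event stream over a live procedure would deliver a state decision every
``hop`` samples.  Each event carries the wall-clock compute time of its own
feature extraction + inference, reported for transparency but never
asserted against a target (it is hardware-dependent).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from typing import List

import numpy as np

from .dwt_features import dwt_single_level, load_wavelet
from .errors import ValidationError
from .forest_classifier import TrainedForest, predict_proba
from .signal_model import Recording, StateLabel

__all__ = ["StateEvent", "classify_stream", "write_events_jsonl"]


@dataclass
class StateEvent:
    """One sliding-window decision."""

    window_end_time_s: float
    predicted: StateLabel
    probabilities: np.ndarray  # indexed by class code, sums to 1
    decision_latency_ms: float

    def to_dict(self) -> dict:
        return {
            "window_end_time_s": float(self.window_end_time_s),
            "predicted": int(self.predicted),
            "state": self.predicted.display_name,
            "probabilities": [float(p) for p in self.probabilities],
            "decision_latency_ms": float(self.decision_latency_ms),
        }


def classify_stream(
    model: TrainedForest,
    wavelet: str,
    rec: Recording,
    window: int = 50,
    hop: int = 50,
    padding: str = "symmetric",
) -> List[StateEvent]:
    """Classify every complete window of ``rec`` at stride ``hop``.

    Event predictions are identical to batch predictions of the same
    windows (streaming/offline equivalence); a recording shorter than one
    window yields an empty list.
    """
    if not 1 <= hop <= window:
        raise ValidationError(f"hop must satisfy 1 <= hop <= window, got {hop}")
    w = load_wavelet(wavelet)
    probe = dwt_single_level(np.zeros(window), w, padding)
    dim = len(probe.approx) + len(probe.detail)
    if dim != model.n_features:
        raise ValidationError(
            f"wavelet {wavelet!r} with window {window} gives {dim} features "
            f"but the model was trained on {model.n_features}"
        )
    events: List[StateEvent] = []
    for end in range(window, len(rec) + 1, hop):
        t0 = time.perf_counter()
        c = dwt_single_level(rec.samples[end - window : end], w, padding)
        features = np.concatenate([c.approx, c.detail])
        proba_row = predict_proba(model, features.reshape(1, -1))[0]
        full = np.zeros(len(StateLabel))
        for col, cls in enumerate(model.classes):
            full[int(cls)] = proba_row[col]
        predicted = StateLabel(int(np.argmax(full)))
        latency_ms = (time.perf_counter() - t0) * 1000.0
        events.append(
            StateEvent(
                window_end_time_s=end / rec.sampling_rate_hz,
                predicted=predicted,
                probabilities=full,
                decision_latency_ms=latency_ms,
            )
        )
    return events


def write_events_jsonl(events: List[StateEvent], path) -> None:
    """One JSON object per line, one line per event."""
    with open(path, "w", encoding="utf-8") as fh:
        for event in events:
            fh.write(json.dumps(event.to_dict()) + "\n")
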