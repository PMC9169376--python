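"""Core data types for labeled shockwave acceleration traces.

A :class:`Recording` is a single-channel acceleration-magnitude time series
sampled (by default) at 100 Hz, carrying one state label per sample.  The
three states describe the laser-irradiance condition during retrograde
intrarenal surgery: ``Idle`` (laser off), ``Stone`` (laser fragmenting a
stone) and ``Tissue`` (laser striking soft tissue — the hazard an early
warning system must flag).  A :class:`Segment` is a fixed-length window cut
from a recording, the unit on which features are computed and predictions
made.

Recordings round-trip through CSV (canonical) and XLSX (the format the
original logging software emitted); columns are ``t_ms``, ``magnitude``,
``label``, matched case-insensitively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "StateLabel",
    "Recording",
    "Segment",
    "read_recording",
    "write_recording",
]

DEFAULT_SAMPLING_RATE_HZ = 100.0

#: Canonical column names; matching on read is case-insensitive.
MAGNITUDE_COLUMN = "magnitude"
LABEL_COLUMN = "label"
TIME_COLUMN = "t_ms"


class StateLabel(IntEnum):
    """Laser-irradiance state; integer codes 0/1/2 are fixed by convention."""

    IDLE = 0
    STONE = 1
    TISSUE = 2

    @property
    def display_name(self) -> str:
        return self.name.capitalize()

    @classmethod
    def from_any(cls, value) -> "StateLabel":
        """Coerce an int code or a (case-insensitive) state name."""
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            try:
                return cls[value.upper()]
            except KeyError:
                raise ValidationError(
                    f"unknown state name {value!r}; expected one of "
                    f"{[s.display_name for s in cls]}"
                ) from None
        code = int(value)
        try:
            return cls(code)
        except ValueError:
            raise ValidationError(
                f"label code {code} outside {{0, 1, 2}}"
            ) from None


def _validate_labels(labels: np.ndarray) -> None:
    bad = ~np.isin(labels, (0, 1, 2))
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"label code {labels[idx]} at row {idx} outside {{0, 1, 2}}"
        )


@dataclass
class Recording:
    """A labeled acceleration-magnitude trace.

    Parameters
    ----------
    samples
        Acceleration magnitudes in arbitrary device units.
    labels
        Per-sample state codes in {0, 1, 2}; same length as ``samples``.
    sampling_rate_hz
        Sampling rate; 100 Hz for the target acquisition hardware.
    meta
        Free-form provenance (source file, simulator seed/config, ...).
    """

    samples: np.ndarray
    labels: np.ndarray
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.samples.ndim != 1 or self.labels.ndim != 1:
            raise ValidationError("samples and labels must be 1-D")
        if len(self.samples) != len(self.labels):
            raise ValidationError(
                f"samples ({len(self.samples)}) and labels "
                f"({len(self.labels)}) differ in length"
            )
        if not self.sampling_rate_hz > 0:
            raise ValidationError("sampling_rate_hz must be positive")
        _validate_labels(self.labels)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return len(self) / self.sampling_rate_hz


@dataclass
class Segment:
    """A fixed-length, single-label window extracted from a recording."""

    values: np.ndarray
    label: StateLabel
    origin: tuple = ("", 0)  # (recording id, start sample index)
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ValidationError("segment values must be a nonempty 1-D array")
        self.label = StateLabel.from_any(self.label)

    def __len__(self) -> int:
        return len(self.values)


def _resolve_dialect(path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "xlsx" if str(path).lower().endswith((".xlsx", ".xls")) else "csv"
    dialect = dialect.lower()
    if dialect not in ("csv", "xlsx"):
        raise ValidationError(f"unknown dialect {dialect!r}; use 'csv' or 'xlsx'")
    return dialect


def read_recording(
    path,
    dialect: str | None = None,
    sampling_rate_hz: float | None = None,
) -> Recording:
    """Read a labeled recording from CSV or XLSX.

    The file must contain a ``magnitude`` and an integer ``label`` column
    (case-insensitive); an optional ``t_ms`` column carries timestamps in
    milliseconds.  If ``sampling_rate_hz`` is not given it is inferred from
    the ``t_ms`` spacing where present, else defaults to 100 Hz.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    dialect = _resolve_dialect(path, dialect)
    try:
        if dialect == "xlsx":
            df = pd.read_excel(path, sheet_name=0, engine="openpyxl")
        else:
            df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise FormatError(f"could not parse {path}: {exc}") from exc

    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in (MAGNITUDE_COLUMN, LABEL_COLUMN):
        if col not in df.columns:
            raise FormatError(
                f"{path}: missing required column {col!r} "
                f"(found {list(df.columns)})"
            )

    try:
        samples = df[MAGNITUDE_COLUMN].to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise FormatError(
            f"{path}: column '{MAGNITUDE_COLUMN}' is not numeric"
        ) from exc
    raw_labels = df[LABEL_COLUMN].to_numpy()
    try:
        labels = raw_labels.astype(np.int64)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: column '{LABEL_COLUMN}' is not integer") from exc
    if not np.array_equal(labels, raw_labels.astype(np.float64)):
        raise FormatError(f"{path}: column '{LABEL_COLUMN}' has non-integer values")
    _validate_labels(labels)

    fs = sampling_rate_hz
    if fs is None and TIME_COLUMN in df.columns and len(df) > 1:
        dt_ms = np.median(np.diff(df[TIME_COLUMN].to_numpy(dtype=np.float64)))
        if dt_ms > 0:
            fs = 1000.0 / dt_ms
    if fs is None:
        fs = DEFAULT_SAMPLING_RATE_HZ

    return Recording(
        samples=samples,
        labels=labels,
        sampling_rate_hz=float(fs),
        meta={"source": str(path), "dialect": dialect},
    )


def write_recording(rec: Recording, path, dialect: str | None = None) -> None:
    """Write a recording as CSV or XLSX with columns ``t_ms,magnitude,label``.

    The written file reads back (via :func:`read_recording`) to an equal
    recording: labels exactly, magnitudes within floating-point round-trip
    tolerance.
    """
    path = Path(path)
    dialect = _resolve_dialect(path, dialect)
    t_ms = np.arange(len(rec)) * (1000.0 / rec.sampling_rate_hz)
    df = pd.DataFrame(
        {
            TIME_COLUMN: t_ms,
            MAGNITUDE_COLUMN: rec.samples,
            LABEL_COLUMN: rec.labels,
        }
    )
    try:
        if dialect == "xlsx":
            df.to_excel(path, index=False, engine="openpyxl")
        else:
            df.to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"could not write {path}: {exc}") from exc
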