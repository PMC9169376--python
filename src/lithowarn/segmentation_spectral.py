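"""Windowing and FFT-based separability analysis.

Recordings are cut into non-overlapping ("tumbling") windows of a fixed
timestep — 50 samples = 500 ms at 100 Hz, the operating point of the warning
system.  Windows straddling a label change are discarded (`pure_label`
policy) so that class statistics and training labels are uncontaminated.

The one-sided FFT magnitude of each window, averaged within each state,
exposes the physical separability the classifier exploits: stone-hit
shockwaves carry the largest broadband magnitude, tissue hits an
intermediate low-frequency signature, the idle state only the noise floor.
Stored magnitudes are linear; plot them on a log axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .errors import ValidationError
from .signal_model import Recording, Segment, StateLabel

__all__ = [
    "DEFAULT_TIMESTEP",
    "Spectrum",
    "segment_recording",
    "fft_magnitude",
    "class_average_spectrum",
]

DEFAULT_TIMESTEP = 50  # samples: 500 ms at 100 Hz


@dataclass
class Spectrum:
    """One-sided magnitude spectrum: ``floor(T/2)+1`` bins from 0 to fs/2."""

    freqs_hz: np.ndarray
    magnitude: np.ndarray

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=np.float64)
        self.magnitude = np.asarray(self.magnitude, dtype=np.float64)
        if self.freqs_hz.shape != self.magnitude.shape:
            raise ValidationError("freqs_hz and magnitude must have equal shape")
        if (self.magnitude < 0).any():
            raise ValidationError("magnitudes must be nonnegative")


def segment_recording(
    rec: Recording,
    timestep: int = DEFAULT_TIMESTEP,
    policy: str = "pure_label",
    recording_id: str | None = None,
) -> List[Segment]:
    """Cut a recording into consecutive pure-label windows.

    Windows of exactly ``timestep`` samples start at index 0 with no
    overlap; a trailing remainder shorter than ``timestep`` is dropped, and
    under the (only) ``pure_label`` policy any window containing more than
    one label value is dropped as well.
    """
    if timestep < 2:
        raise ValidationError(f"timestep must be >= 2, got {timestep}")
    if policy != "pure_label":
        raise ValidationError(f"unknown segmentation policy {policy!r}")
    rec_id = recording_id if recording_id is not None else rec.meta.get("source", "")
    segments: List[Segment] = []
    for start in range(0, len(rec) - timestep + 1, timestep):
        window_labels = rec.labels[start : start + timestep]
        if (window_labels != window_labels[0]).any():
            continue
        segments.append(
            Segment(
                values=rec.samples[start : start + timestep].copy(),
                label=StateLabel(int(window_labels[0])),
                origin=(rec_id, start),
                sampling_rate_hz=rec.sampling_rate_hz,
            )
        )
    return segments


def fft_magnitude(seg: Segment) -> Spectrum:
    """One-sided DFT magnitude of a window (no detrend, no taper).

    Unscaled numpy convention: the full two-sided power ``sum |X_k|^2``
    equals ``T * sum x_n^2`` (Parseval).  For T=50 at 100 Hz this yields 26
    bins at 0, 2, ..., 50 Hz.
    """
    magnitude = np.abs(np.fft.rfft(seg.values))
    freqs = np.fft.rfftfreq(len(seg), d=1.0 / seg.sampling_rate_hz)
    return Spectrum(freqs_hz=freqs, magnitude=magnitude)


def class_average_spectrum(
    segments: Sequence[Segment],
) -> Dict[StateLabel, Spectrum]:
    """Bin-wise arithmetic mean of window magnitudes within each state.

    States with no segments are absent from the returned map; mixed segment
    lengths or sampling rates are rejected.
    """
    if not segments:
        return {}
    length = len(segments[0])
    fs = segments[0].sampling_rate_hz
    for seg in segments:
        if len(seg) != length or seg.sampling_rate_hz != fs:
            raise ValidationError(
                "segments must share one length and sampling rate"
            )
    out: Dict[StateLabel, Spectrum] = {}
    freqs = np.fft.rfftfreq(length, d=1.0 / fs)
    for state in StateLabel:
        mags = [
            np.abs(np.fft.rfft(seg.values)) for seg in segments if seg.label == state
        ]
        if mags:
            out[state] = Spectrum(freqs_hz=freqs, magnitude=np.mean(mags, axis=0))
    return out
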