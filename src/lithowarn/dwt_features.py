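"""Single-level discrete wavelet transform feature extraction.

The DWT passes a window through a two-channel analysis filter bank —
low-pass ``dec_lo`` giving *approximation* coefficients cA, high-pass
``dec_hi`` giving *detail* coefficients cD — followed by dyadic
downsampling.  The coefficients are inner products of the signal with
dilated/translated copies of the mother wavelet, capturing frequency
content while retaining time localization, which suits the non-stationary
shockwave transients better than a plain Fourier magnitude.

Supported families: ``haar``, ``db2``, ``db4`` (orthogonal Daubechies),
``rbio2.4`` (reverse biorthogonal) and ``dmey`` (the 62-tap FIR
approximation of the Meyer wavelet).  Filter taps are embedded as the
standard published double-precision values, so no wavelet library is needed
at runtime.

Two boundary treatments are offered:

``none``
    Periodized (circular) convolution.  No extension samples are invented;
    the window is treated as one period, yielding exactly ``len(x)/2``
    coefficients per channel — the "half the original data length" regime —
    and conserving energy for orthogonal families.  Requires an even window
    at least as long as the filter (which excludes dmey at 50 samples).
``symmetric`` (default)
    Half-sample symmetric extension by L-1 samples each side (reflection is
    repeated when the filter is longer than the window), then linear
    convolution; ``floor((len(x)+L-1)/2)`` coefficients per channel.  Legal
    for every family at any window length, hence the default applied
    uniformly when sweeping families.

The per-window feature vector fed to the classifier is the concatenation
cA ∥ cD.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import List, Sequence

import numpy as np

from ._wavelet_filters import FILTER_BANKS
from .errors import ValidationError
from .signal_model import Segment, StateLabel

__all__ = [
    "SUPPORTED_WAVELETS",
    "WaveletSpec",
    "DWTCoefficients",
    "FeatureVector",
    "load_wavelet",
    "dwt_single_level",
    "idwt_single_level",
    "feature_length",
    "build_feature_table",
]

SUPPORTED_WAVELETS = ("haar", "db2", "db4", "rbio2.4", "dmey")


@dataclass(frozen=True)
class WaveletSpec:
    """A named wavelet with its decomposition/reconstruction filter banks."""

    name: str
    dec_lo: tuple
    dec_hi: tuple
    rec_lo: tuple
    rec_hi: tuple
    orthogonal: bool

    @property
    def filter_length(self) -> int:
        return len(self.dec_lo)


def load_wavelet(name: str) -> WaveletSpec:
    """Return the standard filter bank for a supported wavelet family."""
    key = str(name).lower()
    if key not in FILTER_BANKS:
        raise ValidationError(
            f"unknown wavelet {name!r}; supported: {', '.join(SUPPORTED_WAVELETS)}"
        )
    bank = FILTER_BANKS[key]
    return WaveletSpec(
        name=key,
        dec_lo=tuple(bank["dec_lo"]),
        dec_hi=tuple(bank["dec_hi"]),
        rec_lo=tuple(bank["rec_lo"]),
        rec_hi=tuple(bank["rec_hi"]),
        orthogonal=bank["orthogonal"],
    )


@dataclass
class DWTCoefficients:
    """Output of one analysis step: approximation cA and detail cD."""

    approx: np.ndarray
    detail: np.ndarray
    wavelet: str
    padding: str
    original_length: int

    def __post_init__(self) -> None:
        self.approx = np.asarray(self.approx, dtype=np.float64)
        self.detail = np.asarray(self.detail, dtype=np.float64)
        if len(self.approx) == 0 or len(self.detail) == 0:
            raise ValidationError("coefficient arrays must be nonempty")
        if len(self.approx) != len(self.detail):
            raise ValidationError("approx and detail must have equal length")


@dataclass
class FeatureVector:
    """cA ∥ cD concatenation of one segment, with its label and origin."""

    values: np.ndarray
    label: StateLabel
    origin: tuple = ("", 0)


def _symmetric_extend(x: np.ndarray, n: int) -> np.ndarray:
    """Half-sample symmetric extension by ``n`` samples on each side."""
    if n == 0:
        return x
    reps = n // (2 * len(x)) + 1
    left = np.tile(np.concatenate([x, x[::-1]]), reps)[-n:]
    right = np.tile(np.concatenate([x[::-1], x]), reps)[:n]
    return np.concatenate([left, x, right])


def _periodic_extend(x: np.ndarray, n: int) -> np.ndarray:
    if n == 0:
        return x
    reps = n // len(x) + 1
    return np.concatenate([np.tile(x, reps)[-n:], x, np.tile(x, reps)[:n]])


def dwt_single_level(
    x: Sequence[float],
    w: WaveletSpec | str,
    padding: str = "symmetric",
) -> DWTCoefficients:
    """Single-level analysis: convolve with dec_lo/dec_hi, keep every other
    output.

    ``padding="none"`` uses periodized convolution (even length >= filter
    length required) and returns exactly ``len(x)/2`` coefficients per
    channel; ``padding="symmetric"`` returns ``floor((len(x)+L-1)/2)``.
    """
    if isinstance(w, str):
        w = load_wavelet(w)
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or len(x) < 2:
        raise ValidationError("input must be a 1-D sequence of length >= 2")
    L = w.filter_length
    lo = np.asarray(w.dec_lo)
    hi = np.asarray(w.dec_hi)

    if padding == "none":
        if len(x) < L:
            raise ValidationError(
                f"padding='none' requires len(x) >= filter length ({L}) but "
                f"len(x) = {len(x)}; use padding='symmetric' "
                f"(the {w.name} filter is longer than the window)"
            )
        if len(x) % 2:
            raise ValidationError("padding='none' requires an even input length")
        n = len(x)
        ext = _periodic_extend(x, L - 1)
        # circular convolution: circ[p] = sum_k h[k] x[(p-k) mod n]
        circ_lo = np.convolve(ext, lo)[L - 1 : L - 1 + n]
        circ_hi = np.convolve(ext, hi)[L - 1 : L - 1 + n]
        # downsampling phase L//2 matches the standard periodized transform
        idx = (L // 2 + 2 * np.arange(n // 2)) % n
        approx = circ_lo[idx]
        detail = circ_hi[idx]
    elif padding == "symmetric":
        ext = _symmetric_extend(x, L - 1)
        n_out = (len(x) + L - 1) // 2
        approx = np.convolve(ext, lo)[L : L + 2 * n_out : 2]
        detail = np.convolve(ext, hi)[L : L + 2 * n_out : 2]
    else:
        raise ValidationError(f"unknown padding {padding!r}; use 'none' or 'symmetric'")

    return DWTCoefficients(
        approx=approx,
        detail=detail,
        wavelet=w.name,
        padding=padding,
        original_length=len(x),
    )


@lru_cache(maxsize=64)
def _analysis_matrix(name: str, n: int, padding: str) -> np.ndarray:
    """The (2*n_coeff, n) linear operator of dwt_single_level."""
    w = load_wavelet(name)
    cols = []
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        c = dwt_single_level(e, w, padding)
        cols.append(np.concatenate([c.approx, c.detail]))
    return np.column_stack(cols)


def idwt_single_level(
    c: DWTCoefficients,
    w: WaveletSpec | str,
) -> np.ndarray:
    """Reconstruct the original window from its coefficients (test-time
    inverse).

    The analysis step is a linear map of the window; reconstruction solves
    that linear system (least squares), which is exact to machine precision
    for every supported family — including dmey, whose standard taps are
    only approximately orthogonal so the classical synthesis bank would
    leave a residual.
    """
    if isinstance(w, str):
        w = load_wavelet(w)
    if w.name != c.wavelet:
        raise ValidationError(
            f"coefficients were produced with {c.wavelet!r}, not {w.name!r}"
        )
    matrix = _analysis_matrix(w.name, c.original_length, c.padding)
    rhs = np.concatenate([c.approx, c.detail])
    if matrix.shape[0] != len(rhs):
        raise ValidationError("coefficient length inconsistent with original_length")
    solution, *_ = np.linalg.lstsq(matrix, rhs, rcond=None)
    return solution


def feature_length(timestep: int, w: WaveletSpec | str, padding: str = "symmetric") -> int:
    """Dimension of the cA ∥ cD feature vector for a given window length."""
    if isinstance(w, str):
        w = load_wavelet(w)
    if padding == "none":
        return timestep
    return 2 * ((timestep + w.filter_length - 1) // 2)


def build_feature_table(
    segments: Sequence[Segment],
    w_name: str = "dmey",
    padding: str = "symmetric",
) -> List[FeatureVector]:
    """One cA ∥ cD feature vector per segment, order preserved."""
    if not segments:
        return []
    w = load_wavelet(w_name)
    length = len(segments[0])
    table: List[FeatureVector] = []
    for seg in segments:
        if len(seg) != length:
            raise ValidationError("segments must share one length")
        c = dwt_single_level(seg.values, w, padding)
        table.append(
            FeatureVector(
                values=np.concatenate([c.approx, c.detail]),
                label=seg.label,
                origin=seg.origin,
            )
        )
    return table
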