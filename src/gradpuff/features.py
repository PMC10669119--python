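"""Time- and frequency-domain characterization of recordings and puffs.

Time domain: RMS of the global trace and of each puff; the mean puff
(pointwise average after resampling to a common grid); and a normalized mean
square error between each puff and the mean curve,

    MSE = (1/(N * r^2)) * sum_i (yhat_i - y_i)^2,   r = max(y) - min(y),

which is dimensionless and invariant to a common rescaling of puff and mean
curve. Frequency domain: Welch-WOSA power spectral density and its band
moments — mean frequency (first PSD moment), maximum-amplitude frequency
(argmax), and spectral standard deviation (square root of the second central
moment).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .errors import DegenerateInputError, ParameterError
from .preprocess import PuffSet

__all__ = [
    "MeanPuff",
    "SpectralSummary",
    "rms",
    "mean_puff",
    "puff_mse",
    "welch_psd",
    "spectral_params",
]


@dataclass
class MeanPuff:
    """Average puff curve on a common grid of L samples."""

    curve: np.ndarray
    n_source: int

    def __post_init__(self) -> None:
        self.curve = np.asarray(self.curve, dtype=float)
        if self.curve.size < 2:
            raise ParameterError("mean-puff grid needs at least 2 samples")
        if self.n_source < 1:
            raise ParameterError("mean puff needs at least one source puff")

    @property
    def L(self) -> int:
        return self.curve.size


@dataclass
class SpectralSummary:
    """One-sided PSD plus its band moments (filled by spectral_params)."""

    freqs: np.ndarray
    psd: np.ndarray
    fs: float
    f_mean: float | None = None
    f_max: float | None = None
    spec_sd: float | None = None


def rms(x) -> float:
    """Root mean square, sqrt(mean(x^2))."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise DegenerateInputError("RMS of an empty array is undefined")
    return float(np.sqrt(np.mean(x * x)))


def _resample(seg: np.ndarray, L: int, method: str) -> np.ndarray:
    seg = np.asarray(seg, dtype=float)
    if seg.size == L:
        return seg.copy()
    if method == "fourier":
        return sps.resample(seg, L)
    if method == "linear":
        old = np.linspace(0.0, 1.0, seg.size)
        new = np.linspace(0.0, 1.0, L)
        return np.interp(new, old, seg)
    raise ParameterError(f"unknown resampling method {method!r}")


def mean_puff(
    puffs: PuffSet | Sequence[np.ndarray],
    L: int | None = None,
    method: str = "fourier",
) -> MeanPuff:
    """Pointwise average of puffs on a common grid.

    Puffs of unequal length are first resampled to L (default: the median
    puff length) — band-limited by default, ``method="linear"`` as fallback.
    """
    segs = puffs.segments if isinstance(puffs, PuffSet) else [np.asarray(s, float) for s in puffs]
    if len(segs) == 0:
        raise DegenerateInputError("cannot average an empty puff set")
    if L is None:
        L = int(np.median([s.size for s in segs]))
    if L < 2:
        raise ParameterError("common grid must have at least 2 samples")
    acc = np.zeros(L)
    for s in segs:
        acc += _resample(s, L, method)
    return MeanPuff(curve=acc / len(segs), n_source=len(segs))


def puff_mse(
    puff: np.ndarray,
    mean: MeanPuff,
    normalization: str = "range",
    value_range: float | None = None,
    method: str = "fourier",
) -> float:
    """Normalized mean square error between one puff and the mean curve.

    ``normalization="range"`` (default): sum((yhat-y)^2) / (L * r^2) with
    r the mean-curve peak-to-peak range (or ``value_range`` if given).
    ``normalization="printed"``: sum((yhat-y)^2) / mean(y), the literal
    textbook-style prefactor 1/ybar variant (not scale-invariant).
    """
    y = mean.curve
    yhat = _resample(np.asarray(puff, dtype=float), mean.L, method)
    sq = float(np.sum((yhat - y) ** 2))
    if normalization == "range":
        r = value_range if value_range is not None else float(y.max() - y.min())
        if r == 0:
            raise DegenerateInputError("mean curve has zero range")
        return sq / (mean.L * r * r)
    if normalization == "printed":
        ybar = float(y.mean())
        if ybar == 0:
            raise DegenerateInputError("mean curve has zero mean")
        return sq / ybar
    raise ParameterError(f"unknown normalization {normalization!r}")


def welch_psd(
    x,
    fs: float,
    seg_len: int | None = None,
    overlap: float = 0.5,
    window: str = "hamming",
    detrend=False,
) -> SpectralSummary:
    """Welch-WOSA one-sided power spectral density.

    Defaults: Hamming window, 50% overlap, seg_len = min(4096, len(x))
    (4096 samples is ~1.2 Hz resolution at 5 kHz); a puff-length seg_len
    reduces this to a single modified periodogram.
    """
    x = np.asarray(x, dtype=float)
    if seg_len is None:
        seg_len = min(4096, x.size)
    if seg_len > x.size:
        raise ParameterError(f"seg_len={seg_len} exceeds signal length {x.size}")
    if not 0 <= overlap < 1:
        raise ParameterError("overlap must be in [0, 1)")
    freqs, psd = sps.welch(
        x,
        fs=fs,
        window=window,
        nperseg=seg_len,
        noverlap=int(round(overlap * seg_len)),
        detrend=detrend,
        scaling="density",
    )
    return SpectralSummary(freqs=freqs, psd=psd, fs=fs)


def spectral_params(
    summary: SpectralSummary,
    band: tuple[float, float] | None = None,
) -> SpectralSummary:
    """Fill in the band moments of a PSD.

    f_mean = sum(f*P)/sum(P); f_max = argmax(P); spec_sd =
    sqrt(sum((f-f_mean)^2 * P)/sum(P)), all restricted to ``band``
    (default: the full one-sided band). Returns a new summary.
    """
    f, P = summary.freqs, summary.psd
    if band is not None:
        lo, hi = band
        if lo < 0 or hi > summary.fs / 2 or hi <= lo:
            raise ParameterError(f"band {band} not within [0, fs/2]")
        m = (f >= lo) & (f <= hi)
        f, P = f[m], P[m]
    if f.size == 0 or np.all(P == 0):
        raise DegenerateInputError("PSD has no mass in the requested band")
    total = P.sum()
    f_mean = float((f * P).sum() / total)
    f_max = float(f[int(np.argmax(P))])
    spec_sd = float(np.sqrt(((f - f_mean) ** 2 * P).sum() / total))
    return replace(summary, f_mean=f_mean, f_max=f_max, spec_sd=spec_sd)
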