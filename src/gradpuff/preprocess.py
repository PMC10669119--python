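"""Normalization and artefact-puff segmentation.

The induced potentials are recorded in arbitrary units that differ between
sequences and orientations, so all analyses start from the z-scored trace
y = (x - mean) / SD. Puffs are then delineated either from imported manual
annotations or automatically: a moving-RMS envelope is thresholded at a
robust baseline level (median + k·MAD), runs are merged/pruned by minimum
gap and duration, and each run is contracted by half the envelope window to
undo the deterministic smearing of a centered window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, ParameterError
from .signal_io import AnnotationSet, Recording

__all__ = ["PuffSet", "SegmentationParams", "zscore", "segment_puffs", "puffs_from_annotations"]


@dataclass
class PuffSet:
    """Ordered artefact-burst segments over a parent recording."""

    parent: Recording
    intervals: np.ndarray  # (n, 2) int, half-open

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=int).reshape(-1, 2)

    def __len__(self) -> int:
        return self.intervals.shape[0]

    @property
    def segments(self) -> list[np.ndarray]:
        x = self.parent.samples
        return [x[a:b] for a, b in self.intervals]

    @property
    def lengths(self) -> np.ndarray:
        return self.intervals[:, 1] - self.intervals[:, 0]

    def to_annotations(self) -> AnnotationSet:
        """Export for hand correction and re-import."""
        return AnnotationSet(self.intervals.copy(), n_samples=self.parent.n)


@dataclass(frozen=True)
class SegmentationParams:
    """Automatic-segmentation parameters (all in seconds except threshold_k).

    envelope_window : moving-RMS window width
    threshold_k     : onset threshold in multiples of the robust baseline
                      scale (1.4826·MAD of the envelope) above its median
    min_duration    : detected runs shorter than this are dropped
    min_gap         : gaps shorter than this are merged
    """

    envelope_window: float = 0.005
    threshold_k: float = 3.0
    min_duration: float = 0.005
    min_gap: float = 0.005

    def validate(self) -> None:
        for name in ("envelope_window", "threshold_k", "min_duration", "min_gap"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")


def zscore(rec: Recording, ddof: int = 1) -> Recording:
    """Z-score normalize: y = (x - mean) / SD.

    The sample (n-1) SD is the default convention; pass ``ddof=0`` for the
    population SD. A constant signal has no scale and is rejected.
    """
    x = rec.samples
    mu = x.mean()
    sd = x.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("constant signal cannot be z-scored (SD = 0)")
    return replace(rec, samples=(x - mu) / sd)


def moving_rms(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving-RMS envelope with edge replication."""
    if window < 1:
        raise ParameterError("envelope window must span at least one sample")
    return np.sqrt(ndimage.uniform_filter1d(x * x, size=window, mode="nearest"))


def _runs_above(mask: np.ndarray) -> np.ndarray:
    """Half-open index intervals of True runs in a boolean mask."""
    d = np.diff(mask.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return np.column_stack([starts, ends])


def segment_puffs(rec: Recording, params: SegmentationParams | None = None) -> PuffSet:
    """Automatically delineate artefact puffs.

    Stand-in for a manual segmentation: the moving-RMS envelope is compared
    against median + threshold_k · (1.4826·MAD); threshold crossings define
    candidate runs; gaps < min_gap are merged, runs < min_duration dropped;
    finally each run is contracted by half the envelope window per side
    (centered-window boundary-bias correction), never below one sample.
    """
    params = params or SegmentationParams()
    params.validate()
    fs = rec.fs
    w = int(round(params.envelope_window * fs))
    if w > rec.n:
        raise ParameterError(
            f"envelope_window ({w} samples) longer than the recording ({rec.n})"
        )
    env = moving_rms(rec.samples, max(w, 1))
    med = np.median(env)
    mad = 1.4826 * np.median(np.abs(env - med))
    thr = med + params.threshold_k * mad

    runs = _runs_above(env > thr)

    # merge gaps shorter than min_gap
    min_gap = int(round(params.min_gap * fs))
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] < min_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])

    # drop short runs, then contract by the half-window smearing bias
    min_dur = int(round(params.min_duration * fs))
    half = w // 2
    out = []
    for a, b in merged:
        if b - a < min_dur:
            continue
        a2, b2 = a + half, b - half
        if b2 - a2 < 1:  # keep at least the run center
            c = (a + b) // 2
            a2, b2 = c, c + 1
        out.append((a2, b2))
    return PuffSet(rec, np.asarray(out, dtype=int).reshape(-1, 2))


def puffs_from_annotations(rec: Recording, ann: AnnotationSet) -> PuffSet:
    """Build a PuffSet from (manually produced) annotations."""
    AnnotationSet(ann.intervals, n_samples=rec.n)  # re-validate against rec
    return PuffSet(rec, ann.intervals.copy())
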