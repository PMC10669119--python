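"""Surrogate-based time-frequency stationarity test.

A signal observed over a finite horizon is called stationary *relative to
that horizon* when its local (short-time) spectra do not evolve, i.e. they
all resemble the time-marginal global spectrum. This module implements the
test built on that idea:

1. a multitaper spectrogram with K orthonormal Hermite windows (a
   low-variance estimator of the Wigner-Ville spectrum),
2. a null reference obtained from phase-randomized surrogates — signals with
   exactly the original Fourier modulus but i.i.d. uniform spectral phase,
   hence stationary by construction,
3. a local-vs-global spectral dissimilarity combining a symmetrized
   Kullback-Leibler divergence of the normalized spectra and a log-spectral
   deviation:  k(G,H) = kKL(G~,H~) * (1 + kLSD(G,H)),
4. the test statistic theta = empirical variance over analysis times of the
   local-global dissimilarities; theta1 for the signal, theta0(j) for each
   surrogate,
5. a gamma distribution fitted to {theta0(j)} whose (1-alpha) quantile gives
   the threshold gamma: theta1 > gamma  =>  "non-stationary",
6. the index of non-stationarity INS = sqrt(theta1 / mean(theta0)), ~1 under
   the null, with threshold sqrt(gamma / mean(theta0)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

from .errors import DegenerateInputError, LengthError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "HermiteBank",
    "MultitaperSpectrogram",
    "StationarityResult",
    "TimeFrequencyStationarityTest",
    "hermite_bank",
    "mt_spectrogram",
    "make_surrogates",
    "spectral_distance",
    "local_global_distances",
    "theta_statistic",
    "test_stationarity",
    "ins_curve",
]

#: relative floor applied to spectra before logs in the dissimilarity
EPS_FLOOR = 1e-12


# -- Hermite window bank ------------------------------------------------------


@dataclass
class HermiteBank:
    """K orthonormal Hermite windows of odd length Nh (rows of ``windows``)."""

    windows: np.ndarray  # (K, Nh)

    @property
    def K(self) -> int:
        return self.windows.shape[0]

    @property
    def Nh(self) -> int:
        return self.windows.shape[1]

    def gram(self) -> np.ndarray:
        return self.windows @ self.windows.T


def hermite_bank(K: int, Nh: int, tmax: float | None = None) -> HermiteBank:
    """First K Hermite functions sampled symmetrically about 0, then
    symmetrically (Lowdin) orthonormalized in the discrete inner product.

    ``Nh`` must be odd and exceed 4K so the highest-order window is resolved;
    ``tmax`` is the half-width of the sampling interval in natural Hermite
    units (default covers the K-th function's support comfortably).
    """
    if K < 1:
        raise ParameterError(f"K must be >= 1, got {K}")
    if Nh % 2 == 0 or Nh <= 4 * K:
        raise ParameterError(f"Nh must be odd and > 4K (got Nh={Nh}, K={K})")
    if tmax is None:
        tmax = max(6.0, np.sqrt(2 * K + 1) + 3.0)
    t = np.linspace(-tmax, tmax, Nh)
    psi = np.empty((K, Nh))
    psi[0] = np.pi ** -0.25 * np.exp(-0.5 * t * t)
    if K > 1:
        psi[1] = np.sqrt(2.0) * t * psi[0]
    for k in range(2, K):
        psi[k] = np.sqrt(2.0 / k) * t * psi[k - 1] - np.sqrt((k - 1.0) / k) * psi[k - 2]
    # Lowdin symmetric orthonormalization: W <- G^(-1/2) W. The sampled
    # functions are already near-orthogonal, so this is a tiny correction
    # that preserves their shape and symmetry while making the Gram matrix
    # the identity to machine precision.
    G = psi @ psi.T
    evals, evecs = np.linalg.eigh(G)
    if np.min(evals) <= 0:
        raise ParameterError("Hermite bank is numerically degenerate; increase Nh")
    W = (evecs * evals ** -0.5) @ evecs.T @ psi
    return HermiteBank(windows=W)


# -- multitaper spectrogram ---------------------------------------------------


@dataclass
class MultitaperSpectrogram:
    """K-averaged Hermite spectrogram sampled at times ``tn`` (sample
    indices) and one-sided frequencies ``freqs`` (Hz if fs was given)."""

    tn: np.ndarray
    freqs: np.ndarray
    S: np.ndarray  # (len(tn), len(freqs)), >= 0
    K: int
    Nh: int


def _frame_indices(n: int, Nh: int, stride: int) -> np.ndarray:
    half = Nh // 2
    return np.arange(half, n - half, stride, dtype=int)


def _frames(x2d: np.ndarray, tn: np.ndarray, Nh: int) -> np.ndarray:
    """Extract (m, N, Nh) frames centered on tn, zero-filling out-of-range
    samples (only possible when the record barely exceeds one window)."""
    n = x2d.shape[1]
    half = Nh // 2
    offs = np.arange(-half, half + 1)
    idx = tn[:, None] + offs[None, :]
    valid = (idx >= 0) & (idx < n)
    idx_c = np.clip(idx, 0, n - 1)
    out = x2d[:, idx_c]
    out *= valid[None, :, :]
    return out


def _mt_power(x2d: np.ndarray, bank: HermiteBank, tn: np.ndarray) -> np.ndarray:
    """Batch multitaper spectrogram: (m, N, F) for m signals."""
    frames = _frames(x2d, tn, bank.Nh)
    S = None
    for h in bank.windows:
        F = np.fft.rfft(frames * h, axis=2)
        P = F.real**2 + F.imag**2
        S = P if S is None else S + P
    return S / bank.K


def mt_spectrogram(
    x,
    bank: HermiteBank,
    stride: int | None = None,
    fs: float = 1.0,
) -> MultitaperSpectrogram:
    """Multitaper Hermite spectrogram of ``x``.

    Analysis instants are spaced by ``stride`` samples (default: half the
    window length, i.e. half the equivalent width) and span the positions
    where the window is fully supported by the record. The value at (tn, f)
    is the K-average of the squared short-time Fourier magnitudes.
    """
    x = np.asarray(x, dtype=float)
    if x.size < bank.Nh:
        raise LengthError(
            f"signal of {x.size} samples is shorter than the analysis window "
            f"Nh={bank.Nh}"
        )
    if stride is None:
        stride = max(1, bank.Nh // 2)
    tn = _frame_indices(x.size, bank.Nh, stride)
    if tn.size == 0:
        tn = np.array([x.size // 2], dtype=int)
    S = _mt_power(x[None, :], bank, tn)[0]
    freqs = np.fft.rfftfreq(bank.Nh, d=1.0 / fs)
    return MultitaperSpectrogram(tn=tn, freqs=freqs, S=S, K=bank.K, Nh=bank.Nh)


# -- surrogates ---------------------------------------------------------------


def make_surrogates(x, J: int, seed=None) -> np.ndarray:
    """J phase-randomized surrogates of ``x`` as a (J, n) array.

    Each surrogate keeps the discrete Fourier modulus of x exactly and draws
    the phases i.i.d. uniform on [-pi, pi]; the DC bin (and the Nyquist bin
    for even n) keep their original phase so the time signal stays real with
    an unchanged modulus. Surrogates are stationary by construction and share
    the signal's power spectrum, so they sample the stationary null.
    """
    x = np.asarray(x, dtype=float)
    if J < 1:
        raise ParameterError("need at least one surrogate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = x.size
    X = np.fft.rfft(x)
    mag = np.abs(X)
    phases = rng.uniform(-np.pi, np.pi, size=(J, X.size))
    phases[:, 0] = np.angle(X[0])
    if n % 2 == 0:
        phases[:, -1] = np.angle(X[-1])
    return np.fft.irfft(mag * np.exp(1j * phases), n=n, axis=1)


# -- spectral dissimilarity ---------------------------------------------------


def _distance_batch(S: np.ndarray, H: np.ndarray) -> np.ndarray:
    """k(G,H) for G = rows of S (..., N, F) against H (..., F)."""
    smax = S.max(axis=-1, keepdims=True)
    hmax = H.max(axis=-1, keepdims=True)
    if np.any(smax <= 0) or np.any(hmax <= 0):
        raise DegenerateInputError("zero-mass spectrum in dissimilarity computation")
    G = np.maximum(S, EPS_FLOOR * smax)
    Hf = np.maximum(H, EPS_FLOOR * hmax)[..., None, :]
    Gn = G / G.sum(axis=-1, keepdims=True)
    Hn = Hf / Hf.sum(axis=-1, keepdims=True)
    kl = np.sum((Gn - Hn) * np.log(Gn / Hn), axis=-1)
    lsd = np.sum(np.abs(np.log(G / Hf)), axis=-1)
    return kl * (1.0 + lsd)


def spectral_distance(G, H) -> float:
    """Dissimilarity k(G,H) = kKL(G~,H~) * (1 + kLSD(G,H)) between two
    non-negative spectra on a common grid.

    kKL is the symmetrized Kullback-Leibler (Jeffreys) divergence of the
    unit-sum normalized spectra, kLSD the summed absolute log spectral
    deviation of the raw spectra; bins are floored at 1e-12 of each
    spectrum's maximum before logs. Symmetric, zero iff G = H (after
    flooring), and dimensionless.
    """
    G = np.asarray(G, dtype=float)
    H = np.asarray(H, dtype=float)
    if G.shape != H.shape or G.ndim != 1:
        raise ParameterError("G and H must be 1-D spectra on a common grid")
    if np.any(G < 0) or np.any(H < 0):
        raise DegenerateInputError("spectra must be non-negative")
    return float(_distance_batch(G[None, :], H)[0])


def local_global_distances(spec: MultitaperSpectrogram) -> np.ndarray:
    """Dissimilarity of every local spectrum to the time-marginal global
    spectrum: c_n = k(S(t_n, .), <S>_n)."""
    S = spec.S
    if S.shape[0] < 2:
        raise LengthError("need at least two analysis instants for local-vs-global")
    Gbar = S.mean(axis=0)
    return _distance_batch(S, Gbar)


def theta_statistic(c) -> float:
    """Empirical variance (1/N convention) of the local-global divergences."""
    c = np.asarray(c, dtype=float)
    if c.size < 2:
        raise ParameterError("need at least two divergences")
    return float(np.var(c))


def _theta_batch(x2d: np.ndarray, bank: HermiteBank, tn: np.ndarray) -> np.ndarray:
    """theta for each row of x2d, sharing one frame grid."""
    S = _mt_power(x2d, bank, tn)
    Gbar = S.mean(axis=1)
    c = _distance_batch(S, Gbar)
    return np.var(c, axis=1)


# -- the test -----------------------------------------------------------------


@dataclass
class StationarityResult:
    """Outcome of the surrogate-based time-frequency stationarity test."""

    theta1: float
    theta0: np.ndarray
    gamma_shape: float | None
    gamma_scale: float | None
    threshold: float
    alpha: float
    decision: str  # "stationary" / "non-stationary"
    INS: float
    INS_threshold: float
    J: int
    K: int
    Nh: int
    win_frac: float
    seed: int | None
    ins_convention: str = "sqrt"

    @property
    def theta0_mean(self) -> float:
        return float(np.mean(self.theta0))

    def summary(self) -> str:
        gam = (
            f"shape={self.gamma_shape:.4g}, scale={self.gamma_scale:.4g}"
            if self.gamma_shape is not None
            else "empirical-quantile fallback"
        )
        return "\n".join(
            [
                "Time-frequency surrogate stationarity test",
                f"  windows K / length Nh : {self.K} / {self.Nh} (win_frac={self.win_frac})",
                f"  surrogates J          : {self.J}",
                f"  theta1                : {self.theta1:.6g}",
                f"  null theta0 mean      : {self.theta0_mean:.6g}",
                f"  gamma null fit        : {gam}",
                f"  threshold (alpha={self.alpha:g}) : {self.threshold:.6g}",
                f"  decision              : {self.decision}",
                f"  INS                   : {self.INS:.6g} "
                f"(threshold {self.INS_threshold:.6g}, {self.ins_convention} convention)",
            ]
        )

    def plot_diagnostic(self, ax=None):
        """Histogram of theta0 with the fitted gamma density and the observed
        theta1 marker — the visual check that theta1 sits inside the null
        bulk (stationary) or beyond its tail (non-stationary)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.theta0, bins=min(50, max(10, self.J // 10)),
                density=True, alpha=0.6, label=r"$\theta_0$ (surrogates)")
        if self.gamma_shape is not None:
            xs = np.linspace(0, max(self.theta0.max(), self.theta1) * 1.1, 400)
            ax.plot(xs, spstats.gamma.pdf(xs, self.gamma_shape, scale=self.gamma_scale),
                    label="gamma fit")
        ax.axvline(self.theta1, color="m", lw=2, label=r"$\theta_1$ (signal)")
        ax.axvline(self.threshold, color="k", ls="--", label="threshold")
        ax.set_xlabel(r"$\theta$")
        ax.set_ylabel("density")
        ax.legend()
        return ax


def _odd_window(win_frac: float, n: int) -> int:
    Nh = int(round(win_frac * n))
    if Nh % 2 == 0:
        Nh += 1
    return Nh


def _fit_gamma_threshold(theta0: np.ndarray, alpha: float):
    """ML gamma fit (floc=0, MoM-initialized); returns (shape, scale,
    threshold) with an empirical-quantile fallback on failure."""
    m, v = float(np.mean(theta0)), float(np.var(theta0))
    try:
        if m <= 0 or v <= 0:
            raise ValueError("degenerate theta0 sample")
        a0 = m * m / v
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, loc, scale = spstats.gamma.fit(theta0, a0, floc=0, scale=v / m)
        thr = float(spstats.gamma.ppf(1.0 - alpha, a, loc=loc, scale=scale))
        if not np.isfinite(thr) or thr <= 0:
            raise ValueError("non-finite gamma quantile")
        return float(a), float(scale), thr
    except Exception as exc:  # pragma: no cover - rare numerical failure
        logger.warning("gamma fit failed (%s); using empirical quantile", exc)
        return None, None, float(np.quantile(theta0, 1.0 - alpha))


def test_stationarity(
    x,
    K: int = 5,
    win_frac: float = 0.05,
    J: int = 50,
    alpha: float = 0.05,
    seed: int | None = None,
    stride: int | None = None,
    ins_convention: str = "sqrt",
    batch: int = 256,
) -> StationarityResult:
    """Run the full surrogate test on one signal.

    The analysis window is ``Nh = odd(round(win_frac * len(x)))`` samples
    (win_frac is a fraction of the analyzed record, giving the local horizon
    relative to the global one). theta1 is computed from x, theta0(j) from
    each of J phase-randomized surrogates; a gamma distribution fitted to
    {theta0} gives the threshold at level alpha.

    ``ins_convention="sqrt"`` (default) reports INS = sqrt(theta1 /
    mean(theta0)), which is ~1 under the null; ``"ratio"`` reports the plain
    ratio theta1 / mean(theta0).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    Nh = _odd_window(win_frac, n)
    if Nh > n:
        raise LengthError(f"window Nh={Nh} longer than the signal ({n} samples)")
    bank = hermite_bank(K, Nh)  # raises ParameterError when Nh <= 4K
    if stride is None:
        stride = max(1, Nh // 2)
    tn = _frame_indices(n, Nh, stride)
    if tn.size < 2:
        raise LengthError(
            f"only {tn.size} analysis instant(s) fit (n={n}, Nh={Nh}); "
            "the record is too short for a local-vs-global comparison"
        )
    if ins_convention not in ("sqrt", "ratio"):
        raise ParameterError(f"unknown ins_convention {ins_convention!r}")

    theta1 = float(_theta_batch(x[None, :], bank, tn)[0])

    rng = np.random.default_rng(seed)
    theta0 = np.empty(J)
    done = 0
    while done < J:
        m = min(batch, J - done)
        surr = make_surrogates(x, m, seed=rng)
        theta0[done : done + m] = _theta_batch(surr, bank, tn)
        done += m

    shape, scale, thr = _fit_gamma_threshold(theta0, alpha)
    decision = "non-stationary" if theta1 > thr else "stationary"
    m0 = float(np.mean(theta0))
    if ins_convention == "sqrt":
        ins = float(np.sqrt(theta1 / m0))
        ins_thr = float(np.sqrt(thr / m0))
    else:
        ins = float(theta1 / m0)
        ins_thr = float(thr / m0)

    return StationarityResult(
        theta1=theta1,
        theta0=theta0,
        gamma_shape=shape,
        gamma_scale=scale,
        threshold=thr,
        alpha=alpha,
        decision=decision,
        INS=ins,
        INS_threshold=ins_thr,
        J=J,
        K=K,
        Nh=Nh,
        win_frac=win_frac,
        seed=seed,
        ins_convention=ins_convention,
    )


def ins_curve(
    x,
    K: int = 5,
    win_frac_list=(0.03, 0.04, 0.05, 0.07, 0.075),
    J: int = 50,
    alpha: float = 0.05,
    seed: int | None = None,
) -> list[tuple[float, float, float]]:
    """INS and its threshold across window sizes: list of
    (win_frac, INS, INS_threshold), all runs derived from one seed base."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(tuple(win_frac_list)))
    out = []
    for wf, child in zip(win_frac_list, children):
        res = test_stationarity(
            x, K=K, win_frac=wf, J=J, alpha=alpha,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        out.append((float(wf), res.INS, res.INS_threshold))
    return out


class TimeFrequencyStationarityTest:
    """Model-style interface over :func:`test_stationarity`.

    ``TimeFrequencyStationarityTest(x, K=5, win_frac=0.05, J=5000).fit(seed=0)``
    returns a :class:`StationarityResult` with ``summary()`` and
    ``plot_diagnostic()``.
    """

    def __init__(self, x, K: int = 5, win_frac: float = 0.05, J: int = 5000,
                 alpha: float = 0.05, ins_convention: str = "sqrt"):
        self.x = np.asarray(x, dtype=float)
        self.K = K
        self.win_frac = win_frac
        self.J = J
        self.alpha = alpha
        self.ins_convention = ins_convention

    def fit(self, seed: int | None = None) -> StationarityResult:
        return test_stationarity(
            self.x, K=self.K, win_frac=self.win_frac, J=self.J,
            alpha=self.alpha, seed=seed, ins_convention=self.ins_convention,
        )
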