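"""Synthetic gradient-switching artifact generator.

MRI gradient switching induces short oscillatory voltage bursts ("artefact
puffs") on electrodes placed in the bore. A recording of these induced
potentials is, to a good approximation for analysis purposes, a pseudo-periodic
train of damped oscillatory bursts, amplitude-modulated by a slow
pseudo-sinusoid, riding on a broadband noise floor and band-limited by the
acquisition chain (~350 Hz here). This module generates such recordings with
known ground-truth puff boundaries so that segmentation, feature extraction
and the stationarity tests can all be validated without measured data.

The burst template is an exponentially damped cosine — a deliberate stand-in:
the true waveform depends on coil geometry and sequence programming, and no
closed form is claimed. The template family is pluggable via
``register_template``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError
from .signal_io import AnnotationSet, Recording

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_recording",
    "sequence_preset",
    "register_template",
    "SEQUENCES",
    "ORIENTATIONS",
]

SEQUENCES = ("FSE-like", "CINE-like")
ORIENTATIONS = ("coronal", "axial", "sagittal")


# -- burst templates ----------------------------------------------------------

#: registry of burst-template families: name -> f(t, carrier_hz, decay) -> array
_TEMPLATES: dict[str, Callable[[np.ndarray, float, float], np.ndarray]] = {}


def register_template(name: str, fn: Callable[[np.ndarray, float, float], np.ndarray]) -> None:
    """Register a burst-template family ``fn(t, carrier_hz, decay_per_s)``."""
    _TEMPLATES[name] = fn


register_template(
    "damped_cosine",
    lambda t, f0, lam: np.exp(-lam * t) * np.cos(2 * np.pi * f0 * t),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic induced-potential generator.

    Attributes
    ----------
    fs, duration : float
        Sampling rate (Hz) and record length (s). Defaults match a 5 kHz,
        10 s acquisition.
    puff_period, puff_duration : float
        Seconds between burst onsets and burst length. 0.0625 s between
        onsets gives 80 bursts per 5 s analysis window.
    puff_waveform : str
        Template family name (see ``register_template``).
    carrier_freq : float
        Oscillation frequency of the burst template, Hz.
    decay : float
        Exponential decay constant of the burst envelope, 1/s.
    puff_amplitude : float
        Peak template amplitude, arbitrary units.
    am_frequency, am_depth : float
        Slow amplitude modulation of the burst train: each burst sample at
        global time t is scaled by ``1 + am_depth*sin(2*pi*am_frequency*t)``.
    noise_sd : float
        Standard deviation of the additive white Gaussian floor.
    baseline_amplitude, baseline_freq : float
        Optional additive low-frequency sinusoidal baseline (emulating the
        slow drift observable with no sequence active); off when amplitude 0.
    pink_noise_sd : float
        Optional additive 1/f-ish noise component; off when 0.
    lowpass_cutoff : float or None
        Acquisition-bandwidth emulation: zero-phase Butterworth low-pass
        (order ``lowpass_order``) applied last. ``None`` disables it.
    jitter_sd : float
        SD in seconds of Gaussian onset jitter, truncated at
        ±puff_period/4 so ground-truth intervals stay disjoint.
    seed : int
        RNG seed; identical (config, seed) gives bit-identical output.
    """

    fs: float = 5000.0
    duration: float = 10.0
    puff_period: float = 0.0625
    puff_duration: float = 0.02
    puff_waveform: str = "damped_cosine"
    carrier_freq: float = 288.0
    decay: float = 100.0
    puff_amplitude: float = 1.0
    am_frequency: float = 1.2
    am_depth: float = 0.3
    noise_sd: float = 0.05
    baseline_amplitude: float = 0.0
    baseline_freq: float = 0.8
    pink_noise_sd: float = 0.0
    lowpass_cutoff: float | None = 350.0
    lowpass_order: int = 4
    jitter_sd: float = 0.0
    seed: int = 0
    label: str = ""
    orientation: str = ""

    def validate(self) -> None:
        if not self.fs > 0:
            raise ConfigurationError(f"fs must be > 0, got {self.fs}")
        if not self.duration > 0:
            raise ConfigurationError(f"duration must be > 0, got {self.duration}")
        if not 0 < self.puff_duration < self.puff_period:
            raise ConfigurationError(
                "need 0 < puff_duration < puff_period, got "
                f"puff_duration={self.puff_duration}, puff_period={self.puff_period}"
            )
        if not 0 <= self.am_depth <= 1:
            raise ConfigurationError(f"am_depth must be in [0, 1], got {self.am_depth}")
        if self.lowpass_cutoff is not None and not self.lowpass_cutoff < self.fs / 2:
            raise ConfigurationError(
                f"lowpass_cutoff must be below fs/2={self.fs / 2}, got {self.lowpass_cutoff}"
            )
        if self.noise_sd < 0 or self.pink_noise_sd < 0 or self.jitter_sd < 0:
            raise ConfigurationError("noise/jitter SDs must be non-negative")
        if self.puff_waveform not in _TEMPLATES:
            raise ConfigurationError(f"unknown puff_waveform {self.puff_waveform!r}")


@dataclass
class GroundTruth:
    """True puff boundaries of a generated recording: ordered, disjoint,
    half-open sample intervals, one per burst."""

    boundaries: np.ndarray  # (n, 2) int

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=int).reshape(-1, 2)

    def __len__(self) -> int:
        return self.boundaries.shape[0]

    def to_annotations(self, n_samples: int = 0) -> AnnotationSet:
        return AnnotationSet(self.boundaries.copy(), n_samples=n_samples)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-ish noise via rFFT amplitude shaping."""
    w = rng.standard_normal(n)
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = 1.0 / np.sqrt(f[nz])
    scale[0] = 0.0  # drop DC
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_recording(config: GeneratorConfig) -> tuple[Recording, GroundTruth]:
    """Generate one synthetic induced-potential recording.

    Construction order: damped-oscillation burst train with (optionally
    jittered) onsets every ``puff_period`` seconds, multiplied pointwise by
    the slow AM waveform; plus optional additive low-frequency baseline and
    1/f-ish noise; plus the white Gaussian floor; finally the zero-phase
    low-pass emulating the acquisition bandwidth. Ground truth records the
    half-open sample interval of every burst's template support.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n = int(round(fs * config.duration))
    dur_samp = max(1, int(round(config.puff_duration * fs)))
    template_fn = _TEMPLATES[config.puff_waveform]
    t_tpl = np.arange(dur_samp) / fs
    template = config.puff_amplitude * template_fn(t_tpl, config.carrier_freq, config.decay)

    n_puffs = int(math.floor(config.duration / config.puff_period + 1e-9))
    # jitter is drawn for every nominal onset (even when zero) so that the
    # random stream, hence the noise floor, does not depend on jitter_sd
    jit = rng.standard_normal(n_puffs) * config.jitter_sd
    np.clip(jit, -config.puff_period / 4, config.puff_period / 4, out=jit)

    train = np.zeros(n)
    bounds = []
    tgrid = np.arange(n) / fs
    am = 1.0 + config.am_depth * np.sin(2 * np.pi * config.am_frequency * tgrid)
    for k in range(n_puffs):
        start = int(round((k * config.puff_period + jit[k]) * fs))
        if start >= n:
            break
        end = min(start + dur_samp, n)
        seg = template[: end - start] * am[start:end]
        train[start:end] += seg
        bounds.append((start, end))

    x = train
    if config.baseline_amplitude:
        x = x + config.baseline_amplitude * np.sin(2 * np.pi * config.baseline_freq * tgrid)
    if config.pink_noise_sd:
        x = x + config.pink_noise_sd * _pink_noise(n, rng)
    if config.noise_sd:
        x = x + config.noise_sd * rng.standard_normal(n)
    if config.lowpass_cutoff is not None:
        sos = sps.butter(config.lowpass_order, config.lowpass_cutoff, fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, x)

    rec = Recording(
        samples=x,
        fs=fs,
        label=config.label,
        orientation=config.orientation,
        source=f"gradpuff.synthgen seed={config.seed}",
    )
    return rec, GroundTruth(np.asarray(bounds, dtype=int).reshape(-1, 2))


# -- sequence/orientation presets --------------------------------------------

# Six spectrally distinguishable design points. Burst repetition follows the
# sequence TR regime (FSE: slower, longer bursts; CINE: faster, very short
# bursts — short enough that per-burst time-frequency analysis breaks down,
# as it does on measured CINE data). Carriers are multiples of the repetition
# rate so the pseudo-periodic line comb places a line exactly at the carrier.
# Burst decay follows the one rule decay = 2/puff_duration: the envelope
# falls to e^-2 (~13.5%) of its peak at the end of the nominal support, so
# ground-truth intervals coincide with where the burst carries energy while
# the burst end remains a detectable edge.
_PRESETS: dict[tuple[str, str], dict] = {
    ("FSE-like", "coronal"): dict(
        puff_period=0.0625, puff_duration=0.020, carrier_freq=288.0, decay=100.0,
        am_frequency=1.2, am_depth=0.30,
    ),
    ("FSE-like", "axial"): dict(
        puff_period=0.0625, puff_duration=0.022, carrier_freq=96.0, decay=91.0,
        am_frequency=1.0, am_depth=0.35,
    ),
    ("FSE-like", "sagittal"): dict(
        puff_period=0.0625, puff_duration=0.018, carrier_freq=128.0, decay=111.0,
        am_frequency=1.4, am_depth=0.25,
    ),
    ("CINE-like", "coronal"): dict(
        puff_period=0.05, puff_duration=0.008, carrier_freq=240.0, decay=250.0,
        am_frequency=1.1, am_depth=0.30,
    ),
    ("CINE-like", "axial"): dict(
        puff_period=0.05, puff_duration=0.008, carrier_freq=260.0, decay=250.0,
        am_frequency=0.9, am_depth=0.30,
    ),
    ("CINE-like", "sagittal"): dict(
        puff_period=0.05, puff_duration=0.009, carrier_freq=220.0, decay=222.0,
        am_frequency=1.3, am_depth=0.25,
    ),
}

_SEQ_ALIASES = {"fse": "FSE-like", "fse-like": "FSE-like",
                "cine": "CINE-like", "cine-like": "CINE-like"}


def sequence_preset(name: str, orientation: str, **overrides) -> GeneratorConfig:
    """Return the generator config for one of the six sequence x orientation
    synthetic variants. Extra keyword arguments override preset fields."""
    seq = _SEQ_ALIASES.get(str(name).lower())
    ori = str(orientation).lower()
    if seq is None or ori not in ORIENTATIONS:
        raise KeyError(
            f"unknown preset ({name!r}, {orientation!r}); sequences are "
            f"{SEQUENCES} and orientations {ORIENTATIONS}"
        )
    params = dict(_PRESETS[(seq, ori)])
    params.update(label=seq, orientation=ori)
    params.update(overrides)
    cfg = GeneratorConfig(**params)
    cfg.validate()
    return cfg
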