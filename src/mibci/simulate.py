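"""Synthetic motor-imagery EEG with efficient and inefficient user archetypes.

The generator emulates a 16-electrode sensorimotor montage sampled at
250 S/s with a 0.5–30 Hz acquisition band: per-channel pink (1/f)
background noise is spatially smeared across the montage, a mu (≈10 Hz)
plus beta (≈20 Hz) sensorimotor oscillation is mixed into C3/C4, and
imagery of one hand attenuates the contralateral oscillation
(event-related desynchronization, ERD).

Two archetypes produce class information through different mechanisms:

* ``efficient`` — lateralized ERD: the contralateral motor channel's
  mu/beta amplitude is scaled by sqrt(1 - erd_depth) on imagery trials.
  Band-variance features (what CSP consumes) separate the classes.
* ``inefficient`` — no ERD; instead a phase-locked low-frequency template
  is added at frontal/temporal electrodes with class-dependent *polarity*.
  A sign flip leaves every second-moment statistic untouched, so the two
  class covariances are identical by construction and CSP is blind to it,
  while a waveform-aware decoder can read the polarity directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal

from .records import SubjectRecord

#: The 16-electrode sensorimotor montage (10–20 names, fixed order).
MONTAGE_16: Tuple[str, ...] = (
    "F3", "Fz", "F4", "FC1", "FC5", "FC2", "FC6", "C3",
    "Cz", "C4", "CP1", "CP5", "CP2", "CP6", "T7", "T8",
)

#: Approximate 2-D scalp coordinates (head-radius units) for MONTAGE_16,
#: used to build the spatial smearing matrix.
MONTAGE_XY = {
    "F3": (-0.35, 0.45), "Fz": (0.0, 0.45), "F4": (0.35, 0.45),
    "FC1": (-0.20, 0.25), "FC5": (-0.60, 0.25), "FC2": (0.20, 0.25),
    "FC6": (0.60, 0.25), "C3": (-0.40, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.40, 0.0), "CP1": (-0.20, -0.25), "CP5": (-0.60, -0.25),
    "CP2": (0.20, -0.25), "CP6": (0.60, -0.25), "T7": (-0.80, 0.0),
    "T8": (0.80, 0.0),
}

LEFT, RIGHT = 0, 1
CLASS_NAMES = ("left", "right")

#: Electrodes carrying the inefficient-user template (outside motor cortex).
TEMPLATE_CHANNELS = ("F3", "F4", "T7", "T8")


@dataclass(frozen=True)
class SimConfig:
    """Acquisition geometry and trial plan of the emulated recording."""

    n_channels: int = 16
    channel_names: Tuple[str, ...] = MONTAGE_16
    fs: float = 250.0
    n_trials: int = 120
    epoch_s: float = 4.0
    acquisition_band: Tuple[float, float] = (0.5, 30.0)

    def __post_init__(self) -> None:
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must equal n_channels")
        if self.n_trials % 2 != 0:
            raise ValueError("n_trials must be even (balanced two-class design)")
        n_samp = self.fs * self.epoch_s
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("fs * epoch_s must be an integer sample count")
        lo, hi = self.acquisition_band
        if not (0 < lo < hi < self.fs / 2):
            raise ValueError("acquisition_band must satisfy 0 < low < high < fs/2")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_s))


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters of one simulated subject.

    erd_depth — fractional mu/beta variance reduction at the contralateral
    motor channel during imagery (efficient-user mechanism).
    waveform_contrast — amplitude (relative to background RMS) of the
    class-polarity template at non-motor channels (inefficient-user
    mechanism); variance-neutral by construction.
    snr — power of the sensorimotor oscillation relative to the background
    at the motor channels.
    """

    subject_id: str
    archetype: str  # "efficient" | "inefficient"
    erd_depth: float = 0.0
    waveform_contrast: float = 0.0
    snr: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype not in ("efficient", "inefficient"):
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if not (0.0 <= self.erd_depth <= 1.0):
            raise ValueError("erd_depth must lie in [0, 1]")
        if not (0.0 <= self.waveform_contrast <= 1.0):
            raise ValueError("waveform_contrast must lie in [0, 1]")
        if self.snr < 0:
            raise ValueError("snr must be non-negative")
        if self.archetype == "efficient" and self.waveform_contrast != 0.0:
            raise ValueError("efficient archetype requires waveform_contrast = 0")
        if self.archetype == "inefficient" and self.erd_depth > 0.05:
            raise ValueError("inefficient archetype requires erd_depth ≈ 0")


@dataclass
class EpochSet:
    """Trials × channels × samples tensor with labels and sampling metadata."""

    data: np.ndarray  # (n_trials, n_channels, n_samples), microvolts
    labels: np.ndarray  # int {0: left, 1: right}
    fs: float
    channel_names: Tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal trial count")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel count must equal channel-name count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if not np.all(np.isin(self.labels, (LEFT, RIGHT))):
            raise ValueError("labels must be 0 (left) or 1 (right)")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, name: str) -> int:
        return tuple(self.channel_names).index(name)

    def copy(self) -> "EpochSet":
        return EpochSet(self.data.copy(), self.labels.copy(), self.fs,
                        tuple(self.channel_names))


def smearing_matrix(channel_names: Sequence[str], decay: float = 0.35) -> np.ndarray:
    """Spatial mixing matrix M_ij = exp(-d_ij / decay) on the montage layout.

    Rows are normalized to unit L2 norm so mixing roughly preserves power.
    Gives the background realistic cross-channel covariance for CSP to whiten.
    """
    xy = np.array([MONTAGE_XY[c] for c in channel_names])
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    m = np.exp(-d / decay)
    return m / np.linalg.norm(m, axis=1, keepdims=True)


def pink_noise(rng: np.random.Generator, shape: Tuple[int, ...], n_samples: int) -> np.ndarray:
    """1/f-amplitude noise along the last axis, unit variance per series."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0  # no DC
    out = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _smr_oscillation(rng: np.random.Generator, n_trials: int, n_samples: int,
                     fs: float) -> np.ndarray:
    """Arciform mu rhythm (10 Hz ± jitter) with its phase-locked beta-band
    first harmonic, unit RMS, per trial.

    The sensorimotor mu rhythm is non-sinusoidal; its beta-band component is
    largely the first harmonic, phase-locked to the mu cycle, which is what
    gives the rhythm its comb shape.  Each trial draws a random mu phase and
    a small frequency jitter.
    """
    t = np.arange(n_samples) / fs
    f_mu = 10.0 + rng.uniform(-0.3, 0.3, size=(n_trials, 1))
    ph_mu = rng.uniform(0, 2 * np.pi, size=(n_trials, 1))
    phase = 2 * np.pi * f_mu * t + ph_mu
    osc = np.sin(phase) + 0.4 * np.sin(2 * phase + 0.8)
    # mild slow AM; kept shallow so per-trial rhythm power is homogeneous
    am = pink_noise(rng, (n_trials,), n_samples)
    win = max(int(0.25 * fs), 3)
    kernel = np.ones(win) / win
    am = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), -1, am)
    env = np.clip(1.0 + 0.05 * am, 0.5, None)
    osc = osc * env
    return osc / osc.std(axis=-1, keepdims=True)


def _polarity_template(rng: np.random.Generator, n_samples: int, fs: float) -> np.ndarray:
    """Subject-fixed low-frequency template, unit RMS, Hann-windowed.

    Lives well inside the 0.5–30 Hz acquisition band (≈2–5 Hz content) so
    the hardware band-pass transmits it.
    """
    t = np.arange(n_samples) / fs
    f1 = rng.uniform(2.0, 3.5)
    f2 = rng.uniform(4.0, 5.5)
    ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
    tmpl = np.sin(2 * np.pi * f1 * t + ph1) + 0.6 * np.sin(2 * np.pi * f2 * t + ph2)
    tmpl *= np.hanning(n_samples)
    rms = np.sqrt(np.mean(tmpl ** 2))
    return tmpl / rms


def _acquisition_filter(data: np.ndarray, fs: float, band: Tuple[float, float]) -> np.ndarray:
    sos = signal.butter(5, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def simulate_subject(profile: SubjectProfile,
                     config: SimConfig = SimConfig()) -> Tuple[EpochSet, SubjectRecord]:
    """Generate one subject's balanced left/right epoch set.

    Deterministic given ``profile.seed``.  Returns the epochs plus a
    partially filled :class:`SubjectRecord` (decoding fields are completed
    by the evaluation stage).
    """
    rng = np.random.default_rng(profile.seed)
    n_tr, n_ch, n_samp = config.n_trials, config.n_channels, config.n_samples
    names = tuple(config.channel_names)

    # balanced, shuffled label sequence
    labels = np.array([LEFT] * (n_tr // 2) + [RIGHT] * (n_tr // 2))
    rng.shuffle(labels)

    # spatially smeared pink background, unit-ish channel variance
    m = smearing_matrix(names)
    bg = pink_noise(rng, (n_tr, n_ch), n_samp)
    data = np.einsum("ij,tjs->tis", m, bg)
    bg_rms = data.std()

    # sensorimotor rhythm at C3/C4 with lateralized ERD
    i_c3, i_c4 = names.index("C3"), names.index("C4")
    amp = np.sqrt(profile.snr) * bg_rms
    atten = np.sqrt(1.0 - profile.erd_depth)
    for idx, contra in ((i_c3, RIGHT), (i_c4, LEFT)):
        osc = _smr_oscillation(rng, n_tr, n_samp, config.fs)
        trial_amp = np.full(n_tr, amp)
        trial_amp[labels == contra] *= atten  # ERD contralateral to the cued hand
        pattern = m[:, idx] / m[idx, idx]  # peak weight 1 at the motor electrode
        data += trial_amp[:, None, None] * pattern[None, :, None] * osc[:, None, :]

    # inefficient-user mechanism: phase-locked template, class-dependent polarity
    if profile.waveform_contrast > 0:
        tmpl = _polarity_template(rng, n_samp, config.fs)
        polarity = np.where(labels == LEFT, 1.0, -1.0)
        jitter = rng.lognormal(mean=0.0, sigma=0.1, size=n_tr)
        t_amp = profile.waveform_contrast * bg_rms * polarity * jitter
        ch_idx = [names.index(c) for c in TEMPLATE_CHANNELS]
        for ci in ch_idx:
            data[:, ci, :] += t_amp[:, None] * tmpl[None, :]

    data = _acquisition_filter(data, config.fs, config.acquisition_band)
    data *= 10.0  # microvolt scale

    epochs = EpochSet(np.ascontiguousarray(data), labels, config.fs, names)
    record = SubjectRecord(
        subject_id=profile.subject_id,
        archetype=profile.archetype,
        seed=profile.seed,
        erd_depth=profile.erd_depth,
        waveform_contrast=profile.waveform_contrast,
        snr=profile.snr,
    )
    return epochs, record


#: Cohort effect-size defaults.  Efficient users: complete contralateral
#: desynchronization of a strong sensorimotor rhythm (an idealized textbook
#: ERD, deliberately cleaner than real EEG).  Inefficient users: no ERD and
#: a weak baseline rhythm (low resting SMR amplitude is the classic
#: correlate of BCI inefficiency), but a class-polarity waveform template.
ERD_DEPTH_DEFAULT = 1.0
CONTRAST_DEFAULT = 0.6
SNR_EFFICIENT = 20.0
SNR_INEFFICIENT = 2.0


def default_profile(archetype: str, subject_id: str, seed: int,
                    erd_depth: float = ERD_DEPTH_DEFAULT,
                    waveform_contrast: float = CONTRAST_DEFAULT,
                    snr: Optional[float] = None) -> SubjectProfile:
    """Archetype defaults: efficient users express ERD only, inefficient users
    express the variance-neutral template only."""
    if archetype == "efficient":
        return SubjectProfile(subject_id, "efficient", erd_depth=erd_depth,
                              waveform_contrast=0.0,
                              snr=SNR_EFFICIENT if snr is None else snr,
                              seed=seed)
    return SubjectProfile(subject_id, "inefficient", erd_depth=0.0,
                          waveform_contrast=waveform_contrast,
                          snr=SNR_INEFFICIENT if snr is None else snr,
                          seed=seed)


def simulate_cohort(n_subjects: int, fraction_inefficient: float = 0.5,
                    config: SimConfig = SimConfig(), seed: int = 0,
                    erd_depth: float = ERD_DEPTH_DEFAULT,
                    waveform_contrast: float = CONTRAST_DEFAULT,
                    snr: Optional[float] = None) -> List[Tuple[EpochSet, SubjectRecord]]:
    """Simulate a cohort; per-subject seeds derive from the cohort seed.

    round(n_subjects * fraction_inefficient) subjects are inefficient, the
    rest efficient; archetype order is interleaved deterministically.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for a group analysis")
    if not (0.0 <= fraction_inefficient <= 1.0):
        raise ValueError("fraction_inefficient must lie in [0, 1]")
    n_ineff = int(round(n_subjects * fraction_inefficient))
    archetypes = ["inefficient"] * n_ineff + ["efficient"] * (n_subjects - n_ineff)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_subjects)]
    out = []
    for i, (arch, sub_seed) in enumerate(zip(archetypes, child_seeds)):
        prof = default_profile(arch, f"S{i + 1:02d}", sub_seed,
                               erd_depth=erd_depth,
                               waveform_contrast=waveform_contrast, snr=snr)
        out.append(simulate_subject(prof, config))
    return out
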