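"""Temporal filtering and epoch selection.

Filtering follows the recording chain of a standard MI-BCI rig: a 48–52 Hz
notch and 0.5–30 Hz band-pass at acquisition, then a 7–30 Hz fifth-order
Butterworth stage (optionally a multi-band filter bank) feeding CSP.  All
offline filters are applied forward–backward (zero phase), which epoch-based
offline analysis permits and which avoids group-delay distortion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy import signal

from .simulate import EpochSet


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth filter: 7–30 Hz band-pass by default."""

    kind: str = "bandpass"  # "bandpass" | "notch"
    order: int = 5
    band: Tuple[float, float] = (7.0, 30.0)

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass", "notch"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        lo, hi = self.band
        if not (0 < lo < hi):
            raise ValueError("band must satisfy 0 < low < high")


@dataclass(frozen=True)
class EpochWindow:
    """Seconds from trial onset delimiting the imagery epoch (default 4–8 s)."""

    start_s: float = 4.0
    end_s: float = 8.0

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("end_s must exceed start_s")
        if self.start_s < 0:
            raise ValueError("start_s must be non-negative")


@dataclass(frozen=True)
class FilterBank:
    """Ordered band-pass bands covering 7–30 Hz; default is the single wide band."""

    bands: Tuple[Tuple[float, float], ...] = ((7.0, 30.0),)

    def __post_init__(self) -> None:
        if len(self.bands) == 0:
            raise ValueError("filter bank must contain at least one band")
        for lo, hi in self.bands:
            if not (0 < lo < hi):
                raise ValueError(f"invalid band ({lo}, {hi})")


def _design_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    lo, hi = spec.band
    if hi >= fs / 2:
        raise ValueError(f"band edge {hi} Hz >= Nyquist {fs / 2} Hz")
    btype = "bandpass" if spec.kind == "bandpass" else "bandstop"
    return signal.butter(spec.order, (lo, hi), btype=btype, fs=fs, output="sos")


def apply_filter(epochs: EpochSet, spec: FilterSpec) -> EpochSet:
    """Zero-phase Butterworth filtering of every trial and channel.

    Forward–backward application squares the magnitude response (effective
    order doubling) and cancels phase; reflected padding absorbs the IIR
    transient at the 4 s epoch edges.
    """
    sos = _design_sos(spec, epochs.fs)
    out = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return EpochSet(np.ascontiguousarray(out), epochs.labels.copy(), epochs.fs,
                    tuple(epochs.channel_names))


def extract_epoch(trial_series: np.ndarray, window: EpochWindow,
                  fs: float) -> np.ndarray:
    """Slice the half-open sample interval [start_s*fs, end_s*fs) per trial.

    ``trial_series`` is (trials, channels, samples) over the full trial.
    Returns the sliced tensor; wrap it in an :class:`EpochSet` with the
    caller's labels/metadata as needed.
    """
    series = np.asarray(trial_series)
    n_samples = series.shape[-1]
    i0 = int(round(window.start_s * fs))
    i1 = int(round(window.end_s * fs))
    if i1 > n_samples:
        raise ValueError(
            f"window [{window.start_s}, {window.end_s}] s exceeds the "
            f"{n_samples / fs:g} s trial")
    return series[..., i0:i1]


def apply_filter_bank(epochs: EpochSet, bank: FilterBank = FilterBank()) -> List[EpochSet]:
    """Band-filtered copies of the epochs, one per bank band (FBCSP front end)."""
    return [apply_filter(epochs, FilterSpec(kind="bandpass", band=b)) for b in bank.bands]


def butter_band_magnitude(spec: FilterSpec, fs: float, freq: float) -> float:
    """Analytic |H(f)| of the zero-phase (forward–backward) filter.

    Oracle helper: the squared Butterworth magnitude at ``freq``.
    """
    sos = _design_sos(spec, fs)
    _, h = signal.sosfreqz(sos, worN=[freq], fs=fs)
    return float(np.abs(h[0]) ** 2)
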