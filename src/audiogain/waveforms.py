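"""Sweep-set preprocessing and evoked-potential feature extraction.

A :class:`SweepSet` holds the raw trial-by-sample voltage matrix for one
ear/level/modality recording.  The functions here implement the analysis
chain for a single recording:

``bandpass_abr`` -> ``average_trials`` -> ``extract_abr_wave1`` /
``extract_aep_components`` -> ``compute_gain``.

ABR sweeps are bandpass filtered (100-3000 Hz, 5th-order Butterworth,
zero-phase by default) before averaging; cortical AEP sweeps are averaged
without software filtering.  Wave I amplitude is the difference between the
voltage at stimulus onset and the first post-onset peak; AEP components are
window extrema (P1: max on [15, 30] ms, N1: min on [25, 60] ms, P2: max on
[60, 110] ms).  Central gain is the ratio of an AEP complex amplitude
(P1-N1 or N1-P2) to the ABR wave I amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import signal

__all__ = [
    "SweepSet",
    "Waveform",
    "AbrFeatures",
    "AepFeatures",
    "GainMeasures",
    "GainUndefinedError",
    "bandpass_abr",
    "average_trials",
    "extract_abr_wave1",
    "extract_aep_components",
    "compute_gain",
    "AEP_WINDOWS_MS",
]

#: Component search windows in ms post-onset (inclusive edges).
AEP_WINDOWS_MS = {"P1": (15.0, 30.0), "N1": (25.0, 60.0), "P2": (60.0, 110.0)}

BANDPASS_LOW_HZ = 100.0
BANDPASS_HIGH_HZ = 3000.0
BANDPASS_ORDER = 5
MIN_FS_HZ = 6500.0  # Nyquist above the 3 kHz band edge with margin


@dataclass
class SweepSet:
    """One recording: trial x sample voltage matrix plus acquisition metadata.

    Parameters
    ----------
    voltages
        ``(n_trials, n_samples)`` array in microvolts.
    fs
        Sampling rate in samples/s.
    t0
        Sample index of stimulus onset (0-based), so pre-stimulus baseline
        occupies samples ``[0, t0)``.
    modality
        ``"ABR"`` or ``"AEP"``.
    """

    voltages: np.ndarray
    fs: float
    t0: int
    modality: str
    level_db_spl: Optional[float] = None
    ear: Optional[str] = None
    animal_id: Optional[str] = None
    age_weeks: Optional[float] = None
    stimulus: str = "click"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.voltages.ndim != 2:
            raise ValueError("voltages must be a 2-D trial x sample matrix")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not (0 <= self.t0 < self.voltages.shape[1]):
            raise ValueError("t0 must lie within the record")
        if self.modality not in ("ABR", "AEP"):
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def n_trials(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[1]

    def times_ms(self) -> np.ndarray:
        """Per-sample time in ms, re-referenced so stimulus onset is 0."""
        return (np.arange(self.n_samples) - self.t0) / self.fs * 1e3


@dataclass
class Waveform:
    """A single trial-averaged trace with onset-referenced time axis."""

    t_ms: np.ndarray
    v_uv: np.ndarray

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.v_uv = np.asarray(self.v_uv, dtype=float)
        if self.t_ms.shape != self.v_uv.shape:
            raise ValueError("time and voltage arrays must have equal shape")

    def value_at(self, t_ms: float) -> float:
        """Voltage at the sample closest to ``t_ms``."""
        return float(self.v_uv[int(np.argmin(np.abs(self.t_ms - t_ms)))])


@dataclass
class AbrFeatures:
    """ABR wave I amplitude (onset-to-first-peak) and peak latency."""

    wave1_amplitude: Optional[float]
    wave1_latency: Optional[float]

    @property
    def absent(self) -> bool:
        return self.wave1_amplitude is None


@dataclass
class AepFeatures:
    p1_latency: float
    n1_latency: float
    p2_latency: float
    p1n1_amplitude: float
    n1p2_amplitude: float


@dataclass
class GainMeasures:
    p1n1_gain: float
    n1p2_gain: float


class GainUndefinedError(ValueError):
    """Raised when the gain ratio denominator (wave I) is absent or <= 0."""


def _butter_sos(fs: float):
    return signal.butter(
        BANDPASS_ORDER,
        [BANDPASS_LOW_HZ, BANDPASS_HIGH_HZ],
        btype="bandpass",
        fs=fs,
        output="sos",
    )


def bandpass_abr(sweeps: SweepSet, zero_phase: bool = True) -> SweepSet:
    """Bandpass-filter ABR sweeps (100-3000 Hz, 5th-order Butterworth).

    The default applies the filter forward then time-reversed (zero net
    phase shift; effective order doubles).  ``zero_phase=False`` gives the
    causal single-pass response instead.  AEP sweeps are rejected: they are
    analysed with no software filtering.
    """
    if sweeps.modality == "AEP":
        raise ValueError("AEP sweeps must not be software-filtered")
    if sweeps.fs < MIN_FS_HZ:
        raise ValueError(
            f"fs {sweeps.fs} Hz too low for the 3 kHz band edge "
            f"(need >= {MIN_FS_HZ} Hz)"
        )
    sos = _butter_sos(sweeps.fs)
    if zero_phase:
        filtered = signal.sosfiltfilt(sos, sweeps.voltages, axis=1)
    else:
        filtered = signal.sosfilt(sos, sweeps.voltages, axis=1)
    return replace(sweeps, voltages=filtered)


def average_trials(sweeps: SweepSet) -> Waveform:
    """Pointwise mean across trials, time re-referenced to stimulus onset."""
    if sweeps.n_trials < 1:
        raise ValueError("sweep set has no trials")
    return Waveform(t_ms=sweeps.times_ms(), v_uv=sweeps.voltages.mean(axis=0))


def extract_abr_wave1(
    avg: Waveform,
    search_window_ms: tuple[float, float] = (0.5, 3.0),
    prominence_floor: Optional[float] = None,
) -> AbrFeatures:
    """Extract ABR wave I: earliest qualifying post-onset local maximum.

    Amplitude is ``V(first peak) - V(t=0)`` (baseline is the single sample at
    stimulus onset).  A peak qualifies if it is a local maximum inside
    ``search_window_ms`` with prominence >= ``prominence_floor``; the default
    floor is 2x the pre-stimulus noise SD of the averaged trace (0 when no
    pre-stimulus samples exist), so noise wiggles ahead of the true wave I
    are not mistaken for it.  If no peak qualifies the feature is flagged
    absent (fields ``None``), which is distinct from an amplitude of zero.
    """
    if prominence_floor is None:
        pre = avg.v_uv[avg.t_ms < 0]
        prominence_floor = 2.0 * float(np.std(pre)) if pre.size >= 2 else 0.0
    lo, hi = search_window_ms
    if avg.t_ms[-1] < hi:
        raise ValueError("waveform does not cover the wave I search window")
    mask = (avg.t_ms >= lo) & (avg.t_ms <= hi)
    idx = np.flatnonzero(mask)
    if idx.size < 3:
        raise ValueError("too few samples in the wave I search window")
    # Search for local maxima on a slightly padded segment so window-edge
    # peaks are still seen as maxima, then restrict to the window.
    pad = 2
    seg_lo = max(idx[0] - pad, 0)
    seg_hi = min(idx[-1] + pad + 1, avg.v_uv.size)
    seg = avg.v_uv[seg_lo:seg_hi]
    if prominence_floor > 0:
        peaks, _ = signal.find_peaks(seg, prominence=prominence_floor)
    else:
        peaks, _ = signal.find_peaks(seg)
    peaks = peaks + seg_lo
    peaks = peaks[np.isin(peaks, idx)]
    if peaks.size == 0:
        return AbrFeatures(wave1_amplitude=None, wave1_latency=None)
    first = int(peaks.min())  # earliest wins
    baseline = avg.value_at(0.0)
    return AbrFeatures(
        wave1_amplitude=float(avg.v_uv[first] - baseline),
        wave1_latency=float(avg.t_ms[first]),
    )


def extract_aep_components(avg: Waveform) -> AepFeatures:
    """Window-extremum AEP components; ties broken by earliest sample."""
    if avg.t_ms[-1] < AEP_WINDOWS_MS["P2"][1]:
        raise ValueError("waveform does not cover the 110 ms P2 window")

    def _window(lo: float, hi: float) -> np.ndarray:
        sel = np.flatnonzero((avg.t_ms >= lo) & (avg.t_ms <= hi))
        if sel.size == 0:
            raise ValueError(f"no samples in window [{lo}, {hi}] ms")
        return sel

    w_p1 = _window(*AEP_WINDOWS_MS["P1"])
    w_n1 = _window(*AEP_WINDOWS_MS["N1"])
    w_p2 = _window(*AEP_WINDOWS_MS["P2"])
    i_p1 = w_p1[int(np.argmax(avg.v_uv[w_p1]))]  # argmax returns first max
    i_n1 = w_n1[int(np.argmin(avg.v_uv[w_n1]))]
    i_p2 = w_p2[int(np.argmax(avg.v_uv[w_p2]))]
    v = avg.v_uv
    return AepFeatures(
        p1_latency=float(avg.t_ms[i_p1]),
        n1_latency=float(avg.t_ms[i_n1]),
        p2_latency=float(avg.t_ms[i_p2]),
        p1n1_amplitude=float(v[i_p1] - v[i_n1]),
        n1p2_amplitude=float(v[i_p2] - v[i_n1]),
    )


def compute_gain(abr: AbrFeatures, aep: AepFeatures) -> GainMeasures:
    """Central gain: AEP complex amplitude / ABR wave I amplitude.

    Raises :class:`GainUndefinedError` when wave I is absent or <= 0; such
    recordings are excluded upstream rather than producing infinities.
    """
    if abr.absent:
        raise GainUndefinedError("ABR wave I absent; gain undefined")
    if abr.wave1_amplitude <= 0:
        raise GainUndefinedError(
            f"ABR wave I amplitude {abr.wave1_amplitude} <= 0; gain undefined"
        )
    return GainMeasures(
        p1n1_gain=aep.p1n1_amplitude / abr.wave1_amplitude,
        n1p2_gain=aep.n1p2_amplitude / abr.wave1_amplitude,
    )
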