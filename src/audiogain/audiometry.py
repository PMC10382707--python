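"""Per-ear ABR threshold detection and hearing-status classification.

Threshold detection scans an ascending level series of trial-averaged ABR
waveforms: the threshold is the lowest level whose post-stimulus
peak-to-peak amplitude (1-10 ms window) exceeds ``k`` times the
pre-stimulus noise SD AND for which every higher tested level also exceeds
the criterion.  When no level qualifies the ear is recorded as "above max
tested" (sentinel).

Classification pools all wild-type ears to form a normal-hearing cutoff of
mean + 2.5 SD; an ear is impaired iff its threshold strictly exceeds the
cutoff.  Animal-level degree of hearing loss (dB HL) is the maximum
threshold across the animal's ears minus the wild-type mean of that
per-animal maximum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .waveforms import Waveform

__all__ = [
    "ABOVE_MAX",
    "EarAudiogram",
    "HearingStatus",
    "PrevalenceSummary",
    "detect_threshold",
    "pooled_noise_sd",
    "classify_hearing",
    "compute_hl_db",
    "summarize_by_age_window",
    "summarize_prevalence",
]

logger = logging.getLogger(__name__)

#: Sentinel for "no response up to the maximum tested level".
ABOVE_MAX = "above_max_tested"

DEFAULT_RESPONSE_WINDOW_MS = (1.0, 10.0)
DEFAULT_NOISE_MULTIPLE = 4.0
LEVEL_MIN_DB, LEVEL_MAX_DB = 0.0, 90.0


@dataclass
class EarAudiogram:
    """One threshold record for one ear, stimulus and session."""

    animal_id: str
    ear: str  # "left" | "right"
    stimulus: str  # "click" | "tone_8kHz" | "tone_16kHz"
    age_weeks: Optional[float]
    threshold: object  # float dB SPL, or ABOVE_MAX sentinel

    @property
    def is_sentinel(self) -> bool:
        return self.threshold == ABOVE_MAX

    def numeric(self) -> Optional[float]:
        return None if self.is_sentinel else float(self.threshold)


@dataclass
class HearingStatus:
    animal_id: str
    genotype: str
    ear_impaired: dict  # ear -> bool
    category: str  # "normal" | "monaural_HI" | "binaural_HI"
    hl_db: Optional[float]
    partial: bool = False  # only one ear measured
    cutoff_db_spl: Optional[float] = None

    @property
    def impaired(self) -> bool:
        return self.category != "normal"


@dataclass
class PrevalenceSummary:
    group: str
    ear_impaired: int
    ear_measured: int
    animal_impaired: int
    animal_measured: int

    @property
    def ear_percent(self) -> float:
        if self.ear_measured == 0:
            raise ZeroDivisionError("no measured ears")
        return 100.0 * self.ear_impaired / self.ear_measured

    @property
    def animal_percent(self) -> float:
        if self.animal_measured == 0:
            raise ZeroDivisionError("no measured animals")
        return 100.0 * self.animal_impaired / self.animal_measured


def _peak_to_peak(wave: Waveform, window_ms: tuple[float, float]) -> float:
    sel = (wave.t_ms >= window_ms[0]) & (wave.t_ms <= window_ms[1])
    if not np.any(sel):
        raise ValueError("response window contains no samples")
    v = wave.v_uv[sel]
    return float(v.max() - v.min())


def pooled_noise_sd(sweeps) -> float:
    """Noise SD of the trial-averaged trace, estimated from per-trial
    pre-stimulus samples pooled across trials (SD / sqrt(n_trials)).

    Far more stable than the SD of the short averaged pre-stimulus window;
    pass the result to :func:`detect_threshold` via ``noise_sd``.
    """
    pre = sweeps.voltages[:, : sweeps.t0]
    if pre.shape[1] < 8:
        raise ValueError("missing pre-stimulus baseline samples")
    return float(pre.std(ddof=1)) / math.sqrt(sweeps.n_trials)


def _prestim_sd(wave: Waveform) -> float:
    sel = wave.t_ms < 0
    if np.count_nonzero(sel) < 8:
        raise ValueError("missing pre-stimulus baseline samples")
    return float(np.std(wave.v_uv[sel], ddof=1))


def detect_threshold(
    level_series: dict,
    animal_id: str = "",
    ear: str = "",
    stimulus: str = "click",
    age_weeks: Optional[float] = None,
    k: float = DEFAULT_NOISE_MULTIPLE,
    response_window_ms: tuple[float, float] = DEFAULT_RESPONSE_WINDOW_MS,
    noise_sd: Optional[float] = None,
) -> EarAudiogram:
    """Detect the ABR threshold for one ear from an averaged level series.

    Parameters
    ----------
    level_series
        Mapping of stimulus level (dB SPL) to the trial-averaged
        :class:`~audiogain.waveforms.Waveform` for that level.  Each
        waveform must include pre-stimulus baseline samples (t < 0).
    k
        Noise-multiple criterion: a level responds when its post-stimulus
        peak-to-peak amplitude exceeds ``k`` x the noise SD.
    noise_sd
        Optional externally supplied noise SD of the averaged trace.  By
        default it is estimated per level from the pre-stimulus baseline of
        the averaged waveform.

    Returns the lowest level that responds and above which every tested
    level also responds; the sentinel ``ABOVE_MAX`` if no level qualifies.
    """
    levels = sorted(level_series)
    if len(levels) < 3:
        raise ValueError("need >= 3 levels spanning sub- to supra-threshold")
    if len(set(levels)) != len(levels):
        raise ValueError("duplicate levels in series")
    steps = np.diff(levels)
    if not np.allclose(steps, steps[0]):
        raise ValueError("level series must use a common step")

    responds = {}
    for lvl in levels:
        wave = level_series[lvl]
        sd = noise_sd if noise_sd is not None else _prestim_sd(wave)
        responds[lvl] = _peak_to_peak(wave, response_window_ms) > k * sd

    threshold: object = ABOVE_MAX
    for i, lvl in enumerate(levels):
        if all(responds[l] for l in levels[i:]):
            threshold = float(lvl)
            break
    return EarAudiogram(
        animal_id=animal_id,
        ear=ear,
        stimulus=stimulus,
        age_weeks=age_weeks,
        threshold=threshold,
    )


def _wt_ear_thresholds(audiograms: Iterable[EarAudiogram], genotypes: dict) -> list:
    vals = []
    n_sentinel = 0
    for a in audiograms:
        if genotypes.get(a.animal_id) != "WT":
            continue
        if a.is_sentinel:
            n_sentinel += 1
            continue
        vals.append(a.numeric())
    if n_sentinel:
        logger.info("excluded %d sentinel WT ears from cutoff", n_sentinel)
    return vals


def classify_hearing(
    audiograms: Sequence[EarAudiogram],
    genotypes: dict,
    cutoff_sd: float = 2.5,
    stimulus: str = "click",
) -> tuple[dict, float]:
    """Classify every animal's hearing status against the wild-type cutoff.

    The cutoff is ``mean + cutoff_sd * SD`` over all wild-type ear
    thresholds (ears pooled across animals and sexes; sample SD, ddof=1).
    An ear is impaired iff its threshold strictly exceeds the cutoff;
    sentinel ("above max tested") ears count as impaired.  Animals are
    "binaural_HI" (both ears impaired), "monaural_HI" (exactly one) or
    "normal"; one-eared animals are classified on that ear and flagged
    ``partial``.

    Returns ``(statuses, cutoff)`` where ``statuses`` maps animal id to
    :class:`HearingStatus`.
    """
    records = [a for a in audiograms if a.stimulus == stimulus]
    wt_vals = _wt_ear_thresholds(records, genotypes)
    if len(wt_vals) < 2:
        raise ValueError("need >= 2 numeric WT ear thresholds for the cutoff")
    wt = np.asarray(wt_vals, dtype=float)
    cutoff = float(wt.mean() + cutoff_sd * wt.std(ddof=1))

    by_animal: dict = {}
    for a in records:
        by_animal.setdefault(a.animal_id, {})[a.ear] = a

    statuses = {}
    for animal_id in sorted(by_animal):
        ears = by_animal[animal_id]
        flags = {}
        for ear, rec in sorted(ears.items()):
            flags[ear] = rec.is_sentinel or (rec.numeric() > cutoff)
        n_imp = sum(flags.values())
        if n_imp == 0:
            category = "normal"
        elif n_imp == len(flags) and len(flags) >= 2:
            category = "binaural_HI"
        else:
            category = "monaural_HI"
        statuses[animal_id] = HearingStatus(
            animal_id=animal_id,
            genotype=genotypes.get(animal_id, "unknown"),
            ear_impaired=flags,
            category=category,
            hl_db=None,  # filled by compute_hl_db pass below
            partial=len(flags) == 1,
            cutoff_db_spl=cutoff,
        )

    # Attach dB HL relative to the WT mean of per-animal maxima.
    wt_max = _per_animal_max(records, genotypes, which="WT")
    if wt_max:
        ref = float(np.mean(list(wt_max.values())))
        all_max = _per_animal_max(records, genotypes, which=None)
        for animal_id, status in statuses.items():
            if animal_id in all_max:
                status.hl_db = all_max[animal_id] - ref
    return statuses, cutoff


def _threshold_for_hl(a: EarAudiogram) -> float:
    # Sentinel ears enter dB HL at the instrument ceiling (documented).
    return LEVEL_MAX_DB if a.is_sentinel else a.numeric()


def _per_animal_max(
    records: Sequence[EarAudiogram], genotypes: dict, which: Optional[str]
) -> dict:
    out: dict = {}
    for a in records:
        if which is not None and genotypes.get(a.animal_id) != which:
            continue
        v = _threshold_for_hl(a)
        out[a.animal_id] = max(out.get(a.animal_id, -math.inf), v)
    return out


def compute_hl_db(
    ear_thresholds: Sequence[float],
    wt_reference_maxima: Sequence[float],
) -> float:
    """dB HL = max over the animal's ear thresholds - mean over WT animals
    of their per-animal maximum threshold."""
    if len(ear_thresholds) == 0:
        raise ValueError("need >= 1 measured ear")
    if len(wt_reference_maxima) == 0:
        raise ValueError("empty WT reference")
    return float(max(ear_thresholds) - np.mean(wt_reference_maxima))


def summarize_by_age_window(
    audiograms: Sequence[EarAudiogram],
    windows: Sequence[tuple[float, float, bool]] = (
        (3.0, 6.0, False),  # [3, 6) weeks
        (6.0, 14.0, True),  # [6, 14] weeks
    ),
) -> list:
    """Average repeated numeric thresholds per ear within each age window.

    ``windows`` entries are ``(lo, hi, closed_hi)``.  Sentinel thresholds
    are excluded (count logged).  Ears with sessions in more than one
    window are flagged longitudinal.

    Returns a list of dicts: animal, ear, window, mean threshold,
    n_sessions, longitudinal flag.
    """
    n_sentinel = 0
    per_ear_window: dict = {}
    for a in audiograms:
        if a.age_weeks is None:
            raise ValueError("age_weeks missing on an audiogram record")
        if a.is_sentinel:
            n_sentinel += 1
            continue
        for lo, hi, closed_hi in windows:
            inside = (lo <= a.age_weeks < hi) or (closed_hi and a.age_weeks == hi)
            if inside:
                key = (a.animal_id, a.ear, (lo, hi))
                per_ear_window.setdefault(key, []).append(a.numeric())
    if n_sentinel:
        logger.info("excluded %d sentinel thresholds from age-window means", n_sentinel)

    ears_windows: dict = {}
    for (animal, ear, win) in per_ear_window:
        ears_windows.setdefault((animal, ear), set()).add(win)

    out = []
    for (animal, ear, win), vals in sorted(per_ear_window.items()):
        out.append(
            {
                "animal_id": animal,
                "ear": ear,
                "window_weeks": win,
                "mean_threshold_db_spl": float(np.mean(vals)),
                "n_sessions": len(vals),
                "longitudinal": len(ears_windows[(animal, ear)]) > 1,
            }
        )
    return out


def summarize_prevalence(
    statuses: dict,
    group_of: Optional[dict] = None,
) -> dict:
    """Ear- and animal-level impairment percentages per group.

    ``statuses`` maps animal id to :class:`HearingStatus`; grouping defaults
    to each status's genotype.  Returns group -> :class:`PrevalenceSummary`.
    """
    if not statuses:
        raise ValueError("empty cohort")
    summaries: dict = {}
    for animal_id, st in statuses.items():
        group = (group_of or {}).get(animal_id, st.genotype)
        s = summaries.setdefault(
            group,
            PrevalenceSummary(
                group=group, ear_impaired=0, ear_measured=0,
                animal_impaired=0, animal_measured=0,
            ),
        )
        s.ear_measured += len(st.ear_impaired)
        s.ear_impaired += sum(st.ear_impaired.values())
        s.animal_measured += 1
        s.animal_impaired += int(st.impaired)
    return summaries
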