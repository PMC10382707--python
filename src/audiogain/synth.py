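"""Synthetic cohort generator: waveforms, audiograms, and cell maps.

Generates a two-genotype cohort with the statistical structure the
downstream analysis assumes, so every stage is testable without external
data:

* bimodal per-ear thresholds in the mutant group (independent per-ear
  impairment with a configurable left-ear bias for monaural cases);
* ABR/AEP waveforms built from Gaussian component bumps whose amplitudes
  grow linearly with level above the ear's true threshold, with an optional
  multiplicative central-gain factor on the AEP components of impaired
  animals;
* cell maps with homogeneous-Poisson centroids whose PV density declines
  linearly with the animal's true hearing loss while NeuN density is
  genotype-independent.

Everything is driven by a single cohort seed; per-animal/ear/section child
streams are derived with ``numpy.random.SeedSequence`` spawn keys so adding
animals never perturbs existing ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import shapely
from shapely.geometry import LineString, Polygon

from .histology import CellMap
from .waveforms import SweepSet

__all__ = [
    "CohortConfig",
    "WaveformModelParams",
    "GeometrySpec",
    "EarTruth",
    "AnimalTruth",
    "CohortManifest",
    "generate_cohort",
    "synth_sweepset",
    "synth_cellmap",
    "default_geometry",
    "write_manifest",
    "read_manifest",
    "write_sweepset",
    "read_sweepset",
    "write_cellmap",
    "read_cellmap",
]

LEVEL_MIN_DB, LEVEL_MAX_DB = 0.0, 90.0


@dataclass
class CohortConfig:
    """Ground-truth parameters of a synthetic cohort.

    Threshold defaults are calibrated only approximately, to the printed
    group medians (wild-type ~30 dB SPL, mutant ~40 dB SPL); no per-ear raw
    data exist to calibrate against.
    """

    n_wt: int = 25
    n_mut: int = 25
    p_ear_impaired_mut: float = 0.46
    left_bias: float = 0.7
    wt_threshold_mean: float = 32.0
    wt_threshold_sd: float = 3.5
    impaired_shift_mean: float = 25.0
    impaired_shift_sd: float = 12.0
    gain_factor_hi: float = 2.0
    pv_density_wt: float = 400.0
    pv_density_slope_hl: float = -2.0  # cells/mm^2 per dB HL, A1
    pv_density_slope_hl_m2: float = 0.0  # control region: no HL dependence
    neun_density: float = 2000.0
    ages_weeks: tuple = (4.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wt <= 0 or self.n_mut <= 0:
            raise ValueError("cohort sizes must be positive")
        for name in ("p_ear_impaired_mut", "left_bias"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("wt_threshold_sd", "impaired_shift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("pv_density_wt", "neun_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class WaveformModelParams:
    """Gaussian-bump evoked-waveform model.

    Component tuples are ``(center_ms, width_ms, amp_uv)``; ``amp_uv`` is
    the component amplitude at threshold, and amplitudes grow as
    ``1 + growth_per_db * (level - threshold)`` above it (zero below).
    """

    fs_hz: float = 16000.0
    n_trials: int = 32
    noise_sd_uv: float = 0.0
    growth_per_db: float = 0.05
    abr_components: tuple = (
        (1.5, 0.25, 1.0),   # wave I
        (2.5, 0.30, 0.70),  # wave II
        (3.5, 0.30, 0.50),  # wave III
        (4.5, 0.35, 0.45),  # wave IV
        (5.5, 0.40, 0.35),  # wave V
    )
    aep_components: tuple = (
        (20.0, 4.0, 4.0),    # P1
        (40.0, 8.0, -6.0),   # N1
        (80.0, 10.0, 3.0),   # P2
    )
    abr_pre_ms: float = 5.0
    abr_post_ms: float = 12.0
    aep_pre_ms: float = 20.0
    aep_post_ms: float = 120.0

    def __post_init__(self) -> None:
        if self.fs_hz <= 2 * 3000.0:
            raise ValueError("fs must exceed twice the 3 kHz analysis band")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for c, w, _ in self.abr_components + self.aep_components:
            if w <= 0:
                raise ValueError("component widths must be > 0")
        windows = ((15.0, 30.0), (25.0, 60.0), (60.0, 110.0))
        for (c, _, _), (lo, hi) in zip(self.aep_components, windows):
            if not (lo <= c <= hi):
                raise ValueError(
                    f"AEP component centre {c} ms outside its detection "
                    f"window [{lo}, {hi}] ms"
                )


@dataclass
class EarTruth:
    ear: str
    impaired: bool
    threshold_db_spl: float


@dataclass
class AnimalTruth:
    animal_id: str
    genotype: str  # "WT" | "MUT"
    sex: str
    ages_weeks: tuple
    ears: dict  # ear -> EarTruth
    gain_factor: float
    hl_db: float = 0.0
    densities: dict = field(default_factory=dict)  # hemi -> area -> marker -> d


@dataclass
class CohortManifest:
    config: CohortConfig
    animals: list  # of AnimalTruth

    @property
    def wt(self) -> list:
        return [a for a in self.animals if a.genotype == "WT"]

    @property
    def mut(self) -> list:
        return [a for a in self.animals if a.genotype == "MUT"]


def _animal_rng(seed: int, animal_index: int, *stream: int) -> np.random.Generator:
    """Deterministic per-animal (and sub-stream) generator."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(animal_index, *stream))
    return np.random.default_rng(ss)


def _truncnorm(
    rng: np.random.Generator, mean: float, sd: float, lower: float
) -> float:
    if sd == 0:
        return max(mean, lower)
    a = (lower - mean) / sd
    return float(sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def generate_cohort(config: CohortConfig) -> CohortManifest:
    """Draw the full ground-truth manifest for one cohort.

    Every animal has two ears.  Mutant ears are impaired independently with
    ``p_ear_impaired_mut``; for monaural cases the affected side is redrawn
    with probability ``left_bias`` of being the left ear (this reweights
    sides without changing ear- or animal-level impairment counts).
    Unimpaired thresholds are Normal(wt mean, wt sd) truncated at the
    instrument floor; impaired ears add a nonnegative truncated-normal
    shift.  Thresholds are clipped to the tested 0-90 dB SPL range.
    """
    animals: list[AnimalTruth] = []
    idx = 0
    for genotype, n in (("WT", config.n_wt), ("MUT", config.n_mut)):
        for j in range(n):
            rng = _animal_rng(config.seed, idx)
            sex = "M" if rng.random() < 0.5 else "F"
            if genotype == "MUT":
                imp = rng.random(2) < config.p_ear_impaired_mut
                if imp.sum() == 1:
                    left_affected = rng.random() < config.left_bias
                    imp = np.array([left_affected, not left_affected])
            else:
                imp = np.array([False, False])
            ears = {}
            for ear, impaired in zip(("left", "right"), imp):
                thr = _truncnorm(
                    rng, config.wt_threshold_mean, config.wt_threshold_sd,
                    LEVEL_MIN_DB,
                )
                if impaired:
                    thr += _truncnorm(
                        rng, config.impaired_shift_mean,
                        config.impaired_shift_sd, 0.0,
                    )
                ears[ear] = EarTruth(
                    ear=ear,
                    impaired=bool(impaired),
                    threshold_db_spl=float(np.clip(thr, LEVEL_MIN_DB, LEVEL_MAX_DB)),
                )
            gain = config.gain_factor_hi if any(imp) else 1.0
            animals.append(
                AnimalTruth(
                    animal_id=f"{genotype}{j:03d}",
                    genotype=genotype,
                    sex=sex,
                    ages_weeks=tuple(config.ages_weeks),
                    ears=ears,
                    gain_factor=float(gain),
                )
            )
            idx += 1

    # Ground-truth dB HL and per-hemisphere densities.
    def _max_thr(a: AnimalTruth) -> float:
        return max(e.threshold_db_spl for e in a.ears.values())

    wt_ref = float(np.mean([_max_thr(a) for a in animals if a.genotype == "WT"]))
    for a in animals:
        a.hl_db = _max_thr(a) - wt_ref
        pv_a1 = max(0.0, config.pv_density_wt + config.pv_density_slope_hl * a.hl_db)
        pv_m2 = max(
            0.0, config.pv_density_wt + config.pv_density_slope_hl_m2 * a.hl_db
        )
        a.densities = {
            hemi: {
                "A1": {"PV": pv_a1, "NeuN": config.neun_density},
                "M2": {"PV": pv_m2, "NeuN": config.neun_density},
            }
            for hemi in ("left", "right")
        }
    return CohortManifest(config=config, animals=animals)


# ------------------------------------------------------------- waveforms


def _gaussian_template(
    t_ms: np.ndarray, components: Sequence[tuple], scale: float
) -> np.ndarray:
    v = np.zeros_like(t_ms)
    for center, width, amp in components:
        v += amp * scale * np.exp(-0.5 * ((t_ms - center) / width) ** 2)
    return v


def evoked_template(
    level: float,
    threshold: float,
    modality: str,
    params: WaveformModelParams,
    gain_factor: float = 1.0,
) -> tuple[np.ndarray, int]:
    """Deterministic evoked template for one level; returns (trace, t0).

    Zero everywhere below threshold; above (and at) threshold the component
    amplitudes scale by ``1 + growth_per_db * (level - threshold)``.  AEP
    templates are additionally multiplied by ``gain_factor``.
    """
    if modality == "ABR":
        pre, post = params.abr_pre_ms, params.abr_post_ms
        components = params.abr_components
        mult = 1.0
    elif modality == "AEP":
        pre, post = params.aep_pre_ms, params.aep_post_ms
        components = params.aep_components
        mult = gain_factor
    else:
        raise ValueError(f"unknown modality {modality!r}")
    n_pre = int(round(pre * params.fs_hz / 1e3))
    n_post = int(round(post * params.fs_hz / 1e3))
    t_ms = (np.arange(n_pre + n_post) - n_pre) / params.fs_hz * 1e3
    if level < threshold:
        scale = 0.0
    else:
        scale = 1.0 + params.growth_per_db * (level - threshold)
    return mult * _gaussian_template(t_ms, components, scale), n_pre


def synth_sweepset(
    ear_truth: EarTruth,
    level: float,
    modality: str,
    params: WaveformModelParams,
    rng: np.random.Generator,
    gain_factor: float = 1.0,
    animal_id: Optional[str] = None,
    age_weeks: Optional[float] = None,
) -> SweepSet:
    """Simulate one multi-trial recording for an ear at one stimulus level.

    Trials are independent Gaussian-noise realisations around the same
    deterministic evoked template.
    """
    if not (LEVEL_MIN_DB <= level <= LEVEL_MAX_DB):
        raise ValueError(f"level {level} dB SPL outside [0, 90]")
    template, t0 = evoked_template(
        level, ear_truth.threshold_db_spl, modality, params, gain_factor
    )
    noise = rng.normal(0.0, params.noise_sd_uv, size=(params.n_trials, template.size))
    if params.noise_sd_uv == 0:
        noise = np.zeros((params.n_trials, template.size))
    return SweepSet(
        voltages=template[None, :] + noise,
        fs=params.fs_hz,
        t0=t0,
        modality=modality,
        level_db_spl=float(level),
        ear=ear_truth.ear,
        animal_id=animal_id,
        age_weeks=age_weeks,
        stimulus="click",
    )


# -------------------------------------------------------------- cell maps


@dataclass
class GeometrySpec:
    """Region polygon plus pia/wm polylines, coordinates in um."""

    region_xy: tuple
    pia_xy: tuple
    wm_xy: tuple
    section_thickness_um: float = 50.0

    def region(self) -> Polygon:
        return Polygon(self.region_xy)

    def pia(self) -> LineString:
        return LineString(self.pia_xy)

    def wm(self) -> LineString:
        return LineString(self.wm_xy)

    def validate(self) -> None:
        poly = self.region()
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("degenerate region polygon (area <= 0)")
        if self.pia().intersects(self.wm()):
            raise ValueError("pia and wm polylines cross")


def default_geometry(width_um: float = 1000.0, depth_um: float = 900.0) -> GeometrySpec:
    """Rectangular cortical slab: pia along the top edge, wm along the bottom."""
    hw = width_um / 2.0
    return GeometrySpec(
        region_xy=((-hw, -depth_um), (hw, -depth_um), (hw, 0.0), (-hw, 0.0)),
        pia_xy=((-hw - 100.0, 0.0), (hw + 100.0, 0.0)),
        wm_xy=((-hw - 100.0, -depth_um), (hw + 100.0, -depth_um)),
    )


def synth_cellmap(
    pv_density_per_mm2: float,
    neun_density_per_mm2: float,
    geometry: GeometrySpec,
    rng: np.random.Generator,
    animal_id: Optional[str] = None,
    hemisphere: Optional[str] = None,
    area_label: Optional[str] = None,
) -> CellMap:
    """Homogeneous spatial Poisson centroids at the true per-marker density.

    Expected count per marker is ``density x polygon area``; positions are
    uniform over the region polygon (rejection sampling in its bounding
    box).
    """
    geometry.validate()
    region = geometry.region()
    area_mm2 = region.area / 1e6
    minx, miny, maxx, maxy = region.bounds

    def _scatter(density: float) -> np.ndarray:
        n = rng.poisson(density * area_mm2)
        pts = np.empty((0, 2))
        while len(pts) < n:
            m = 2 * (n - len(pts)) + 8
            cand = np.column_stack(
                [
                    rng.uniform(minx, maxx, size=m),
                    rng.uniform(miny, maxy, size=m),
                ]
            )
            keep = shapely.covers(region, shapely.points(cand))
            pts = np.vstack([pts, cand[keep]])
        return pts[:n]

    pv = _scatter(pv_density_per_mm2)
    neun = _scatter(neun_density_per_mm2)
    centroids = np.vstack([pv, neun])
    markers = ["PV"] * len(pv) + ["NeuN"] * len(neun)
    return CellMap(
        centroids=centroids,
        markers=markers,
        region=region,
        pia=geometry.pia(),
        wm=geometry.wm(),
        animal_id=animal_id,
        hemisphere=hemisphere,
        area_label=area_label,
        section_thickness_um=geometry.section_thickness_um,
    )


# -------------------------------------------------------------------- IO


def write_manifest(manifest: CohortManifest, path) -> None:
    payload = {
        "config": asdict(manifest.config),
        "animals": [
            {
                **{
                    k: v
                    for k, v in asdict(a).items()
                    if k not in ("ears",)
                },
                "ears": {e: asdict(t) for e, t in a.ears.items()},
            }
            for a in manifest.animals
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_manifest(path) -> CohortManifest:
    payload = json.loads(Path(path).read_text())
    cfg_d = dict(payload["config"])
    cfg_d["ages_weeks"] = tuple(cfg_d["ages_weeks"])
    config = CohortConfig(**cfg_d)
    animals = []
    for a in payload["animals"]:
        ears = {e: EarTruth(**t) for e, t in a["ears"].items()}
        animals.append(
            AnimalTruth(
                animal_id=a["animal_id"],
                genotype=a["genotype"],
                sex=a["sex"],
                ages_weeks=tuple(a["ages_weeks"]),
                ears=ears,
                gain_factor=a["gain_factor"],
                hl_db=a["hl_db"],
                densities=a["densities"],
            )
        )
    return CohortManifest(config=config, animals=animals)


def write_sweepset(sweeps: SweepSet, csv_path, json_path) -> None:
    """Long-format CSV (trial, sample_index, voltage_uV) + JSON sidecar."""
    n_t, n_s = sweeps.voltages.shape
    df = pd.DataFrame(
        {
            "trial": np.repeat(np.arange(n_t), n_s),
            "sample_index": np.tile(np.arange(n_s), n_t),
            "voltage_uV": sweeps.voltages.ravel(),
        }
    )
    df.to_csv(csv_path, index=False)
    sidecar = {
        "fs_hz": sweeps.fs,
        "t0_sample": sweeps.t0,
        "modality": sweeps.modality,
        "level_db_spl": sweeps.level_db_spl,
        "ear": sweeps.ear,
        "animal_id": sweeps.animal_id,
        "age_weeks": sweeps.age_weeks,
        "stimulus": sweeps.stimulus,
        "n_trials": n_t,
        "n_samples": n_s,
    }
    Path(json_path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_sweepset(csv_path, json_path) -> SweepSet:
    meta = json.loads(Path(json_path).read_text())
    df = pd.read_csv(csv_path)
    volts = (
        df.pivot(index="trial", columns="sample_index", values="voltage_uV")
        .sort_index()
        .to_numpy()
    )
    return SweepSet(
        voltages=volts,
        fs=meta["fs_hz"],
        t0=meta["t0_sample"],
        modality=meta["modality"],
        level_db_spl=meta.get("level_db_spl"),
        ear=meta.get("ear"),
        animal_id=meta.get("animal_id"),
        age_weeks=meta.get("age_weeks"),
        stimulus=meta.get("stimulus", "click"),
    )


def write_cellmap(cellmap: CellMap, csv_path, json_path) -> None:
    df = pd.DataFrame(
        {
            "x_um": cellmap.centroids[:, 0],
            "y_um": cellmap.centroids[:, 1],
            "marker": cellmap.markers,
        }
    )
    df.to_csv(csv_path, index=False)
    geo = {
        "region_xy": [list(p) for p in cellmap.region.exterior.coords[:-1]],
        "pia_xy": [list(p) for p in cellmap.pia.coords],
        "wm_xy": [list(p) for p in cellmap.wm.coords],
        "animal_id": cellmap.animal_id,
        "hemisphere": cellmap.hemisphere,
        "area_label": cellmap.area_label,
        "section_thickness_um": cellmap.section_thickness_um,
        "units": "um",
    }
    Path(json_path).write_text(json.dumps(geo, indent=2, sort_keys=True))


def read_cellmap(csv_path, json_path) -> CellMap:
    geo = json.loads(Path(json_path).read_text())
    df = pd.read_csv(csv_path)
    return CellMap(
        centroids=df[["x_um", "y_um"]].to_numpy(),
        markers=list(df["marker"]),
        region=Polygon([tuple(p) for p in geo["region_xy"]]),
        pia=LineString([tuple(p) for p in geo["pia_xy"]]),
        wm=LineString([tuple(p) for p in geo["wm_xy"]]),
        animal_id=geo.get("animal_id"),
        hemisphere=geo.get("hemisphere"),
        area_label=geo.get("area_label"),
        section_thickness_um=geo.get("section_thickness_um", 50.0),
    )
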