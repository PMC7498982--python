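"""Synthetic cohorts and volumes with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
small severe-TBI cohort (default 14 patients, 21 healthy controls) whose
regional microstructure metrics carry

* a linear age trend per region, shared by patients and controls,
* in patients, a **global damage pattern** (all five regions move
  together) scaled by a per-patient severity score ``g_i``, and
* a **deep-vs-superficial pattern** (CC and BS move opposite to FT, PO,
  BT) scaled by an independent severity score ``d_i``,

with i.i.d. Gaussian measurement noise.  Amnesia duration (PTA, days) is
a linear function of the two severities plus noise, clipped to a
plausible range and rounded to whole days.  Controls have
``g_i = d_i = 0`` and no PTA.

For one metric the patient model is

    x_ir = b_r + s_r·age_i + e_g·g_i·P_r + e_d·d_i·D_r + ε_ir,
    PTA_i = clip(c0 + c1·g_i + c2·d_i + η_i, bounds), rounded,

with unit-norm patterns P (all entries one sign) and D (CC, BS opposite
in sign to FT, PO, BT), and g_i, d_i ~ N(0, 1) independent.

Every random draw comes from one seeded stream in a documented order
(ages, severities, metric noise per metric, PTA noise), so output is
bit-identical for identical (config, seed).  The ground truth (severity
scores, patterns, noiseless means and PTA) is returned alongside the
tables for recovery tests.

A second generator paints small labeled block volumes with known regional
values and planted spherical lesions, returning the analytically computed
regional means before and after lesion exclusion (and after erosion and
FA-thresholding) so volumetric extraction can be checked exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import DEEP_REGIONS, REGION_LABELS, REGIONS, WM_REGIONS
from .roi import VolumeSet

__all__ = [
    "MetricParams",
    "CohortConfig",
    "SyntheticGroundTruth",
    "VolumeConfig",
    "generate_cohort",
    "generate_volume_set",
    "write_cohort",
    "default_cohort_config",
    "default_volume_config",
]

_SQRT5 = np.sqrt(5.0)

#: Unit-norm global pattern: all regions move together.
GLOBAL_PATTERN = tuple(1.0 / _SQRT5 for _ in REGIONS)

#: Unit-norm deep-vs-superficial pattern: CC, BS opposite to FT, PO, BT.
DEEP_PATTERN = tuple(
    (-1.0 if r in DEEP_REGIONS else 1.0) / _SQRT5 for r in REGIONS
)


@dataclass(frozen=True)
class MetricParams:
    """Generative parameters for one metric, in that metric's units.

    ``effect_global`` / ``effect_deep`` are metric units per SD of the
    corresponding severity score; their signs encode the damage
    direction (e.g. negative global effect for FA, positive for MD).
    """

    region_baselines: tuple  # per region, REGIONS order
    age_slopes: tuple  # metric units per year, per region
    effect_global: float
    effect_deep: float
    noise_sd: float

    def __post_init__(self):
        for name in ("region_baselines", "age_slopes"):
            v = getattr(self, name)
            if len(v) != len(REGIONS):
                raise ValueError(f"{name} must have {len(REGIONS)} entries")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _default_metrics() -> dict[str, MetricParams]:
    """Defaults chosen so the planted patterns are recoverable at n = 14.

    FA is unitless; MD is in 10⁻³ mm²/s; microbleed count and volume (µL)
    are continuous damage scores.  Damage lowers FA and raises the rest;
    the deep effect is roughly half the global effect, with the sign that
    puts the larger change in CC/BS.
    """
    return {
        "FA": MetricParams(
            region_baselines=(0.45, 0.44, 0.55, 0.50, 0.30),
            age_slopes=(-0.0008,) * 5,
            effect_global=-0.040,
            effect_deep=0.025,
            noise_sd=0.010,
        ),
        "MD": MetricParams(
            region_baselines=(0.72, 0.74, 0.78, 0.80, 0.75),
            age_slopes=(0.0015,) * 5,
            effect_global=0.045,
            effect_deep=-0.028,
            noise_sd=0.015,
        ),
        "MB_count": MetricParams(
            region_baselines=(2.0, 1.5, 1.0, 0.8, 0.8),
            age_slopes=(0.0,) * 5,
            effect_global=2.0,
            effect_deep=-1.0,
            noise_sd=0.8,
        ),
        "MB_volume": MetricParams(
            region_baselines=(40.0, 30.0, 20.0, 15.0, 15.0),
            age_slopes=(0.0,) * 5,
            effect_global=30.0,
            effect_deep=-15.0,
            noise_sd=12.0,
        ),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generative configuration.

    Defaults reproduce the study conditions: 14 patients and 21 controls,
    ages uniform on 18–77 years, PTA centred near 190 days with the two
    severity scores contributing 80 and 60 days per SD.
    """

    n_patients: int = 14
    n_controls: int = 21
    age_range: tuple = (18.0, 77.0)
    metrics: Mapping[str, MetricParams] = field(default_factory=_default_metrics)
    global_pattern: tuple = GLOBAL_PATTERN
    deep_pattern: tuple = DEEP_PATTERN
    pta_coefs: tuple = (190.0, 80.0, 60.0)  # intercept, days/SD global, days/SD deep
    pta_noise_sd: float = 40.0
    pta_bounds: tuple = (0.0, 450.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 5:
            raise ValueError(
                f"invariant violated: n_patients >= 5 (got {self.n_patients})"
            )
        if self.n_controls < 5:
            raise ValueError(
                f"invariant violated: n_controls >= 5 (got {self.n_controls})"
            )
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("invariant violated: age_range must be (min, max)")
        g = np.asarray(self.global_pattern, dtype=float)
        d = np.asarray(self.deep_pattern, dtype=float)
        for name, v in (("global_pattern", g), ("deep_pattern", d)):
            if v.shape != (len(REGIONS),):
                raise ValueError(f"invariant violated: {name} must be a 5-vector")
            if abs(np.linalg.norm(v) - 1.0) > 1e-8:
                raise ValueError(f"invariant violated: {name} must have unit norm")
        if not (np.all(g > 0) or np.all(g < 0)):
            raise ValueError(
                "invariant violated: global_pattern entries must all share one sign"
            )
        deep_idx = [i for i, r in enumerate(REGIONS) if r in DEEP_REGIONS]
        sup_idx = [i for i, r in enumerate(REGIONS) if r not in DEEP_REGIONS]
        if not (
            (np.all(d[deep_idx] < 0) and np.all(d[sup_idx] > 0))
            or (np.all(d[deep_idx] > 0) and np.all(d[sup_idx] < 0))
        ):
            raise ValueError(
                "invariant violated: deep_pattern must have CC and BS opposite "
                "in sign to FT, PO, BT"
            )
        if len(self.pta_coefs) != 3:
            raise ValueError("pta_coefs must be (intercept, per-SD global, per-SD deep)")
        if self.pta_noise_sd < 0:
            raise ValueError("pta_noise_sd must be >= 0")
        if not self.pta_bounds[0] < self.pta_bounds[1]:
            raise ValueError("pta_bounds must be (min, max)")
        for name, mp in self.metrics.items():
            if not isinstance(mp, MetricParams):
                raise ValueError(f"metrics[{name!r}] must be a MetricParams")

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=int(seed))


def default_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    """The default study conditions, optionally overridden field-by-field."""
    return replace(CohortConfig(seed=int(seed)), **overrides)


@dataclass
class SyntheticGroundTruth:
    """Everything needed to verify recovery of the planted structure."""

    subject_ids: list
    patient_ids: list
    ages: np.ndarray  # all subjects, patients first
    g: np.ndarray  # per-patient global severity, SD units
    d: np.ndarray  # per-patient deep severity, SD units
    global_pattern: np.ndarray
    deep_pattern: np.ndarray
    noiseless_means: dict  # metric -> DataFrame (subjects × regions)
    noiseless_pta: np.ndarray  # per patient, clipped, unrounded
    seed: int

    def recompute_noiseless_means(self, config: CohortConfig) -> dict:
        """Regenerate the noiseless regional means from the stored scores.

        Used by closure tests: the result must equal ``noiseless_means``
        exactly, because both paths evaluate the same generative formula
        on the same stored ages and severities.
        """
        return _noiseless_means(
            config,
            self.subject_ids,
            self.patient_ids,
            self.ages,
            self.g,
            self.d,
        )

    def to_dict(self) -> dict:
        return {
            "seed": int(self.seed),
            "subject_ids": list(self.subject_ids),
            "patient_ids": list(self.patient_ids),
            "ages": self.ages.tolist(),
            "g": self.g.tolist(),
            "d": self.d.tolist(),
            "global_pattern": self.global_pattern.tolist(),
            "deep_pattern": self.deep_pattern.tolist(),
            "noiseless_pta": self.noiseless_pta.tolist(),
            "noiseless_means": {
                m: df.to_dict(orient="split") for m, df in self.noiseless_means.items()
            },
        }


def _noiseless_means(config, subject_ids, patient_ids, ages, g, d):
    P = np.asarray(config.global_pattern, dtype=float)
    D = np.asarray(config.deep_pattern, dtype=float)
    n_pat = len(patient_ids)
    is_patient = np.zeros(len(subject_ids), dtype=bool)
    is_patient[:n_pat] = True
    out = {}
    for name, mp in config.metrics.items():
        base = np.asarray(mp.region_baselines, dtype=float)
        slope = np.asarray(mp.age_slopes, dtype=float)
        vals = base[None, :] + np.outer(ages, slope)
        vals[:n_pat] += mp.effect_global * np.outer(g, P)
        vals[:n_pat] += mp.effect_deep * np.outer(d, D)
        out[name] = pd.DataFrame(vals, index=list(subject_ids), columns=list(REGIONS))
    return out


def generate_cohort(config: CohortConfig):
    """Generate one synthetic cohort.

    Returns
    -------
    subjects : DataFrame
        Columns ``subject_id, group, age, pta_days`` (PTA missing for
        controls); patients first.
    metric_tables : dict of metric name -> wide DataFrame
        Subjects × regions regional means, indexed by subject id.
    truth : SyntheticGroundTruth

    Notes
    -----
    Draw order from the single seeded stream: ages (all subjects),
    severities (g then d, patients only), metric noise in the order the
    metrics appear in the config, PTA noise.  This makes output
    reproducible independent of any internal loop order.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_pat, n_con = config.n_patients, config.n_controls
    n = n_pat + n_con
    patient_ids = [f"P{i + 1:02d}" for i in range(n_pat)]
    control_ids = [f"C{i + 1:02d}" for i in range(n_con)]
    subject_ids = patient_ids + control_ids

    ages = rng.uniform(config.age_range[0], config.age_range[1], size=n)
    g = rng.standard_normal(n_pat)
    d = rng.standard_normal(n_pat)

    clean = _noiseless_means(config, subject_ids, patient_ids, ages, g, d)
    metric_tables = {}
    for name, mp in config.metrics.items():
        noise = rng.normal(0.0, mp.noise_sd, size=(n, len(REGIONS)))
        metric_tables[name] = clean[name] + noise

    c0, c1, c2 = config.pta_coefs
    pta_clean = np.clip(c0 + c1 * g + c2 * d, *config.pta_bounds)
    pta_noise = rng.normal(0.0, config.pta_noise_sd, size=n_pat)
    pta = np.round(np.clip(c0 + c1 * g + c2 * d + pta_noise, *config.pta_bounds))

    subjects = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "group": ["patient"] * n_pat + ["control"] * n_con,
            "age": ages,
            "pta_days": list(pta) + [np.nan] * n_con,
        }
    )
    truth = SyntheticGroundTruth(
        subject_ids=subject_ids,
        patient_ids=patient_ids,
        ages=ages,
        g=g,
        d=d,
        global_pattern=np.asarray(config.global_pattern, dtype=float),
        deep_pattern=np.asarray(config.deep_pattern, dtype=float),
        noiseless_means=clean,
        noiseless_pta=pta_clean,
        seed=config.seed,
    )
    return subjects, metric_tables, truth


def write_cohort(subjects, metric_tables, truth, out_dir) -> dict[str, Path]:
    """Write a generated cohort as CSV (+ JSON ground truth); returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    p = out_dir / "subjects.csv"
    subjects.to_csv(p, index=False)
    paths["subjects"] = p
    for name, table in metric_tables.items():
        p = out_dir / f"metrics_{name}.csv"
        table.to_csv(p, index_label="subject_id")
        paths[f"metrics_{name}"] = p
    p = out_dir / "ground_truth.json"
    p.write_text(json.dumps(truth.to_dict(), indent=2))
    paths["ground_truth"] = p
    return paths


# ---------------------------------------------------------------------------
# Volumes


def _default_layout() -> dict[str, tuple]:
    """Five disjoint 5×8×8 blocks along the x axis of a 32×12×12 grid."""
    return {
        r: ((1 + 6 * i, 6 + 6 * i), (2, 10), (2, 10))
        for i, r in enumerate(REGIONS)
    }


@dataclass(frozen=True)
class VolumeConfig:
    """Configuration for painted block volumes with planted lesions.

    ``region_layout`` maps region -> ((x0, x1), (y0, y1), (z0, z1)) with
    exclusive upper bounds; blocks must be pairwise disjoint and at least
    3 voxels thick per axis so they survive 1-voxel erosion.
    ``lesion_spheres`` are (center voxel, radius in voxels); a voxel
    belongs to a sphere if its index lies within the radius of the center
    (Euclidean, voxel units).  Lesion voxels are painted with
    ``lesion_values`` so exclusion visibly changes a region's mean.
    """

    grid_shape: tuple = (32, 12, 12)
    voxel_size: tuple = (1.0, 1.0, 1.0)
    region_layout: Mapping[str, tuple] = field(default_factory=_default_layout)
    region_values: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "FA": {"FT": 0.45, "PO": 0.44, "CC": 0.55, "BS": 0.50, "BT": 0.35},
            "MD": {"FT": 0.72, "PO": 0.74, "CC": 0.78, "BS": 0.80, "BT": 0.75},
        }
    )
    background_values: Mapping[str, float] = field(
        default_factory=lambda: {"FA": 0.05, "MD": 0.30}
    )
    lesion_values: Mapping[str, float] = field(
        default_factory=lambda: {"FA": 0.95, "MD": 2.50}
    )
    value_noise_sd: float = 0.0
    lesion_spheres: Sequence[tuple] = ()
    fa_threshold: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        shape = tuple(int(s) for s in self.grid_shape)
        if len(shape) != 3 or min(shape) < 3:
            raise ValueError("grid_shape must be 3-D with every axis >= 3")
        if set(self.region_layout) != set(REGIONS):
            raise ValueError(f"region_layout must cover exactly {REGIONS}")
        seen = np.zeros(shape, dtype=bool)
        for region, bounds in self.region_layout.items():
            sl = tuple(slice(lo, hi) for lo, hi in bounds)
            for (lo, hi), size in zip(bounds, shape):
                if not (0 <= lo < hi <= size):
                    raise ValueError(
                        f"invariant violated: block for {region} exceeds the grid"
                    )
                if hi - lo < 3:
                    raise ValueError(
                        f"invariant violated: block for {region} is thinner than "
                        "3 voxels and would not survive 1-voxel erosion"
                    )
            if seen[sl].any():
                raise ValueError(
                    f"invariant violated: block for {region} overlaps another block"
                )
            seen[sl] = True
        for center, radius in self.lesion_spheres:
            if radius <= 0:
                raise ValueError("lesion radius must be > 0")
            for c, size in zip(center, shape):
                if c - radius < 0 or c + radius > size - 1:
                    raise ValueError(
                        "invariant violated: lesion sphere must lie inside the grid"
                    )
        for name in self.region_values:
            if name not in self.background_values or name not in self.lesion_values:
                raise ValueError(
                    f"metric {name!r} needs background and lesion values too"
                )


def default_volume_config(seed: int = 0, **overrides) -> VolumeConfig:
    return replace(VolumeConfig(seed=int(seed)), **overrides)


def _sphere_mask(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    dist2 = sum((gr - c) ** 2 for gr, c in zip(grids, center))
    return dist2 <= radius**2


def generate_volume_set(config: VolumeConfig):
    """Paint a labeled block volume set and compute its true regional means.

    Returns
    -------
    volumes : VolumeSet
    truth : DataFrame
        One row per (region, metric) with the mean over the region's
        *eroded* block (inner cuboid, computed analytically by shrinking
        the block bounds — no morphology code involved), with the strict
        FA threshold applied to WM regions, before (``mean_pre``,
        ``n_pre``) and after (``mean_post``, ``n_post``) removal of
        lesion-sphere voxels.  Empty selections yield NaN means and zero
        counts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = tuple(int(s) for s in config.grid_shape)

    labels = np.zeros(shape, dtype=np.int16)
    for region, bounds in config.region_layout.items():
        sl = tuple(slice(lo, hi) for lo, hi in bounds)
        labels[sl] = REGION_LABELS[region]

    exclusion = np.zeros(shape, dtype=bool)
    for center, radius in config.lesion_spheres:
        exclusion |= _sphere_mask(shape, center, radius)

    metric_volumes = {}
    for name, values in config.region_values.items():
        vol = np.full(shape, float(config.background_values[name]))
        for region, bounds in config.region_layout.items():
            sl = tuple(slice(lo, hi) for lo, hi in bounds)
            vol[sl] = float(values[region])
        if config.value_noise_sd > 0:
            vol = vol + rng.normal(0.0, config.value_noise_sd, size=shape)
            if name == "FA":
                vol = np.clip(vol, 0.0, 1.0)
        vol[exclusion] = float(config.lesion_values[name])
        if name == "FA":
            vol = np.clip(vol, 0.0, 1.0)
        metric_volumes[name] = vol

    volumes = VolumeSet(
        label_volume=labels,
        metric_volumes=metric_volumes,
        exclusion_mask=exclusion,
        voxel_size=config.voxel_size,
    )

    fa = metric_volumes.get("FA")
    rows = []
    for region, bounds in config.region_layout.items():
        inner = tuple(slice(lo + 1, hi - 1) for lo, hi in bounds)
        eroded = np.zeros(shape, dtype=bool)
        eroded[inner] = True
        for name, vol in metric_volumes.items():
            sel = eroded.copy()
            if region in WM_REGIONS and fa is not None:
                sel &= fa > config.fa_threshold
            pre = vol[sel]
            post = vol[sel & ~exclusion]
            rows.append(
                {
                    "region": region,
                    "metric": name,
                    "mean_pre": float(pre.mean()) if pre.size else np.nan,
                    "n_pre": int(pre.size),
                    "mean_post": float(post.mean()) if post.size else np.nan,
                    "n_post": int(post.size),
                }
            )
    truth = pd.DataFrame(
        rows, columns=["region", "metric", "mean_pre", "n_pre", "mean_post", "n_post"]
    )
    return volumes, truth
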