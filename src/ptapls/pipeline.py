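"""End-to-end orchestration: adjust → standardize → PLS → inference.

:func:`run_analysis` takes a subject table and per-metric regional
tables, applies healthy-control age adjustment to the DTI metrics
(microbleed metrics are standardized only), fits the full-cohort PLS1
model per metric set, tests component–outcome associations at the
Bonferroni-corrected threshold, and validates out-of-sample prediction
with leave-one-out cross-validation against a permutation null.

Combined metric sets (FA plus one companion) concatenate the two
age-adjusted 5-region blocks into a 10-predictor matrix, FA columns
first.

A subject with missing amnesia duration (the study's deceased patient)
has the outcome imputed to a configurable constant, 400 days by default,
before any analysis; the imputation is recorded in provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__ as _pkg_version
from .adjustment import apply_age_adjustment, fit_age_trends, zscore_columns
from .inference import (
    correlate_components,
    permutation_test,
    spearman_corr,
)
from .pls import fit_pls1, select_n_components
from .regions import REGIONS

logger = logging.getLogger("ptapls")

__all__ = [
    "AnalysisConfig",
    "MetricSetResult",
    "run_analysis",
    "summarize_clinical",
    "clinical_outcome_correlations",
    "regional_table_to_wide",
]

#: Metrics that receive healthy-control age adjustment.
AGE_ADJUSTED_METRICS = ("FA", "MD")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the full analysis, with the study defaults."""

    metric_sets: tuple = (("FA",), ("FA", "MD"), ("FA", "MB_volume"), ("FA", "MB_count"))
    fa_threshold: float = 0.3
    erosion: bool = True
    n_components: int = 3
    variance_threshold: float = 80.0
    alpha: float = 0.05
    n_comparisons: int = 3
    n_permutations: int = 10_000
    impute_pta_days: float = 400.0
    adjustment_method: str = "center"
    seed: int = 0

    @property
    def alpha_corrected(self) -> float:
        """Bonferroni-corrected threshold, rounded to 3 decimals (0.017)."""
        return round(self.alpha / self.n_comparisons, 3)

    def validate(self) -> None:
        for ms in self.metric_sets:
            if len(ms) == 2 and ms[0] != "FA":
                raise ValueError(
                    f"combined metric set {ms} must pair FA with one companion"
                )
            if len(ms) > 2:
                raise ValueError(f"metric set {ms} has more than two metrics")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")

    def hash(self) -> str:
        """Stable hash of the configuration, recorded in every output."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class MetricSetResult:
    """Everything computed for one metric set (e.g. FA, or FA+MB_count)."""

    metrics: tuple
    fit: object  # PLSFit on the full patient cohort
    associations: list
    loocv: object  # LOOCVResult
    feature_names: tuple
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "metrics": list(self.metrics),
            "feature_names": list(self.feature_names),
            "fit": self.fit.to_dict(),
            "associations": [asdict(a) for a in self.associations],
            "loocv": self.loocv.to_dict(),
            "provenance": self.provenance,
        }


def regional_table_to_wide(long_table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Pivot a long extraction table (subject,region,metric,mean,...) to wide."""
    sub = long_table[long_table["metric"] == metric]
    wide = sub.pivot(index="subject", columns="region", values="mean")
    return wide.reindex(columns=list(REGIONS))


def _prepare_patient_predictors(subjects, metric_tables, config):
    """Split groups, impute missing PTA, age-adjust the DTI metrics."""
    patients = subjects[subjects["group"] == "patient"].set_index("subject_id")
    controls = subjects[subjects["group"] == "control"].set_index("subject_id")
    if len(patients) == 0:
        raise ValueError("no patients in the subject table")

    pta = patients["pta_days"].copy()
    imputed = pta[pta.isna()].index.tolist()
    if imputed:
        logger.info("imputing PTA=%s days for subjects %s", config.impute_pta_days, imputed)
        pta = pta.fillna(config.impute_pta_days)

    needed_adjust = [
        m for m in metric_tables if m in AGE_ADJUSTED_METRICS
    ]
    trends = {}
    if needed_adjust:
        if len(controls) == 0:
            raise ValueError("age adjustment requires healthy controls")
        trends = fit_age_trends(
            {m: metric_tables[m].loc[controls.index] for m in needed_adjust},
            controls["age"],
        )
    adjusted: dict[str, pd.DataFrame] = {}
    for m, table in metric_tables.items():
        pat_block = table.loc[patients.index]
        if m in AGE_ADJUSTED_METRICS:
            adjusted[m] = apply_age_adjustment(
                {m: pat_block}, patients["age"], trends, method=config.adjustment_method
            )[m]
        else:
            adjusted[m] = pat_block.copy()
    return patients, pta, adjusted, trends, imputed


def _assemble_x(adjusted: Mapping[str, pd.DataFrame], metric_set: Sequence[str]):
    blocks, names = [], []
    for m in metric_set:
        if m not in adjusted:
            raise KeyError(f"metric {m!r} not among the supplied tables")
        blocks.append(adjusted[m])
        names.extend(f"{m}_{r}" for r in REGIONS)
    X = pd.concat(blocks, axis=1)
    X.columns = names
    return X


def run_analysis(
    subjects: pd.DataFrame,
    metric_tables: Mapping[str, pd.DataFrame],
    config: AnalysisConfig = AnalysisConfig(),
) -> dict:
    """Run the full analysis for every configured metric set.

    Parameters
    ----------
    subjects
        Columns ``subject_id, group, age, pta_days``.
    metric_tables
        Metric name -> wide regional-means table indexed by subject id
        (patients and controls).
    config
        See :class:`AnalysisConfig`.

    Returns
    -------
    dict with one :class:`MetricSetResult` per metric set (keyed by
    ``"+".join(metrics)``) plus a ``"provenance"`` entry.
    """
    config.validate()
    patients, pta, adjusted, trends, imputed = _prepare_patient_predictors(
        subjects, metric_tables, config
    )
    provenance = {
        "version": _pkg_version,
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_patients": int(len(patients)),
        "imputed_pta_subjects": imputed,
        "impute_pta_days": config.impute_pta_days,
        "adjustment_method": config.adjustment_method,
        "one_tailed_direction": "positive after the loading sign convention",
    }
    y_days = pta.to_numpy(dtype=float)

    results: dict[str, object] = {"provenance": provenance}
    for metric_set in config.metric_sets:
        key = "+".join(metric_set)
        Xdf = _assemble_x(adjusted, metric_set)
        logger.info("metric set %s: X shape %s", key, Xdf.shape)
        Xz, x_mean, x_sd = zscore_columns(Xdf)
        y_z = (y_days - y_days.mean()) / y_days.std(ddof=1)
        fit = fit_pls1(
            Xz.to_numpy(),
            y_z,
            config.n_components,
            feature_names=tuple(Xdf.columns),
            x_mean=x_mean.to_numpy(),
            x_sd=x_sd.to_numpy(),
            y_mean=float(y_days.mean()),
            y_sd=float(y_days.std(ddof=1)),
        )
        associations = correlate_components(
            fit,
            y_days,
            alpha_corrected=config.alpha_corrected,
            n_components=min(config.n_components, fit.n_components),
        )
        loocv = permutation_test(
            Xdf.to_numpy(),
            y_days,
            n_components=config.n_components,
            B=config.n_permutations,
            seed=config.seed,
        )
        results[key] = MetricSetResult(
            metrics=tuple(metric_set),
            fit=fit,
            associations=associations,
            loocv=loocv,
            feature_names=tuple(Xdf.columns),
            provenance=provenance,
        )
    return results


def component_count_report(
    subjects: pd.DataFrame,
    metric_tables: Mapping[str, pd.DataFrame],
    config: AnalysisConfig = AnalysisConfig(),
) -> dict:
    """Cumulative predictor-variance per single metric and the selected count.

    Fits a full-rank PLS1 per metric and applies the strict
    ``variance_threshold`` exceedance rule across all of them.
    """
    patients, pta, adjusted, _, _ = _prepare_patient_predictors(
        subjects, metric_tables, config
    )
    y_days = pta.to_numpy(dtype=float)
    y_z = (y_days - y_days.mean()) / y_days.std(ddof=1)
    tables = {}
    for m, block in adjusted.items():
        Xz, _, _ = zscore_columns(block)
        full = fit_pls1(Xz.to_numpy(), y_z, len(REGIONS))
        tables[m] = full.pct_var_x
    return {
        "pct_var_x": {m: v.tolist() for m, v in tables.items()},
        "selected_n_components": select_n_components(tables, config.variance_threshold),
    }


def summarize_clinical(table: pd.DataFrame) -> pd.DataFrame:
    """Per-variable cohort summary: mean (SD), median, range, n.

    Missing values are excluded pairwise.  Mean and SD are rounded to
    integers, matching how such cohort tables are conventionally printed;
    SD is reported as missing when fewer than two values remain.
    """
    if table is None or len(table) == 0:
        raise ValueError("cannot summarize an empty table")
    num = table.select_dtypes(include=[np.number])
    if num.shape[1] == 0:
        raise ValueError("no numeric columns to summarize")
    rows = []
    for col in num.columns:
        vals = num[col].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            continue
        rows.append(
            {
                "variable": col,
                "n": int(vals.size),
                "mean": int(round(vals.mean())),
                "sd": int(round(vals.std(ddof=1))) if vals.size > 1 else pd.NA,
                "median": float(np.median(vals)),
                "min": float(vals.min()),
                "max": float(vals.max()),
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def clinical_outcome_correlations(
    table: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    age_column: str = "age",
) -> pd.DataFrame:
    """Spearman correlation of clinical covariates with the outcome,
    corrected for age by rank residualization.

    Both variables are rank-transformed, residualized on the ranks of
    age by least squares, and the residuals correlated (a partial
    Spearman correlation).  Two-sided p-values from the t-approximation.
    This is a descriptive report; the exact age-correction convention is
    recorded here rather than inferred from any external source.
    """
    rows = []
    for cov in covariates:
        sub = table[[cov, outcome, age_column]].dropna()
        if len(sub) < 5:
            raise ValueError(f"need >= 5 complete cases for {cov!r}, got {len(sub)}")
        ranks = {c: stats.rankdata(sub[c]) for c in (cov, outcome, age_column)}
        age_r = ranks[age_column]
        A = np.column_stack([np.ones_like(age_r), age_r])

        def _resid(v):
            beta, *_ = np.linalg.lstsq(A, v, rcond=None)
            return v - A @ beta

        rx, ry = _resid(ranks[cov]), _resid(ranks[outcome])
        n = len(sub)
        rho = float(np.corrcoef(rx, ry)[0, 1])
        t = rho * np.sqrt((n - 3) / max(1e-12, 1.0 - rho * rho))
        p = float(2 * stats.t.sf(abs(t), df=n - 3))
        rows.append({"covariate": cov, "rho": rho, "p_value": p, "n": n})
    return pd.DataFrame(rows).set_index("covariate")
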