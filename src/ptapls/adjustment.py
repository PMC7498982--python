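"""Age adjustment against healthy-control trends, and standardization.

Regional FA falls and MD rises slowly with healthy ageing, so patient
values are adjusted before pattern analysis: a straight line of metric on
age is fit per (region, metric) in the healthy-control group, and the
control-derived slope is removed from each patient value:

    adjusted = observed − slope · (age − reference_age)

where ``reference_age`` is the control group's mean age.  Slope-only
centering keeps patient values on their native scale; full
residualization against the control line (subtracting intercept + slope·age)
is available via ``method="residualize"`` — the two differ by a constant
per column and are therefore interchangeable after z-scoring.

Microbleed count and volume carry no comparable normative ageing trend and
are standardized only, never age-adjusted.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .regions import REGIONS

__all__ = [
    "AgeTrend",
    "fit_age_trends",
    "apply_age_adjustment",
    "zscore_columns",
    "trends_to_json",
    "trends_from_json",
]


@dataclass(frozen=True)
class AgeTrend:
    """Linear metric-on-age trend for one (region, metric) in controls."""

    region: str
    metric: str
    slope: float  # metric units per year
    intercept: float  # metric units at age 0
    reference_age: float  # control mean age, years
    n_controls: int

    def value_at(self, age) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(age, dtype=float)


def fit_age_trends(
    control_tables: Mapping[str, pd.DataFrame],
    control_ages: pd.Series,
) -> dict[tuple[str, str], AgeTrend]:
    """Ordinary least-squares line of metric on age per (region, metric).

    Parameters
    ----------
    control_tables
        Mapping metric name -> wide table (control subjects × region
        columns) of healthy-control regional means.
    control_ages
        Ages in years, indexed like the tables' rows.

    Returns
    -------
    dict keyed by ``(region, metric)``.

    Raises
    ------
    ValueError
        Fewer than 3 finite control values for some (region, metric), or
        degenerate (all-equal) ages.
    """
    trends: dict[tuple[str, str], AgeTrend] = {}
    for metric, table in control_tables.items():
        missing = [r for r in REGIONS if r not in table.columns]
        if missing:
            raise ValueError(f"{metric} control table lacks region columns {missing}")
        ages_all = control_ages.loc[table.index].to_numpy(dtype=float)
        for region in REGIONS:
            vals = table[region].to_numpy(dtype=float)
            ok = np.isfinite(vals) & np.isfinite(ages_all)
            if ok.sum() < 3:
                raise ValueError(
                    f"need >= 3 finite control values for ({region}, {metric}), "
                    f"got {int(ok.sum())}"
                )
            ages = ages_all[ok]
            if np.ptp(ages) == 0:
                raise ValueError(
                    f"control ages are all equal ({ages[0]}); cannot fit an "
                    f"age trend for ({region}, {metric})"
                )
            res = stats.linregress(ages, vals[ok])
            trends[(region, metric)] = AgeTrend(
                region=region,
                metric=metric,
                slope=float(res.slope),
                intercept=float(res.intercept),
                reference_age=float(ages.mean()),
                n_controls=int(ok.sum()),
            )
    return trends


def apply_age_adjustment(
    patient_tables: Mapping[str, pd.DataFrame],
    patient_ages: pd.Series,
    trends: Mapping[tuple[str, str], AgeTrend],
    method: str = "center",
) -> dict[str, pd.DataFrame]:
    """Remove the control-derived age trend from patient regional values.

    ``method="center"`` (default) subtracts ``slope · (age − reference_age)``;
    ``method="residualize"`` subtracts the full control line
    ``intercept + slope · age``.  Only the tables passed in are adjusted —
    callers decide which metrics receive adjustment.

    Raises
    ------
    KeyError
        A (region, metric) present in the tables has no fitted trend.
    """
    if method not in ("center", "residualize"):
        raise ValueError(f"unknown adjustment method {method!r}")
    adjusted: dict[str, pd.DataFrame] = {}
    for metric, table in patient_tables.items():
        out = table.copy()
        ages = patient_ages.loc[table.index].to_numpy(dtype=float)
        for region in table.columns:
            key = (region, metric)
            if key not in trends:
                raise KeyError(
                    f"no age trend fitted for (region={region}, metric={metric})"
                )
            tr = trends[key]
            if method == "center":
                out[region] = table[region] - tr.slope * (ages - tr.reference_age)
            else:
                out[region] = table[region] - tr.value_at(ages)
        adjusted[metric] = out
    return adjusted


def zscore_columns(table: pd.DataFrame):
    """Standardize each column to mean 0, sample SD 1 (n−1 denominator).

    Returns ``(standardized table, means, sds)``; the constants are
    returned so held-out rows can be placed on the same scale.

    Raises
    ------
    ValueError
        Naming the first zero-variance column encountered.
    """
    means = table.mean()
    sds = table.std(ddof=1)
    bad = sds[(sds == 0) | ~np.isfinite(sds)]
    if len(bad):
        raise ValueError(
            f"column {bad.index[0]!r} has zero (or undefined) variance; "
            "cannot z-score"
        )
    return (table - means) / sds, means, sds


def trends_to_json(trends: Mapping[tuple[str, str], AgeTrend]) -> str:
    return json.dumps([asdict(t) for t in trends.values()], indent=2)


def trends_from_json(text: str) -> dict[tuple[str, str], AgeTrend]:
    return {
        (d["region"], d["metric"]): AgeTrend(**d) for d in json.loads(text)
    }
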