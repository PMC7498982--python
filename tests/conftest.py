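import numpy as np
import pandas as pd
import pytest

from ptapls import (
    default_cohort_config,
    default_volume_config,
    generate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


def standardized_instance(rng, n=14, p=5):
    """Random standardized (X, y) as used throughout the PLS tests."""
    X = rng.standard_normal((n, p))
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    y = rng.standard_normal(n)
    y = (y - y.mean()) / y.std(ddof=1)
    return X, y


@pytest.fixture
def default_cohort():
    cfg = default_cohort_config(seed=7)
    subjects, tables, truth = generate_cohort(cfg)
    return cfg, subjects, tables, truth


@pytest.fixture
def quiet_cohort_config():
    """All variation switched off: no noise, no effects, no age slopes."""
    cfg = default_cohort_config(seed=3)
    metrics = {
        name: mp.__class__(
            region_baselines=mp.region_baselines,
            age_slopes=(0.0,) * 5,
            effect_global=0.0,
            effect_deep=0.0,
            noise_sd=0.0,
        )
        for name, mp in cfg.metrics.items()
    }
    return default_cohort_config(seed=3, metrics=metrics, pta_noise_sd=0.0)


@pytest.fixture
def volume_config():
    return default_volume_config(seed=11)


def patients_xy(subjects: pd.DataFrame, tables, metric="FA"):
    """Patient predictor block and PTA vector straight from a cohort."""
    pat = subjects[subjects["group"] == "patient"].set_index("subject_id")
    X = tables[metric].loc[pat.index].to_numpy()
    y = pat["pta_days"].to_numpy(dtype=float)
    return X, y
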