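"""Component–outcome association and cross-validated prediction testing.

Two inferential surfaces:

* **Component associations** — Spearman rank correlation between each of
  the first three component scores and amnesia duration, with one-tailed
  p-values from the t-approximation (n−2 df) and a Bonferroni-corrected
  threshold (0.05/3 ≈ 0.017 at the defaults).

* **Leave-one-out prediction with a permutation null** — each subject is
  predicted by a PLS1 model trained on the others, with *all*
  normalization (column means and SDs for predictors and outcome)
  recomputed without the held-out case so no information leaks into the
  fold.  The observed Spearman correlation between held-out predictions
  and true outcomes is referred to an empirical null built by re-running
  the complete cross-validation pipeline — fold-wise re-standardization
  included — on B random permutations of the outcome vector.  The
  empirical p-value is the fraction of null correlations strictly
  exceeding the observed one (an add-one smoothed variant is available,
  since the strict rule can return exactly 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .pls import PLSFit, _pls1_coef

__all__ = [
    "ComponentAssociation",
    "LOOCVResult",
    "spearman_corr",
    "correlate_components",
    "loocv_predict",
    "loocv_fold_loadings",
    "permutation_test",
    "plot_prediction",
]

_TAILS = {"positive": "greater", "negative": "less", "two": "two-sided"}


def spearman_corr(x, y, tail: str = "two") -> tuple[float, float]:
    """Spearman rank correlation with a directional p-value.

    rho is the Pearson correlation of mid-ranks (ties get average ranks);
    the p-value uses the t-approximation with n−2 degrees of freedom,
    halved and directed for the one-tailed alternatives.

    Parameters
    ----------
    x, y : equal-length sequences of at least 4 finite values.
    tail : {"positive", "negative", "two"}
        Alternative hypothesis: rho > 0, rho < 0, or rho ≠ 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if x.size < 4:
        raise ValueError(f"need at least 4 observations, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a constant vector")
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {sorted(_TAILS)}, got {tail!r}")
    rho, p = stats.spearmanr(x, y, alternative=_TAILS[tail])
    return float(rho), float(p)


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """rho only, lean path for permutation loops."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx -= rx.mean()
    ry -= ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        return np.nan
    return float((rx @ ry) / denom)


@dataclass(frozen=True)
class ComponentAssociation:
    """Spearman association of one PLS component score with the outcome."""

    component: int  # 1-based
    rho: float
    p_value: float
    significant: bool
    alpha_corrected: float
    tail: str


def correlate_components(
    fit: PLSFit,
    y,
    alpha_corrected: float = 0.05 / 3,
    n_components: int = 3,
    tail: str = "positive",
) -> list[ComponentAssociation]:
    """Associate the first ``n_components`` component scores with ``y``.

    The components are tested in the fit's sign convention; the tail is
    recorded on each result so the orientation-dependence of one-tailed
    p-values stays visible in output.
    """
    if fit.n_components < n_components:
        raise ValueError(
            f"fit has {fit.n_components} components, {n_components} requested"
        )
    y = np.asarray(y, dtype=float)
    out = []
    for j in range(n_components):
        rho, p = spearman_corr(fit.x_scores[:, j], y, tail=tail)
        out.append(
            ComponentAssociation(
                component=j + 1,
                rho=rho,
                p_value=p,
                significant=bool(p < alpha_corrected),
                alpha_corrected=float(alpha_corrected),
                tail=tail,
            )
        )
    return out


def _loocv_core(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Held-out standardized predictions; assumes validated inputs."""
    n = X.shape[0]
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr = X[mask]
        ytr = y[mask]
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0, ddof=1)
        ym = ytr.mean()
        ysd = ytr.std(ddof=1)
        if np.any(sd == 0) or ysd == 0:
            cols = np.nonzero(sd == 0)[0]
            what = (
                f"predictor column(s) {cols.tolist()}" if cols.size else "the outcome"
            )
            raise ValueError(
                f"zero variance in {what} after leaving out subject {i}"
            )
        B = _pls1_coef((Xtr - mu) / sd, (ytr - ym) / ysd, k)
        preds[i] = ((X[i] - mu) / sd) @ B
    return preds


def loocv_predict(X, y, n_components: int = 3) -> np.ndarray:
    """Leave-one-out PLS1 predictions with fold-wise re-standardization.

    Parameters
    ----------
    X : (n, p) array of age-adjusted, *unstandardized* predictors.
    y : (n,) outcome (days).
    n_components : components per fold (each fold has n−1 subjects and
        needs at least ``n_components + 2`` of them).

    Returns
    -------
    (n,) array of held-out predictions, each in its own fold's
    standardized outcome units.  Subject i's prediction never uses
    subject i's outcome or predictor row for training or normalization.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, p) with one y value per row")
    n = X.shape[0]
    if n < n_components + 3:
        raise ValueError(
            f"need at least n_components + 3 = {n_components + 3} subjects, got {n}"
        )
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite")
    return _loocv_core(X, y, n_components)


def loocv_fold_loadings(X, y, n_components: int = 3):
    """Per-fold PLS1 predictor loadings, summarized as mean ± standard error.

    Each leave-one-out fold is standardized and fit with the usual sign
    convention, so fold loadings are comparable across folds.  Returns
    ``(mean, se)``, both (predictors × components).
    """
    from .pls import fit_pls1

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    loadings = np.empty((n, X.shape[1], n_components))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = X[mask], y[mask]
        Xs = (Xtr - Xtr.mean(0)) / Xtr.std(0, ddof=1)
        ys = (ytr - ytr.mean()) / ytr.std(ddof=1)
        loadings[i] = fit_pls1(Xs, ys, n_components).x_loadings
    mean = loadings.mean(axis=0)
    se = loadings.std(axis=0, ddof=1) / np.sqrt(n)
    return mean, se


@dataclass
class LOOCVResult:
    """Cross-validated prediction performance with its permutation null."""

    predictions: np.ndarray  # per-subject held-out standardized predictions
    observed_rho: float
    null_rhos: np.ndarray  # B permutation correlations
    p_value: float
    B: int
    seed: int
    n_components: int
    counting_rule: str  # "strict" (#{null > obs}/B) or "add_one"
    tail: str = "positive"
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "observed_rho": float(self.observed_rho),
            "p_value": float(self.p_value),
            "B": int(self.B),
            "seed": int(self.seed),
            "n_components": int(self.n_components),
            "counting_rule": self.counting_rule,
            "tail": self.tail,
            "predictions": self.predictions.tolist(),
            "null_summary": {
                "mean": float(np.mean(self.null_rhos)),
                "sd": float(np.std(self.null_rhos, ddof=1)),
                "q95": float(np.quantile(self.null_rhos, 0.95)),
            },
            **self.extra,
        }


def permutation_test(
    X,
    y,
    n_components: int = 3,
    B: int = 10_000,
    seed: int = 0,
    *,
    smoothed: bool = False,
) -> LOOCVResult:
    """Permutation test of the leave-one-out prediction correlation.

    The observed statistic is the Spearman correlation between the
    held-out predictions and the true outcomes.  Each of the B null draws
    permutes the outcome vector across subjects uniformly at random
    (sampled with replacement from the permutation group), re-runs the
    *full* leave-one-out pipeline — fold-wise normalization included — on
    the permuted outcome, and records the prediction–permuted-outcome
    correlation.

    ``p = #{null > observed} / B`` by default (strict exceedance); with
    ``smoothed=True``, ``p = (1 + #{null ≥ observed}) / (1 + B)``, which
    cannot return 0.
    """
    if B < 100:
        raise ValueError(f"B must be >= 100, got {B}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    preds = loocv_predict(X, y, n_components)
    observed = _spearman_rho(preds, y)

    rng = np.random.default_rng(seed)
    n = y.shape[0]
    null = np.empty(B)
    for b in range(B):
        yp = y[rng.permutation(n)]
        pp = _loocv_core(X, yp, n_components)
        null[b] = _spearman_rho(pp, yp)

    if smoothed:
        p = (1 + int(np.sum(null >= observed))) / (1 + B)
        rule = "add_one"
    else:
        p = int(np.sum(null > observed)) / B
        rule = "strict"
    return LOOCVResult(
        predictions=preds,
        observed_rho=observed,
        null_rhos=null,
        p_value=float(p),
        B=B,
        seed=seed,
        n_components=n_components,
        counting_rule=rule,
    )


def plot_prediction(result: LOOCVResult, y, path=None):
    """Scatter of held-out standardized predictions against the true
    standardized outcome, annotated with rho and the permutation p."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    y = np.asarray(y, dtype=float)
    y_z = (y - y.mean()) / y.std(ddof=1)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(y_z, result.predictions, color="tab:blue")
    ax.set_xlabel("true PTA (z score)")
    ax.set_ylabel("predicted PTA (z score)")
    ax.set_title(
        f"Spearman r = {result.observed_rho:.2f}, "
        f"$p_{{perm}}$ = {result.p_value:.3f} (B = {result.B})"
    )
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
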