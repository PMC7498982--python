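"""PLS1 regression: covariance-maximizing components for a single outcome.

Partial least squares with one response (PLS1) extracts orthogonal latent
components t_a = X_a w_a that maximize covariance between the predictor
block and the outcome, deflating X after each component:

    w_a ∝ X_aᵀ f_a,   t_a = X_a w_a,   p_a = X_aᵀ t_a / t_aᵀt_a,
    q_a = f_aᵀ t_a / t_aᵀt_a,   X_{a+1} = X_a − t_a p_aᵀ,
    f_{a+1} = f_a − q_a t_a.

Regression coefficients for k components are B_k = W_k (P_kᵀ W_k)⁻¹ q_k,
so standardized predictions are X B_k.  The procedure is deterministic
(no random initialization) and, at full rank, its fitted values coincide
with ordinary least squares.

Component signs are arbitrary in PLS.  Here each component is oriented so
that the sum of its predictor loadings is ≤ 0 (ties broken by making the
first loading ≤ 0), which matches the orientation in which a global
*decrease* of FA loads negatively and the component score correlates
positively with amnesia duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PLSFit", "fit_pls1", "predict", "select_n_components"]

_STANDARDIZED_MEAN_TOL = 1e-8
_STANDARDIZED_SD_TOL = 1e-6


@dataclass
class PLSFit:
    """Result of a PLS1 fit on standardized data.

    Attributes
    ----------
    n_components : int
        Number of extracted components.
    x_weights : (p, k) ndarray
        Weight vectors w_a (unit norm), applied to deflated X.
    x_loadings : (p, k) ndarray
        Predictor loadings p_a; the per-region "spatial pattern" of each
        component.
    y_loadings : (k,) ndarray
        Outcome loadings q_a.
    x_scores : (n, k) ndarray
        Component scores t_a; mutually orthogonal.
    coef_by_ncomp : (k, p) ndarray
        Row j holds the regression coefficients using components 1..j+1.
    pct_var_x, pct_var_y : (k,) ndarray
        Cumulative percentage of predictor-block (resp. outcome) variance
        captured by components 1..a.
    x_mean, x_sd, y_mean, y_sd
        Normalization constants the caller used to standardize; stored so
        new observations can be placed on the training scale.
    feature_names : tuple of str
        Predictor column names, for error messages and serialization.
    """

    n_components: int
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_scores: np.ndarray
    coef_by_ncomp: np.ndarray
    pct_var_x: np.ndarray
    pct_var_y: np.ndarray
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    feature_names: tuple = field(default_factory=tuple)

    @property
    def coefficients(self) -> np.ndarray:
        """Coefficients at the fit's full component count."""
        return self.coef_by_ncomp[-1]

    def standardize_x(self, X_raw: np.ndarray) -> np.ndarray:
        """Place raw predictor rows on the training scale."""
        return (np.asarray(X_raw, dtype=float) - self.x_mean) / self.x_sd

    def destandardize_y(self, y_std: np.ndarray) -> np.ndarray:
        """Map standardized predictions back to outcome units."""
        return np.asarray(y_std, dtype=float) * self.y_sd + self.y_mean

    def to_dict(self) -> dict:
        """JSON-serializable representation of the fit."""
        return {
            "n_components": int(self.n_components),
            "feature_names": list(self.feature_names),
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "x_scores": self.x_scores.tolist(),
            "coef_by_ncomp": self.coef_by_ncomp.tolist(),
            "pct_var_x": self.pct_var_x.tolist(),
            "pct_var_y": self.pct_var_y.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "y_mean": float(self.y_mean),
            "y_sd": float(self.y_sd),
        }


def _check_standardized(arr: np.ndarray, name: str) -> None:
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    if np.any(np.abs(mean) > _STANDARDIZED_MEAN_TOL) or np.any(
        np.abs(sd - 1.0) > _STANDARDIZED_SD_TOL
    ):
        raise ValueError(
            f"{name} is not standardized (columns must have mean 0 and "
            f"sample SD 1); got means {np.round(mean, 6)} and SDs {np.round(sd, 6)}"
        )


def _pls1_core(X: np.ndarray, y: np.ndarray, k: int):
    """Deflation PLS1 on pre-standardized data; no validation, no sign fix.

    Returns (W, P, q, T).  Kept lean because leave-one-out and permutation
    loops call it tens of thousands of times.
    """
    n, p = X.shape
    Xd = X.copy()
    f = y.copy()
    W = np.empty((p, k))
    P = np.empty((p, k))
    q = np.empty(k)
    T = np.empty((n, k))
    for a in range(k):
        w = Xd.T @ f
        nw = np.linalg.norm(w)
        if nw <= 1e-14:
            raise np.linalg.LinAlgError(
                f"PLS1 deflation exhausted covariance at component {a + 1}"
            )
        w /= nw
        t = Xd @ w
        tt = t @ t
        if tt <= 1e-28:
            raise np.linalg.LinAlgError(
                f"degenerate score vector at component {a + 1}"
            )
        pa = (Xd.T @ t) / tt
        qa = (f @ t) / tt
        W[:, a] = w
        P[:, a] = pa
        q[a] = qa
        T[:, a] = t
        Xd -= np.outer(t, pa)
        f -= qa * t
    return W, P, q, T


def _coef_from_wpq(W: np.ndarray, P: np.ndarray, q: np.ndarray, k: int) -> np.ndarray:
    """Regression coefficients B_k = W_k (P_kᵀ W_k)⁻¹ q_k."""
    Wk = W[:, :k]
    return Wk @ np.linalg.solve(P[:, :k].T @ Wk, q[:k])


def _pls1_coef(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Fast path: coefficient vector only (sign-invariant)."""
    W, P, q, _ = _pls1_core(X, y, k)
    return _coef_from_wpq(W, P, q, k)


def fit_pls1(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    *,
    feature_names: tuple = (),
    x_mean=None,
    x_sd=None,
    y_mean: float = 0.0,
    y_sd: float = 1.0,
    check_standardized: bool = True,
) -> PLSFit:
    """Fit PLS1 on standardized predictors X (n × p) and outcome y (n,).

    Parameters
    ----------
    X, y
        Standardized data: every column must have mean 0 and sample SD 1
        (n−1 denominator).  Violations raise ``ValueError``.
    n_components
        Number of components; must not exceed ``rank(X)`` and requires
        at least ``n_components + 2`` subjects.
    feature_names
        Optional predictor names, stored on the fit.
    x_mean, x_sd, y_mean, y_sd
        The normalization constants used to standardize, stored for reuse
        on held-out observations.  Default to the identity transform.
    check_standardized
        Disable only when the caller guarantees standardization.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be a 2-D array (subjects × predictors)")
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError(f"X has {n} rows but y has {y.shape[0]} values")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("X and y must be finite")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n < n_components + 2:
        raise ValueError(
            f"need at least n_components + 2 = {n_components + 2} subjects, got {n}"
        )
    rank = np.linalg.matrix_rank(X)
    if n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds rank(X)={rank}"
        )
    if check_standardized:
        _check_standardized(X, "X")
        _check_standardized(y[:, None], "y")

    W, P, q, T = _pls1_core(X, y, n_components)

    # Orient each component: sum of predictor loadings <= 0, ties broken by
    # the first (FT) loading <= 0.  Flipping (w, t, p, q) jointly leaves
    # the factorization and all predictions unchanged.
    for a in range(n_components):
        s = P[:, a].sum()
        if s > 0 or (s == 0 and P[0, a] > 0):
            W[:, a] *= -1.0
            P[:, a] *= -1.0
            T[:, a] *= -1.0
            q[a] *= -1.0

    coef_by_ncomp = np.vstack(
        [_coef_from_wpq(W, P, q, k) for k in range(1, n_components + 1)]
    )

    ss_x = np.sum(X * X)
    ss_y = y @ y
    tt = np.sum(T * T, axis=0)
    var_x_per_comp = tt * np.sum(P * P, axis=0)
    var_y_per_comp = q * q * tt
    pct_var_x = 100.0 * np.cumsum(var_x_per_comp) / ss_x
    pct_var_y = 100.0 * np.cumsum(var_y_per_comp) / ss_y

    if x_mean is None:
        x_mean = np.zeros(p)
    if x_sd is None:
        x_sd = np.ones(p)

    return PLSFit(
        n_components=n_components,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        x_scores=T,
        coef_by_ncomp=coef_by_ncomp,
        pct_var_x=pct_var_x,
        pct_var_y=pct_var_y,
        x_mean=np.asarray(x_mean, dtype=float),
        x_sd=np.asarray(x_sd, dtype=float),
        y_mean=float(y_mean),
        y_sd=float(y_sd),
        feature_names=tuple(feature_names),
    )


def predict(fit: PLSFit, X_new: np.ndarray, n_components: int | None = None) -> np.ndarray:
    """Standardized predictions for standardized predictor rows.

    ``X_new`` must already be on the training scale (use
    :meth:`PLSFit.standardize_x` for raw rows).  Returns predictions in
    standardized outcome units.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    p = fit.x_loadings.shape[0]
    if X_new.shape[1] != p:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, fit expects {p}"
            + (f" ({', '.join(fit.feature_names)})" if fit.feature_names else "")
        )
    k = fit.n_components if n_components is None else n_components
    if not 1 <= k <= fit.n_components:
        raise ValueError(f"n_components must be in [1, {fit.n_components}]")
    return X_new @ fit.coef_by_ncomp[k - 1]


def select_n_components(pct_var_tables, threshold: float = 80.0) -> int:
    """Smallest k whose cumulative %-variance *strictly* exceeds ``threshold``
    for every analyzed variable.

    Parameters
    ----------
    pct_var_tables : mapping of variable name -> cumulative %-variance vector,
        or a sequence of vectors (auto-named var0, var1, ...).
    threshold : percent, default 80.

    Raises
    ------
    ValueError
        If some variable never exceeds the threshold, naming it.
    """
    if not hasattr(pct_var_tables, "items"):
        pct_var_tables = {f"var{i}": v for i, v in enumerate(pct_var_tables)}
    if not pct_var_tables:
        raise ValueError("no variance tables supplied")
    chosen = 0
    for name, vec in pct_var_tables.items():
        vec = np.asarray(vec, dtype=float)
        if np.any(np.diff(vec) < -1e-9) or vec.min() < -1e-9 or vec.max() > 100 + 1e-9:
            raise ValueError(f"variance vector for {name!r} is not a cumulative percentage")
        exceeding = np.nonzero(vec > threshold)[0]
        if exceeding.size == 0:
            raise ValueError(
                f"variable {name!r} never exceeds {threshold}% "
                f"(max cumulative variance {vec.max():.1f}%)"
            )
        chosen = max(chosen, int(exceeding[0]) + 1)
    return chosen
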