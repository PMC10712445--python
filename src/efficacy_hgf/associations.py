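"""Brain-psychometric association stage: sparse PLS, confirmatory OLS and
backward stepwise AIC regression.

Sparse partial least squares (regression mode) finds pairs of sparse loading
vectors whose score vectors maximize covariance between the brain matrix X
and the psychometric matrix Y, retaining only the ``keep_x``/``keep_y``
largest-magnitude loadings per component via soft-thresholding.  Tuning is
two-step: the component count (and sparsity sizes) minimizing
cross-validated prediction error is chosen first, then selection stability
of each variable is measured over repeated CV refits and the stable sets
thresholded.  Confirmatory statistics on the implicated subsets come from
ordinary least squares; symptom-level structure is probed with backward
stepwise regression under AIC.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SPLSResult",
    "StepwiseResult",
    "spls_fit",
    "spls_predict",
    "tune_spls",
    "confirmatory_ols",
    "stepwise_backward_aic",
]


def _soft_threshold_keep(v: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold retaining the ``keep`` largest-magnitude entries."""
    if keep >= len(v):
        return v.copy()
    lam = np.sort(np.abs(v))[-(keep + 1)]
    return np.sign(v) * np.maximum(np.abs(v) - lam, 0.0)


@dataclass
class SPLSResult:
    n_components: int
    x_loadings: np.ndarray  # p x H sparse weight vectors
    y_loadings: np.ndarray  # q x H sparse weight vectors
    x_scores: np.ndarray  # n x H
    y_scores: np.ndarray  # n x H
    selected_X: list
    selected_Y: list
    variance_explained_Y: float
    coef: np.ndarray  # p x q regression coefficients, standardized space
    x_mean: np.ndarray = field(repr=False, default=None)
    x_sd: np.ndarray = field(repr=False, default=None)
    y_mean: np.ndarray = field(repr=False, default=None)
    y_sd: np.ndarray = field(repr=False, default=None)
    x_proj: np.ndarray = field(repr=False, default=None)  # p x H: W (P'W)^-1
    stability_freq: dict | None = None


def _as_matrix(A):
    if isinstance(A, pd.DataFrame):
        return A.to_numpy(float), list(A.columns)
    A = np.asarray(A, float)
    if A.ndim == 1:
        A = A[:, None]
    return A, list(range(A.shape[1]))


def _standardize(A: np.ndarray):
    mean = A.mean(axis=0)
    sd = A.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (A - mean) / sd, mean, sd


def spls_fit(X, Y, n_components: int = 1, keep_x: int | None = None,
             keep_y: int | None = None, max_iter: int = 500,
             tol: float = 1e-9) -> SPLSResult:
    """Regression-mode sparse PLS of Y on X.

    Columns are z-scored internally.  Per component, the loading pair is
    iterated on the cross-covariance matrix with soft-thresholding keeping
    the ``keep_x``/``keep_y`` largest loadings until convergence, then X and
    Y are deflated by the X-score regression.  ``keep=None`` disables
    sparsity on that side (dense PLS).
    """
    Xm, x_names = _as_matrix(X)
    Ym, y_names = _as_matrix(Y)
    n, p = Xm.shape
    q = Ym.shape[1]
    if n_components >= n:
        raise ValueError("n_components must be < n_subjects")
    keep_x = p if keep_x is None else keep_x
    keep_y = q if keep_y is None else keep_y
    if keep_x > p or keep_y > q or keep_x < 1 or keep_y < 1:
        raise ValueError("keep counts must be in [1, n_columns]")

    Xs, x_mean, x_sd = _standardize(Xm)
    Ys, y_mean, y_sd = _standardize(Ym)
    Xd, Yd = Xs.copy(), Ys.copy()
    ss_y_total = float(np.sum(Ys**2))

    W = np.zeros((p, n_components))
    C = np.zeros((q, n_components))
    P = np.zeros((p, n_components))
    D = np.zeros((q, n_components))
    T = np.zeros((n, n_components))
    S = np.zeros((n, n_components))

    for h in range(n_components):
        M = Xd.T @ Yd
        # initialize from the dominant right singular direction
        _, _, vt = np.linalg.svd(M, full_matrices=False)
        v = vt[0]
        u = np.zeros(p)
        for _ in range(max_iter):
            u_new = _soft_threshold_keep(M @ v, keep_x)
            nu = np.linalg.norm(u_new)
            if nu == 0:
                break
            u_new /= nu
            v_new = _soft_threshold_keep(M.T @ u_new, keep_y)
            nv = np.linalg.norm(v_new)
            if nv == 0:
                break
            v_new /= nv
            if np.linalg.norm(u_new - u) < tol and np.linalg.norm(v_new - v) < tol:
                u, v = u_new, v_new
                break
            u, v = u_new, v_new
        t = Xd @ u
        s = Yd @ v
        tt = float(t @ t)
        if tt == 0:
            n_components = h
            W, C, P, D, T, S = (A[:, :h] for A in (W, C, P, D, T, S))
            break
        W[:, h], C[:, h], T[:, h], S[:, h] = u, v, t, s
        P[:, h] = Xd.T @ t / tt
        D[:, h] = Yd.T @ t / tt
        Xd = Xd - np.outer(t, P[:, h])
        Yd = Yd - np.outer(t, D[:, h])

    var_expl = 1.0 - float(np.sum(Yd**2)) / ss_y_total if ss_y_total > 0 else 0.0
    # regression coefficients: B = W (P'W)^-1 D'
    if n_components > 0:
        x_proj = W @ np.linalg.pinv(P.T @ W)
        coef = x_proj @ D.T
    else:
        x_proj = np.zeros((p, 0))
        coef = np.zeros((p, q))

    sel_x = sorted({x_names[j] for h in range(n_components)
                    for j in np.nonzero(W[:, h])[0]})
    sel_y = sorted({y_names[j] for h in range(n_components)
                    for j in np.nonzero(C[:, h])[0]})
    return SPLSResult(
        n_components=n_components, x_loadings=W, y_loadings=C,
        x_scores=T, y_scores=S, selected_X=sel_x, selected_Y=sel_y,
        variance_explained_Y=var_expl, coef=coef,
        x_mean=x_mean, x_sd=x_sd, y_mean=y_mean, y_sd=y_sd, x_proj=x_proj,
    )


def spls_predict(fit: SPLSResult, X_new) -> np.ndarray:
    """Predict Y (original scale) for new rows of X."""
    Xm, _ = _as_matrix(X_new)
    Xs = (Xm - fit.x_mean) / fit.x_sd
    return Xs @ fit.coef * fit.y_sd + fit.y_mean


def _cv_splits(n: int, folds: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    return [np.sort(idx[f::folds]) for f in range(folds)]


def tune_spls(X, Y, components_grid=(1, 2, 3), keep_x_grid=None,
              keep_y_grid=None, folds: int = 4, repeats: int = 1000,
              stability_threshold: float = 0.8, seed: int = 0) -> dict:
    """Two-step sPLS tuning with repeated cross-validation.

    Step 1 chooses the (n_components, keep_x, keep_y) combination minimizing
    the repeated-CV mean squared error of held-out Y prediction.  The
    component grid always includes 0 components — the training-mean
    predictor — so that when the model has no out-of-sample predictive
    validity (pure noise) no components, and hence no variables, are
    retained.  Step 2 refits at the chosen sizes on every training split
    (``repeats x folds`` refits) and records per-variable selection
    frequencies; variables at or above ``stability_threshold`` form the
    stable sets.  Deterministic given ``seed``.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    Xm, x_names = _as_matrix(X)
    Ym, y_names = _as_matrix(Y)
    n, p = Xm.shape
    q = Ym.shape[1]
    if n < 2 * folds:
        raise ValueError(f"n={n} too small to split into {folds} folds")
    keep_x_grid = [p] if keep_x_grid is None else list(keep_x_grid)
    keep_y_grid = [q] if keep_y_grid is None else list(keep_y_grid)
    comps = sorted({0, *components_grid})
    grid = [(0, keep_x_grid[0], keep_y_grid[0])] if 0 in comps else []
    grid += list(itertools.product([c for c in comps if c > 0],
                                   keep_x_grid, keep_y_grid))

    rng = np.random.default_rng(seed)
    # A smaller repeat count suffices for the size search; stability uses
    # the full repeat budget below.
    tune_repeats = min(repeats, 50)
    splits = [_cv_splits(n, folds, rng) for _ in range(tune_repeats)]
    mse = {}
    for ncomp, kx, ky in grid:
        errs = []
        for rep_splits in splits:
            for test_idx in rep_splits:
                train_idx = np.setdiff1d(np.arange(n), test_idx)
                if ncomp == 0:
                    pred = np.broadcast_to(Ym[train_idx].mean(axis=0),
                                           (len(test_idx), q))
                else:
                    fit = spls_fit(Xm[train_idx], Ym[train_idx], ncomp, kx, ky)
                    pred = spls_predict(fit, Xm[test_idx])
                errs.append(np.mean((Ym[test_idx] - pred) ** 2))
        mse[(ncomp, kx, ky)] = float(np.mean(errs))
    chosen = min(mse, key=lambda k: (mse[k], k))
    ncomp, kx, ky = chosen

    count_x = np.zeros(p)
    count_y = np.zeros(q)
    n_refits = 0
    for _ in range(repeats if ncomp > 0 else 0):
        for test_idx in _cv_splits(n, folds, rng):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            fit = spls_fit(Xm[train_idx], Ym[train_idx], ncomp, kx, ky)
            sel_x = {j for h in range(fit.n_components)
                     for j in np.nonzero(fit.x_loadings[:, h])[0]}
            sel_y = {j for h in range(fit.n_components)
                     for j in np.nonzero(fit.y_loadings[:, h])[0]}
            for j in sel_x:
                count_x[j] += 1
            for j in sel_y:
                count_y[j] += 1
            n_refits += 1
    denom = max(n_refits, 1)
    freq_x = dict(zip(x_names, count_x / denom))
    freq_y = dict(zip(y_names, count_y / denom))
    stable_x = sorted(k for k, f in freq_x.items() if f >= stability_threshold)
    stable_y = sorted(k for k, f in freq_y.items() if f >= stability_threshold)
    return {
        "n_components": ncomp,
        "keep_x": kx,
        "keep_y": ky,
        "cv_mse": mse,
        "n_refits": n_refits,
        "stability_freq_X": freq_x,
        "stability_freq_Y": freq_y,
        "stable_X": stable_x,
        "stable_Y": stable_y,
        "threshold": stability_threshold,
    }


def confirmatory_ols(response, predictors) -> pd.DataFrame:
    """OLS with intercept: estimates, standard errors, t and two-sided p."""
    y = np.asarray(response, float)
    Xm, names = _as_matrix(predictors)
    if len(y) <= Xm.shape[1] + 1:
        raise ValueError("need n > p + 1 observations")
    X = sm.add_constant(pd.DataFrame(Xm, columns=[str(c) for c in names]))
    if np.linalg.cond(X.to_numpy()) > 1e10:
        raise ValueError("predictors are collinear (condition number > 1e10)")
    res = sm.OLS(y, X).fit()
    return pd.DataFrame({
        "estimate": res.params,
        "se": res.bse,
        "t": res.tvalues,
        "p": res.pvalues,
    })


@dataclass
class StepwiseResult:
    table: pd.DataFrame
    retained: list[str]
    final_aic: float
    path: list  # (dropped_name, aic_after_drop)
    full_aic: float


def stepwise_backward_aic(response, predictors) -> StepwiseResult:
    """Backward stepwise OLS under AIC.

    Starts from the full model and repeatedly drops the single predictor
    whose removal most decreases AIC, stopping when no removal helps.  Ties
    are broken by dropping the larger column index.  The intercept is always
    retained.
    """
    y = np.asarray(response, float)
    Xm, names = _as_matrix(predictors)
    names = [str(c) for c in names]
    if len(y) <= Xm.shape[1] + 1:
        raise ValueError("need n > p + 1 observations")
    df = pd.DataFrame(Xm, columns=names)

    def aic_of(cols):
        X = sm.add_constant(df[cols]) if cols else \
            pd.DataFrame({"const": np.ones(len(y))})
        return sm.OLS(y, X).fit().aic

    current = list(names)
    current_aic = aic_of(current)
    full_aic = current_aic
    path = []
    while current:
        # candidate drops, scanned from the largest column index down so
        # that equal-AIC ties resolve to the larger index
        best = None
        for j in range(len(current) - 1, -1, -1):
            cols = current[:j] + current[j + 1:]
            a = aic_of(cols)
            if a < current_aic - 1e-12 and (best is None or a < best[1] - 1e-12):
                best = (j, a)
        if best is None:
            break
        j, a = best
        path.append((current[j], float(a)))
        current = current[:j] + current[j + 1:]
        current_aic = a

    X = sm.add_constant(df[current]) if current else \
        pd.DataFrame({"const": np.ones(len(y))})
    res = sm.OLS(y, X).fit()
    table = pd.DataFrame({
        "estimate": res.params, "se": res.bse,
        "t": res.tvalues, "p": res.pvalues,
    })
    return StepwiseResult(
        table=table, retained=current, final_aic=float(res.aic),
        path=path, full_aic=float(full_aic),
    )
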