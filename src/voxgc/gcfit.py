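"""Granger-causality estimators for two-ROI voxel datasets.

Three estimators are provided:

* :func:`fit_lasso_gc` — the LASSO-GC method.  For every row equation of
  the order-1 VAR, the observations are split into two random halves; the
  LARS path with GCV tuning on the first half pre-selects predictors, and
  an OLS refit on the second half yields the coefficient, a signed
  t-score, and a two-sided p-value.  Splitting keeps the selection and
  inference data disjoint, so the refit t-tests are not biased by the
  selection.
* :func:`fit_pairwise_gc` — the bivariate baseline: a separate two-variable
  AR(1) model per ordered voxel pair, fit by OLS on all observations.
  Omitted-variable bias makes this method prone to spurious causality
  (e.g. a chain x→y→z yields an apparent x→z link).
* :func:`fit_averaged_gc` — the region-averaging baseline: each ROI is
  collapsed to its mean series and a single bivariate AR(1) gives one
  t-score per direction.

A significant non-zero coefficient is equivalent to significant Granger
causality at model order one; the signed t-score doubles as the GC
strength, positive for enhancing and negative for suppressing influences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datasets import PairedRoiDataset, RegressionProblem, lagged_arrays

__all__ = [
    "CoefficientEstimates",
    "AveragedGcResult",
    "ols_refit",
    "fit_lasso_gc",
    "fit_pairwise_gc",
    "fit_averaged_gc",
    "residual_correlation",
]

_PERFECT_FIT_TOL = 1e-12


@dataclass
class CoefficientEstimates:
    """Full coefficient-matrix estimate with per-entry inference.

    Matrices are receiver-rows × sender-columns over the stacked voxel
    index (X first).  Entries that were not pre-selected carry b=0, t=0,
    p=1 and ``selected=False``.
    """

    b_hat: np.ndarray
    t_scores: np.ndarray
    p_values: np.ndarray
    selected: np.ndarray
    partition: tuple[int, int]
    method: str
    n_obs_fit: int
    row_df: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        shape = self.b_hat.shape
        for name in ("t_scores", "p_values", "selected"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape differs from b_hat")
        if self.row_df is None:
            self.row_df = np.full(shape[0], -1, dtype=int)


@dataclass
class AveragedGcResult:
    """Single t-score per direction from the region-averaged bivariate fit."""

    t_yx: float
    t_xy: float
    p_yx: float
    p_xy: float


def ols_refit(problem: RegressionProblem, active) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """OLS on the design restricted to ``active`` columns, with t-tests.

    Returns ``(b, t, p, df)`` with vectors aligned to the order of
    ``active``; df = n_obs − (columns actually fitted).  Collinear columns
    are dropped deterministically (lowest index kept) and reported with
    b=0, t=0, p=1.  A numerically perfect fit yields signed-infinity
    t sentinels with p=0.
    """
    active = list(active)
    n = problem.n_obs
    k = len(active)
    if k == 0:
        return np.zeros(0), np.zeros(0), np.zeros(0), n
    if k >= n:
        raise ValueError(f"active set size {k} >= n_obs {n}")
    X = problem.design[:, active]
    y = problem.response

    # deterministic greedy drop of dependent columns, lowest index kept
    kept: list[int] = []
    R_cols: list[np.ndarray] = []
    for idx in range(k):
        col = X[:, idx].astype(float)
        v = col.copy()
        for q in R_cols:
            v -= (q @ col) * q
        nv = np.linalg.norm(v)
        if nv > 1e-10 * max(np.linalg.norm(col), 1.0):
            R_cols.append(v / nv)
            kept.append(idx)
    if len(kept) < k:
        warnings.warn(
            f"collinear active set: dropped {k - len(kept)} dependent column(s)",
            stacklevel=2,
        )
    Xk = X[:, kept]
    df = n - len(kept)
    XtX = Xk.T @ Xk
    bk = np.linalg.solve(XtX, Xk.T @ y)
    resid = y - Xk @ bk
    rss = float(resid @ resid)

    b = np.zeros(k)
    t = np.zeros(k)
    p = np.ones(k)
    for pos, idx in enumerate(kept):
        b[idx] = bk[pos]
    if rss <= _PERFECT_FIT_TOL * max(1.0, float(y @ y)) or df <= 0:
        warnings.warn("perfect fit: t-scores reported as signed infinity", stacklevel=2)
        for idx in kept:
            t[idx] = np.inf * np.sign(b[idx]) if b[idx] != 0 else 0.0
            p[idx] = 0.0
        return b, t, p, df
    sigma2 = rss / df
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    for pos, idx in enumerate(kept):
        t[idx] = bk[pos] / se[pos] if se[pos] > 0 else 0.0
        p[idx] = 2 * stats.t.sf(abs(t[idx]), df=df)
    return b, t, p, df


def _split_halves(rng: np.random.Generator, obs_trial: np.ndarray, mode: str):
    """Random disjoint halves of the observations; odd counts favor selection.

    ``pooled_time`` permutes observations directly; ``across_trials``
    permutes whole trials so that selection and refit never share a trial.
    """
    n = len(obs_trial)
    if mode == "across_trials":
        trials = np.unique(obs_trial)
        perm = rng.permutation(trials)
        n_sel = (len(perm) + 1) // 2
        sel_trials = set(perm[:n_sel].tolist())
        sel = np.array([t in sel_trials for t in obs_trial])
        return np.nonzero(sel)[0], np.nonzero(~sel)[0]
    perm = rng.permutation(n)
    n_sel = (n + 1) // 2
    return np.sort(perm[:n_sel]), np.sort(perm[n_sel:])


def fit_lasso_gc(
    dataset: PairedRoiDataset,
    order: int = 1,
    seed: int = 0,
    mode: str = "pooled_time",
    n_grid: int = 100,
    split: str = "half",
) -> CoefficientEstimates:
    """LASSO pre-selection plus OLS refit with t-tests, per row equation.

    ``split`` controls how the selection and refit stages share data.
    ``"half"`` (default) randomly halves the observations (or whole trials
    in ``across_trials`` mode) with one global seeded split shared by all
    row equations, keeping selection and inference disjoint so the refit
    t-tests are valid post-selection.  ``"none"`` reuses all observations
    for both stages — the procedure used when only a single realization
    exists and no trials can be sorted into two sets; its per-coefficient
    p-values are then inflated by the selection and should be read as a
    ranking device for the summary statistics, not confirmatory tests.

    Rows whose GCV-selected set is too large for the refit stage fall back
    to an empty selection with a warning.  Deterministic given
    ``(dataset, seed)``.
    """
    from .lasso import lars_path, select_by_gcv

    if order != 1:
        raise ValueError("summary semantics are defined for order 1")
    if split not in ("half", "none"):
        raise ValueError(f"unknown split policy {split!r}")
    design, responses, obs_trial, _, _ = lagged_arrays(dataset, order)
    N = dataset.m + dataset.n
    rng = np.random.default_rng(seed)
    if split == "none":
        sel_rows = fit_rows = np.arange(len(obs_trial))
    else:
        sel_rows, fit_rows = _split_halves(rng, obs_trial, mode)
    if len(fit_rows) < 2:
        raise ValueError("too few observations to split into selection and refit halves")

    b_hat = np.zeros((N, N))
    t_scores = np.zeros((N, N))
    p_values = np.ones((N, N))
    selected = np.zeros((N, N), dtype=bool)
    row_df = np.zeros(N, dtype=int)

    for i in range(N):
        sel_problem = RegressionProblem(
            design=design[sel_rows],
            response=responses[sel_rows, i],
            predictor_index=[(v, 1) for v in range(N)],
            obs_trial=obs_trial[sel_rows],
            obs_time=np.zeros(len(sel_rows)),
            mode=mode,
        )
        path = lars_path(sel_problem)
        active, _ = select_by_gcv(path, n_grid=n_grid)
        if len(active) >= len(fit_rows):
            warnings.warn(
                f"row {i}: selected set ({len(active)}) too large for refit half; "
                "falling back to empty selection",
                stacklevel=2,
            )
            active = ()
        fit_problem = RegressionProblem(
            design=design[fit_rows],
            response=responses[fit_rows, i],
            predictor_index=[(v, 1) for v in range(N)],
            obs_trial=obs_trial[fit_rows],
            obs_time=np.zeros(len(fit_rows)),
            mode=mode,
        )
        b, t, p, df = ols_refit(fit_problem, active)
        row_df[i] = df
        for pos, j in enumerate(active):
            b_hat[i, j] = b[pos]
            t_scores[i, j] = t[pos]
            p_values[i, j] = p[pos]
            selected[i, j] = True
    return CoefficientEstimates(
        b_hat=b_hat, t_scores=t_scores, p_values=p_values, selected=selected,
        partition=(dataset.m, dataset.n), method="lasso_gc",
        n_obs_fit=len(fit_rows), row_df=row_df,
    )


def fit_pairwise_gc(dataset: PairedRoiDataset, order: int = 1) -> CoefficientEstimates:
    """Bivariate AR(1) per ordered voxel pair, OLS on all observations.

    The cross coefficient of the pair (sender j → receiver i) fills entry
    (i, j); diagonal entries come from each voxel's own univariate AR(1)
    fit, so every entry is estimated exactly once.  All pairs within and
    between regions are fit.
    """
    if order != 1:
        raise ValueError("pairwise baseline is defined for order 1")
    L, Yt, _, _, _ = lagged_arrays(dataset, order)
    nobs, N = L.shape
    if nobs < 3:
        raise ValueError("insufficient time points for a bivariate fit")
    G = L.T @ L                       # G[a, b] = lag_a · lag_b
    C = L.T @ Yt                      # C[a, i] = lag_a · response_i
    yTy = np.einsum("ti,ti->i", Yt, Yt)

    g_own = np.diag(G)[:, None]       # (i, 1): lag_i · lag_i
    g_cross = G                       # (i, j)
    g_send = np.diag(G)[None, :]      # (1, j)
    c_own = np.diag(C)[:, None]       # lag_i · response_i
    c_send = C.T                      # (i, j): lag_j · response_i
    det = g_own * g_send - g_cross**2
    with np.errstate(divide="ignore", invalid="ignore"):
        b_own = (g_send * c_own - g_cross * c_send) / det
        b_cross = (g_own * c_send - g_cross * c_own) / det
        rss = yTy[:, None] - b_own * c_own - b_cross * c_send
        sigma2 = np.maximum(rss, 0.0) / (nobs - 2)
        var_cross = sigma2 * g_own / det
        t = b_cross / np.sqrt(np.maximum(var_cross, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df=nobs - 2)

    # diagonal: univariate AR(1) per voxel
    b_diag = np.diag(C) / np.diag(G)
    rss_d = yTy - b_diag * np.diag(C)
    sigma2_d = np.maximum(rss_d, 0.0) / (nobs - 1)
    t_diag = b_diag / np.sqrt(np.maximum(sigma2_d / np.diag(G), 1e-300))
    p_diag = 2 * stats.t.sf(np.abs(t_diag), df=nobs - 1)

    b_hat = b_cross.copy()
    np.fill_diagonal(b_hat, b_diag)
    np.fill_diagonal(t, t_diag)
    np.fill_diagonal(p, p_diag)
    return CoefficientEstimates(
        b_hat=b_hat, t_scores=t, p_values=p,
        selected=np.ones((N, N), dtype=bool),
        partition=(dataset.m, dataset.n), method="pairwise_gc",
        n_obs_fit=nobs, row_df=np.full(N, nobs - 2, dtype=int),
    )


def fit_averaged_gc(dataset: PairedRoiDataset, order: int = 1) -> AveragedGcResult:
    """Region-averaged bivariate AR(1): one t-score per direction.

    Voxels are averaged within each region; the two mean series enter a
    single bivariate AR(1) fit by OLS on all observations.  ``t_yx`` tests
    the lagged Y-average in the X-average's equation (Y→X), ``t_xy`` the
    reverse.
    """
    avg = PairedRoiDataset(
        x_series=dataset.x_series.mean(axis=0, keepdims=True),
        y_series=dataset.y_series.mean(axis=0, keepdims=True),
        roi_labels=dataset.roi_labels,
    )
    est = fit_pairwise_gc(avg, order)
    return AveragedGcResult(
        t_yx=float(est.t_scores[0, 1]), t_xy=float(est.t_scores[1, 0]),
        p_yx=float(est.p_values[0, 1]), p_xy=float(est.p_values[1, 0]),
    )


def residual_correlation(
    dataset: PairedRoiDataset,
    estimates: CoefficientEstimates,
    order: int = 1,
) -> np.ndarray:
    """Pairwise correlation of per-voxel model residuals, unit diagonal.

    Residuals are computed from the fitted coefficient matrix on the full
    observation set.  Low off-diagonal correlations indicate the fitted
    model has captured the shared dynamics (the innovations of a
    well-specified VAR are independent across voxels).
    """
    L, Yt, _, _, _ = lagged_arrays(dataset, order)
    resid = Yt - L @ estimates.b_hat.T
    centered = resid - resid.mean(axis=0)
    sd = centered.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    corr = (centered / safe).T @ (centered / safe) / resid.shape[0]
    corr[sd == 0, :] = 0.0
    corr[:, sd == 0] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr
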