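"""Row-wise LASSO solved by least-angle regression, tuned by GCV.

Each row equation of the VAR is an ordinary regression with p·(m+n)
predictors.  The LASSO constrains the sum of absolute coefficients,
Σ|b| ≤ c — equivalently it minimizes ½‖y − Xb‖² + λΣ|b| — and sets a
subset of coefficients exactly to zero.  The LARS algorithm (with the
LASSO modification that drops a variable when its coefficient crosses
zero) traces the entire solution path from the all-zero solution to the
unpenalized least-squares end.

The tuning value is chosen by generalized cross-validation,

    GCV(c) = (RSS/n) / (1 − df/n)²,

evaluated on roughly a hundred candidate c values spanning [0, c_max];
df is the number of active predictors.  The active set at the global GCV
minimum is the pre-selected predictor set passed on to the OLS refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LassoPath", "PathStep", "lars_path", "gcv_score", "select_by_gcv"]


@dataclass
class PathStep:
    """One knot of the piecewise-linear LASSO path."""

    c: float                      # Σ|b| at this knot
    lam: float                    # penalty λ = max |X'r| at this knot
    coefficients: np.ndarray
    active_set: tuple[int, ...]
    rss: float

    @property
    def df(self) -> int:
        return len(self.active_set)


@dataclass
class LassoPath:
    """Ordered knots of the LARS-LASSO path for one regression problem."""

    steps: list[PathStep]
    design: np.ndarray = field(repr=False)
    response: np.ndarray = field(repr=False)

    @property
    def n_obs(self) -> int:
        return self.design.shape[0]

    @property
    def c_max(self) -> float:
        return self.steps[-1].c

    def interpolate(self, c: float) -> np.ndarray:
        """Coefficient vector at constraint value ``c``.

        The path is piecewise linear in the coefficients between knots, so
        linear interpolation inside the first segment whose c-range covers
        the requested value is exact.  Values beyond the path end clamp to
        the final (unpenalized) solution.
        """
        steps = self.steps
        if c <= steps[0].c:
            return steps[0].coefficients.copy()
        for lo, hi in zip(steps[:-1], steps[1:]):
            span = hi.c - lo.c
            if lo.c <= c <= hi.c and span > 0:
                theta = (c - lo.c) / span
                return (1 - theta) * lo.coefficients + theta * hi.coefficients
        return steps[-1].coefficients.copy()


def lars_path(problem, max_steps: int | None = None, tol: float = 1e-12) -> LassoPath:
    """Trace the full LASSO path of a regression problem by LARS.

    ``problem`` provides ``design`` (n_obs × p) and ``response``; columns
    are used as supplied (the assembly stage demeans them — no intercept
    is fitted).  The path starts at the all-zero solution and ends when
    the residual correlation is exhausted or the active set reaches the
    design rank limit, which also handles predictors > observations.
    Equal-correlation ties break deterministically toward the lowest
    predictor index.
    """
    X = np.asarray(problem.design, dtype=float)
    y = np.asarray(problem.response, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design/response shape mismatch")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in design or response")
    n, p = X.shape
    if n < 1:
        raise ValueError("need at least 1 observation")
    if max_steps is None:
        max_steps = 8 * p + 16

    G = X.T @ X
    cov = X.T @ y                       # running X'(y − Xb)
    beta = np.zeros(p)
    active: list[int] = []
    signs = np.zeros(p)
    steps = [PathStep(0.0, float(np.max(np.abs(cov), initial=0.0)),
                      beta.copy(), (), float(y @ y))]
    # scale-aware thresholds: correlations live on the scale of X'y
    scale = max(float(np.max(np.abs(cov), initial=0.0)), 1.0)
    eps = tol * scale
    max_active = min(p, int(np.linalg.matrix_rank(X))) if n < p else p
    drop_pending: list[int] = []

    for _ in range(max_steps):
        inactive = [j for j in range(p) if j not in active]
        C = float(np.max(np.abs(cov[inactive]), initial=0.0)) if inactive else 0.0
        C_active = float(np.max(np.abs(cov[active]), initial=0.0)) if active else 0.0
        C = max(C, C_active)
        if C <= eps:
            break
        if not drop_pending and inactive and len(active) < max_active:
            # admit every inactive predictor tied at the maximum correlation
            for j in inactive:
                if abs(cov[j]) >= C - eps:
                    active.append(j)
                    signs[j] = np.sign(cov[j])
        drop_pending = []
        if not active:
            break
        A_idx = np.array(sorted(active))
        sA = signs[A_idx]
        GA = G[np.ix_(A_idx, A_idx)] * np.outer(sA, sA)
        try:
            w = np.linalg.solve(GA, np.ones(len(A_idx)))
        except np.linalg.LinAlgError:
            w = np.linalg.lstsq(GA, np.ones(len(A_idx)), rcond=None)[0]
        denom = float(np.sum(w))
        if denom <= 0:
            break
        AA = 1.0 / np.sqrt(denom)
        wA = AA * w                      # equiangular weights, all > 0 in theory
        # correlation decay rates: a_j = x_j' u for all predictors
        a = G[:, A_idx] @ (sA * wA)

        # distance to the next equality event among inactive predictors
        gamma_hat = C / AA               # full step: correlations reach zero
        for j in range(p):
            if j in active:
                continue
            for num, den in ((C - cov[j], AA - a[j]), (C + cov[j], AA + a[j])):
                if den > eps and eps < num / den < gamma_hat:
                    gamma_hat = num / den
        # distance to the first sign change among active coefficients
        d_beta = sA * wA
        gamma_tilde = np.inf
        for k, j in enumerate(A_idx):
            if d_beta[k] != 0:
                g = -beta[j] / d_beta[k]
                if eps < g < gamma_tilde:
                    gamma_tilde = g
        gamma = min(gamma_hat, gamma_tilde)
        if not np.isfinite(gamma) or gamma <= 0:
            break

        beta[A_idx] += gamma * d_beta
        cov -= gamma * a
        if gamma_tilde <= gamma_hat:     # LASSO modification: drop at zero
            for k, j in enumerate(A_idx):
                if abs(beta[j]) <= eps * max(1.0, abs(gamma * d_beta[k])):
                    beta[j] = 0.0
                    if j in active:
                        active.remove(j)
                        signs[j] = 0.0
                        drop_pending.append(j)
        resid = y - X @ beta
        steps.append(PathStep(
            c=float(np.sum(np.abs(beta))),
            lam=float(np.max(np.abs(X.T @ resid), initial=0.0)),
            coefficients=beta.copy(),
            active_set=tuple(j for j in range(p) if beta[j] != 0.0),
            rss=float(resid @ resid),
        ))
        if steps[-1].lam <= eps and not drop_pending:
            break
    return LassoPath(steps=steps, design=X, response=y)


def gcv_score(rss: float, n_obs: int, df: int) -> float:
    """Generalized cross-validation score (RSS/n) / (1 − df/n)²."""
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if df < 0:
        raise ValueError("df must be non-negative")
    if df >= n_obs:
        raise ValueError("saturated model: GCV undefined for df >= n_obs")
    return (rss / n_obs) / (1.0 - df / n_obs) ** 2


def select_by_gcv(path: LassoPath, n_grid: int = 100):
    """Pick the predictor set minimizing GCV along the path.

    Candidate constraint values are the union of the path knots and an
    ``n_grid``-point linear grid on [0, c_max]; coefficients at off-knot
    values are linear interpolations within their segment.  The degrees of
    freedom at a candidate equal its non-zero coefficient count; RSS is
    recomputed exactly from the design.  Ties break toward the smaller c
    (the sparser model).  Returns ``(active_set, info)`` where ``info``
    records the winning c, coefficients and the evaluated GCV curve.
    """
    if not path.steps:
        raise ValueError("empty path")
    n = path.n_obs
    knot_cs = [s.c for s in path.steps]
    grid = np.unique(np.concatenate([np.linspace(0.0, path.c_max, n_grid), knot_cs]))
    best = None
    curve = []
    for c in grid:
        b = path.interpolate(float(c))
        df = int(np.count_nonzero(b))
        if df >= n:
            continue
        resid = path.response - path.design @ b
        g = gcv_score(float(resid @ resid), n, df)
        curve.append((float(c), df, g))
        if best is None or g < best[2] - 1e-15:
            best = (float(c), b, g)
    if best is None:   # every candidate saturated (tiny n); fall back to empty
        b0 = path.steps[0].coefficients
        best = (0.0, b0, gcv_score(float(path.response @ path.response), n, 0))
    c_star, b_star, g_star = best
    active = tuple(int(j) for j in np.nonzero(b_star)[0])
    info = {"c": c_star, "gcv": g_star, "coefficients": b_star, "curve": curve}
    return active, info
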