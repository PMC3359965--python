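"""Two-ROI voxel datasets, VAR models, and lagged-regression assembly.

The central objects are :class:`PairedRoiDataset` — voxel-by-time(-by-trial)
series for two regions of interest X (m voxels) and Y (n voxels) — and
:class:`MvarModel`, an order-p vector-autoregressive model over the stacked
(m+n)-voxel vector Z.  The stacked index convention places the X voxels at
rows 0..m-1 and the Y voxels at rows m..m+n-1.  Coefficient entry
``B[k][i, j]`` is the weight with which voxel *j* at lag *k* predicts voxel
*i* at the current time, so rows are receivers and columns are senders.

Submatrix names follow the predictor-first convention used throughout the
package: ``B_yx`` holds the Y→X couplings (rows X, columns Y), ``B_xy`` the
X→Y couplings (rows Y, columns X), and ``B_xx``/``B_yy`` the within-region
couplings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PairedRoiDataset",
    "MvarModel",
    "RegressionProblem",
    "assemble_regression",
    "znormalize",
]

BLOCKS = ("xx", "yy", "yx", "xy")


def _as_3d(a: np.ndarray, name: str) -> np.ndarray:
    """Coerce a (voxels, T) or (voxels, T, R) array to 3-D float."""
    a = np.asarray(a, dtype=float)
    if a.ndim == 2:
        a = a[:, :, None]
    if a.ndim != 3:
        raise ValueError(f"{name} must be (voxels, T) or (voxels, T, trials), got ndim={a.ndim}")
    return a


@dataclass
class PairedRoiDataset:
    """Voxel time series for two regions of interest.

    Parameters
    ----------
    x_series, y_series
        Arrays of shape (voxels, T) or (voxels, T, trials).  Both regions
        must share the number of time points T and trials R.
    roi_labels
        Pair of region identifiers, default ``("X", "Y")``.
    x_voxel_ids, y_voxel_ids
        Optional per-voxel identifiers; generated as ``X0..`` / ``Y0..``
        when omitted.
    """

    x_series: np.ndarray
    y_series: np.ndarray
    roi_labels: tuple[str, str] = ("X", "Y")
    x_voxel_ids: list[str] = field(default_factory=list)
    y_voxel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x_series = _as_3d(self.x_series, "x_series")
        self.y_series = _as_3d(self.y_series, "y_series")
        m, tx, rx = self.x_series.shape
        n, ty, ry = self.y_series.shape
        if m < 1 or n < 1:
            raise ValueError("each ROI needs at least one voxel")
        if (tx, rx) != (ty, ry):
            raise ValueError(
                f"ROIs must share time points and trials: X has (T={tx}, R={rx}), Y has (T={ty}, R={ry})"
            )
        if tx < 2:
            raise ValueError("need at least 2 time points")
        for name, arr in (("x_series", self.x_series), ("y_series", self.y_series)):
            if not np.all(np.isfinite(arr)):
                bad = np.unique(np.nonzero(~np.isfinite(arr))[0])
                raise ValueError(f"non-finite values in {name}, voxel rows {bad.tolist()}")
            sd = arr.reshape(arr.shape[0], -1).std(axis=1)
            if np.any(sd == 0):
                bad = np.nonzero(sd == 0)[0]
                raise ValueError(f"degenerate series: zero-variance voxels {bad.tolist()} in {name}")
        if not self.x_voxel_ids:
            self.x_voxel_ids = [f"X{i}" for i in range(m)]
        if not self.y_voxel_ids:
            self.y_voxel_ids = [f"Y{i}" for i in range(n)]
        if len(self.x_voxel_ids) != m or len(self.y_voxel_ids) != n:
            raise ValueError("voxel id lists must match voxel counts")

    # -- shape helpers ---------------------------------------------------
    @property
    def m(self) -> int:
        return self.x_series.shape[0]

    @property
    def n(self) -> int:
        return self.y_series.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.x_series.shape[1]

    @property
    def n_trials(self) -> int:
        return self.x_series.shape[2]

    @property
    def voxel_ids(self) -> list[str]:
        return list(self.x_voxel_ids) + list(self.y_voxel_ids)

    def stacked(self) -> np.ndarray:
        """Return the stacked series Z of shape (m+n, T, R), X rows first."""
        return np.concatenate([self.x_series, self.y_series], axis=0)


@dataclass
class MvarModel:
    """Order-p VAR model over the stacked voxel vector.

    ``coeffs`` is a list of p square (m+n)×(m+n) matrices; ``coeffs[k-1][i, j]``
    predicts voxel i at time t from voxel j at time t−k.  ``partition`` is the
    (m, n) split of the stacked index; ``innovation_sd`` the standard
    deviation of the i.i.d. Gaussian innovation process driving simulation.
    """

    coeffs: list[np.ndarray]
    partition: tuple[int, int]
    innovation_sd: float = 0.1

    def __post_init__(self) -> None:
        self.coeffs = [np.asarray(b, dtype=float) for b in self.coeffs]
        if not self.coeffs:
            raise ValueError("need at least one coefficient matrix")
        d = self.coeffs[0].shape[0]
        for b in self.coeffs:
            if b.shape != (d, d):
                raise ValueError("all coefficient matrices must be square and same size")
            if not np.all(np.isfinite(b)):
                raise ValueError("non-finite coefficients")
        m, n = self.partition
        if m + n != d:
            raise ValueError(f"partition {self.partition} does not sum to matrix size {d}")
        if self.innovation_sd <= 0:
            raise ValueError("innovation_sd must be positive")

    @property
    def order(self) -> int:
        return len(self.coeffs)

    @property
    def size(self) -> int:
        return self.coeffs[0].shape[0]

    def submatrix(self, block: str, lag: int = 1) -> np.ndarray:
        """One of the four coupling blocks of B_lag (view, not copy).

        ``block`` uses predictor-first naming: ``"yx"`` = Y→X (rows X,
        columns Y), ``"xy"`` = X→Y, ``"xx"``/``"yy"`` within-region.
        """
        return submatrix_view(self.coeffs[lag - 1], self.partition, block)

    def companion_spectral_radius(self) -> float:
        """Spectral radius of the companion matrix; < 1 means stable."""
        p, d = self.order, self.size
        comp = np.zeros((p * d, p * d))
        comp[:d] = np.hstack(self.coeffs)
        if p > 1:
            comp[d:, : (p - 1) * d] = np.eye((p - 1) * d)
        return float(np.max(np.abs(np.linalg.eigvals(comp))))

    def is_stable(self) -> bool:
        return self.companion_spectral_radius() < 1.0


def submatrix_view(matrix: np.ndarray, partition: tuple[int, int], block: str) -> np.ndarray:
    """Slice one coupling block out of a stacked (m+n)×(m+n) matrix.

    Rows are receivers, columns senders; block names are predictor-first
    (``"yx"`` = from Y to X, i.e. rows 0..m-1, columns m..m+n-1).
    """
    m, n = partition
    if block == "xx":
        return matrix[:m, :m]
    if block == "yy":
        return matrix[m:, m:]
    if block == "yx":
        return matrix[:m, m:]
    if block == "xy":
        return matrix[m:, :m]
    raise ValueError(f"unknown block {block!r}; expected one of {BLOCKS}")


@dataclass
class RegressionProblem:
    """One row equation of the VAR in regression form.

    ``design`` has one column per (source voxel, lag) pair, covering all
    p × (m+n) predictors; ``response`` is the row voxel's current value.
    ``obs_trial``/``obs_time`` record, per observation, the trial it came
    from and the time index of the response, so that observation- or
    trial-level resampling never has to re-derive them.
    """

    design: np.ndarray
    response: np.ndarray
    predictor_index: list[tuple[int, int]]
    obs_trial: np.ndarray
    obs_time: np.ndarray
    mode: str = "pooled_time"

    def __post_init__(self) -> None:
        if self.design.shape[0] != self.response.shape[0]:
            raise ValueError("design and response row counts differ")
        if self.design.shape[1] != len(self.predictor_index):
            raise ValueError("predictor_index must cover every design column")

    @property
    def n_obs(self) -> int:
        return self.design.shape[0]

    def restrict(self, rows: np.ndarray) -> "RegressionProblem":
        """Row-subset view used by split-half fitting."""
        return RegressionProblem(
            design=self.design[rows],
            response=self.response[rows],
            predictor_index=self.predictor_index,
            obs_trial=self.obs_trial[rows],
            obs_time=self.obs_time[rows],
            mode=self.mode,
        )


def lagged_arrays(
    dataset: PairedRoiDataset, order: int, demean: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Build the shared lagged design for all row equations at once.

    Returns ``(design, responses, obs_trial, obs_time, predictor_index)``
    where ``design`` is (n_obs, p·(m+n)) and ``responses`` is
    (n_obs, m+n) — column i of ``responses`` is the response vector of row
    equation i.  Observations pool all admissible time steps of every
    trial; a lagged window never straddles a trial boundary.  Voxel series
    are demeaned per voxel within each trial (the models carry no
    intercept).
    """
    T = dataset.n_timepoints
    if order >= T:
        raise ValueError(f"insufficient time points: order {order} >= T {T}")
    if order < 1:
        raise ValueError("order must be >= 1")
    z = dataset.stacked()  # (N, T, R)
    if demean:
        z = z - z.mean(axis=1, keepdims=True)
    N, _, R = z.shape

    design_rows, resp_rows, trial_idx, time_idx = [], [], [], []
    for r in range(R):
        zr = z[:, :, r]  # (N, T)
        # responses at times order..T-1; predictor block k is Z_{t-k}
        resp_rows.append(zr[:, order:].T)  # (T-order, N)
        design_rows.append(
            np.concatenate([zr[:, order - k : T - k].T for k in range(1, order + 1)], axis=1)
        )
        trial_idx.append(np.full(T - order, r))
        time_idx.append(np.arange(order, T))
    design = np.concatenate(design_rows, axis=0)
    responses = np.concatenate(resp_rows, axis=0)
    predictor_index = [(v, k) for k in range(1, order + 1) for v in range(N)]
    return (
        design,
        responses,
        np.concatenate(trial_idx),
        np.concatenate(time_idx),
        predictor_index,
    )


def assemble_regression(
    dataset: PairedRoiDataset,
    row_voxel: int,
    order: int = 1,
    mode: str = "pooled_time",
) -> RegressionProblem:
    """Assemble the lagged regression for one row equation of the VAR.

    ``row_voxel`` indexes the stacked vector (X voxels first).  In
    ``pooled_time`` mode the R×(T−order) lagged transitions of all trials
    are pooled as observations; ``across_trials`` assembles the same rows
    but marks the problem so that downstream resampling treats whole
    trials as the observational unit.
    """
    if mode not in ("pooled_time", "across_trials"):
        raise ValueError(f"unknown assembly mode {mode!r}")
    N = dataset.m + dataset.n
    if not 0 <= row_voxel < N:
        raise ValueError(f"row_voxel {row_voxel} outside stacked range 0..{N - 1}")
    design, responses, obs_trial, obs_time, pidx = lagged_arrays(dataset, order)
    return RegressionProblem(
        design=design,
        response=responses[:, row_voxel].copy(),
        predictor_index=pidx,
        obs_trial=obs_trial,
        obs_time=obs_time,
        mode=mode,
    )


def znormalize(values: np.ndarray) -> np.ndarray:
    """Standardize to mean 0 and unit sample (n−1) standard deviation."""
    a = np.asarray(values, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 values to normalize")
    sd = a.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance normalization")
    return (a - a.mean()) / sd
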