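"""Sparse random VAR(1) simulation models and pseudo-voxel data generation.

The simulation schedule is a packaged table of 56 models over two
pseudo-regions (m = 30 X-voxels, n = 50 Y-voxels).  Each model fixes, per
coupling block, the fraction of non-zero coefficients; connection density
rises roughly every 8 models from ~0.05 to ~0.29.  Non-zero coefficients
are drawn from zero-mean normals with block-specific scales (0.08 within
regions, 0.2 for Y→X, 0.1 for X→Y) and the series are driven by an i.i.d.
Gaussian innovation process with standard deviation 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .datasets import BLOCKS, MvarModel, PairedRoiDataset, submatrix_view
from .summarize import SummaryStats, block_summaries

__all__ = [
    "DensitySpec",
    "density_schedule",
    "schedule_spec",
    "build_simulation_model",
    "iterate_model",
    "model_truth_summary",
]

N_MODELS = 56
_SCHEDULE: pd.DataFrame | None = None


@dataclass
class DensitySpec:
    """Density and scale parameters of one simulation model.

    ``frac_*`` give the fraction of non-zero coefficients per coupling
    block; ``sd_*`` the normal scale of the non-zero draws.  Defaults are
    the study conditions: 30 X-voxels, 50 Y-voxels, within-region scale
    0.08, Y→X scale 0.2, X→Y scale 0.1.
    """

    model_id: int
    frac_xx: float
    frac_yy: float
    frac_yx: float
    frac_xy: float
    sd_xx: float = 0.08
    sd_yy: float = 0.08
    sd_yx: float = 0.2
    sd_xy: float = 0.1
    m: int = 30
    n: int = 50

    def __post_init__(self) -> None:
        for name in BLOCKS:
            frac = getattr(self, f"frac_{name}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"frac_{name}={frac} outside [0, 1]")
            if getattr(self, f"sd_{name}") <= 0:
                raise ValueError(f"sd_{name} must be positive")
        if self.m < 1 or self.n < 1:
            raise ValueError("voxel counts must be >= 1")

    def block_shape(self, block: str) -> tuple[int, int]:
        """(rows=receivers, cols=senders) of one coupling block."""
        return {
            "xx": (self.m, self.m),
            "yy": (self.n, self.n),
            "yx": (self.m, self.n),
            "xy": (self.n, self.m),
        }[block]

    def nonzero_count(self, block: str) -> int:
        rows, cols = self.block_shape(block)
        return int(round(getattr(self, f"frac_{block}") * rows * cols))


def density_schedule() -> pd.DataFrame:
    """The packaged 56-model density schedule, indexed by model_id."""
    global _SCHEDULE
    if _SCHEDULE is None:
        with resources.files("voxgc.data").joinpath("density_schedule.csv").open() as fh:
            _SCHEDULE = pd.read_csv(fh).set_index("model_id")
    return _SCHEDULE


def schedule_spec(model_id: int, **overrides) -> DensitySpec:
    """Density spec for one of the 56 scheduled simulation models."""
    if not 1 <= int(model_id) <= N_MODELS:
        raise ValueError(f"unknown simulation model {model_id}; ids run 1..{N_MODELS}")
    row = density_schedule().loc[int(model_id)]
    return DensitySpec(
        model_id=int(model_id),
        frac_xx=float(row["frac_xx"]),
        frac_yy=float(row["frac_yy"]),
        frac_yx=float(row["frac_yx"]),
        frac_xy=float(row["frac_xy"]),
        **overrides,
    )


def build_simulation_model(
    spec: DensitySpec,
    seed: int,
    require_stable: bool = True,
    max_redraws: int = 100,
) -> MvarModel:
    """Draw a sparse random VAR(1) coefficient matrix matching ``spec``.

    Per block, exactly ``round(frac × rows × cols)`` entries at uniformly
    random positions (diagonal included for the within-region blocks) are
    drawn i.i.d. normal(0, block scale); the rest are exactly zero.  With
    ``require_stable`` the draw is repeated until the spectral radius of
    the coefficient matrix is below 1, up to ``max_redraws`` extra
    attempts.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    d = spec.m + spec.n
    for _ in range(max_redraws + 1):
        B = np.zeros((d, d))
        for block in BLOCKS:
            rows, cols = spec.block_shape(block)
            count = spec.nonzero_count(block)
            view = submatrix_view(B, (spec.m, spec.n), block)
            if count:
                flat = rng.choice(rows * cols, size=count, replace=False)
                ri, ci = np.unravel_index(flat, (rows, cols))
                view[ri, ci] = rng.normal(0.0, getattr(spec, f"sd_{block}"), size=count)
        model = MvarModel(coeffs=[B], partition=(spec.m, spec.n), innovation_sd=0.1)
        if not require_stable or model.is_stable():
            return model
    raise RuntimeError(
        f"unstable model: no stable draw for spec {spec.model_id} in {max_redraws + 1} attempts"
    )


def iterate_model(
    model: MvarModel,
    T: int = 200,
    seed: int = 0,
    burn_in: int = 0,
) -> PairedRoiDataset:
    """Iterate a VAR model to produce a pseudo-voxel dataset of length T.

    The state is initialized with draws from normal(0, 0.1); each step adds
    an innovation drawn normal(0, ``model.innovation_sd``).  The first
    ``burn_in`` generated points are discarded.  An overflow guard aborts
    when any value exceeds 1e12 in magnitude (unstable models diverge).
    """
    p, d = model.order, model.size
    if T < p + 1:
        raise ValueError(f"T={T} too short for order {p}")
    rng = np.random.default_rng(seed)
    history = [rng.normal(0.0, 0.1, size=d) for _ in range(p)]
    out = np.empty((d, burn_in + T))
    for t in range(burn_in + T):
        z = rng.normal(0.0, model.innovation_sd, size=d)
        for k in range(1, p + 1):
            z += model.coeffs[k - 1] @ history[-k]
        if np.max(np.abs(z)) > 1e12:
            raise RuntimeError(f"simulation diverged at step {t}")
        out[:, t] = z
        history.append(z)
        history = history[-p:]
    out = out[:, burn_in:]
    m, _ = model.partition
    return PairedRoiDataset(x_series=out[:m], y_series=out[m:])


def model_truth_summary(model: MvarModel, normalize_w: bool = True) -> SummaryStats:
    """Ground-truth f and W computed directly from a model's coefficients.

    Truth f per block is the fraction of non-zero coefficients; truth W
    applies the same receiver-sum formula as the estimators to the
    z-normalized coefficient values with "significant" meaning non-zero,
    through the identical code path used for estimates.
    """
    if model.order != 1:
        raise ValueError("truth summaries are defined for order-1 models")
    B = model.coeffs[0]
    f, W, nsig = block_summaries(
        B, B != 0, model.partition, normalize_w=normalize_w, include_diagonal=True
    )
    return SummaryStats(f=f, W=W, n_significant=nsig, alpha=None, fdr_applied=False)
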