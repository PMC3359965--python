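"""Dataset and report readers/writers plus run configuration.

Two on-disk dataset formats are supported: a NumPy ``.npz`` container with
named arrays ``x`` (m×T×R) and ``y`` (n×T×R), and a delimited text table
with one voxel per row and columns ``roi``, ``voxel``, ``trial``,
``t0..t{T-1}``.  Reports are JSON with a verbatim configuration echo.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import PairedRoiDataset

__all__ = ["RunConfig", "read_dataset", "write_dataset", "write_report", "estimates_to_edges"]


@dataclass
class RunConfig:
    """Validated settings echoed verbatim into every report."""

    seed: int = 0
    order: int = 1
    alpha: float = 0.05
    fdr: bool = True
    mode: str = "pooled_time"
    n_grid: int = 100
    require_stable: bool = True

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.mode not in ("pooled_time", "across_trials"):
            raise ValueError(f"unknown assembly mode {self.mode!r}")
        if self.n_grid < 2:
            raise ValueError("n_grid must be >= 2")

    def as_dict(self) -> dict:
        return asdict(self)


def write_dataset(dataset: PairedRoiDataset, path: str | Path, fmt: str | None = None) -> None:
    """Write a dataset as ``.npz`` (default) or delimited CSV."""
    path = Path(path)
    fmt = fmt or ("delimited" if path.suffix.lower() in (".csv", ".tsv", ".txt") else "npz")
    if fmt == "npz":
        np.savez(
            path,
            x=dataset.x_series,
            y=dataset.y_series,
            x_ids=np.array(dataset.x_voxel_ids),
            y_ids=np.array(dataset.y_voxel_ids),
            roi_labels=np.array(dataset.roi_labels),
        )
        return
    if fmt != "delimited":
        raise ValueError(f"unknown format {fmt!r}")
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    T = dataset.n_timepoints
    rows = []
    for roi, series, ids in (
        (dataset.roi_labels[0], dataset.x_series, dataset.x_voxel_ids),
        (dataset.roi_labels[1], dataset.y_series, dataset.y_voxel_ids),
    ):
        for v in range(series.shape[0]):
            for r in range(series.shape[2]):
                rows.append([roi, ids[v], r, *series[v, :, r]])
    cols = ["roi", "voxel", "trial"] + [f"t{t}" for t in range(T)]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False)


def read_dataset(path: str | Path, fmt: str | None = None) -> PairedRoiDataset:
    """Read a dataset written by :func:`write_dataset` (either format)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or ("npz" if path.suffix.lower() == ".npz" else "delimited")
    if fmt == "npz":
        with np.load(path, allow_pickle=False) as z:
            labels = tuple(str(v) for v in z["roi_labels"]) if "roi_labels" in z else ("X", "Y")
            return PairedRoiDataset(
                x_series=z["x"],
                y_series=z["y"],
                roi_labels=labels,
                x_voxel_ids=[str(v) for v in z["x_ids"]] if "x_ids" in z else [],
                y_voxel_ids=[str(v) for v in z["y_ids"]] if "y_ids" in z else [],
            )
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep)
    for col in ("roi", "voxel", "trial"):
        if col not in df.columns:
            raise ValueError(f"delimited dataset missing column {col!r}")
    tcols = [c for c in df.columns if c.startswith("t") and c[1:].isdigit()]
    tcols.sort(key=lambda c: int(c[1:]))
    rois = list(dict.fromkeys(df["roi"]))
    if len(rois) != 2:
        raise ValueError(f"expected exactly 2 ROI labels, found {rois}")
    series, ids = [], []
    for roi in rois:
        sub = df[df["roi"] == roi]
        voxels = list(dict.fromkeys(sub["voxel"]))
        trials = sorted(sub["trial"].unique())
        arr = np.empty((len(voxels), len(tcols), len(trials)))
        for vi, vox in enumerate(voxels):
            for ri, tr in enumerate(trials):
                sel = sub[(sub["voxel"] == vox) & (sub["trial"] == tr)]
                if len(sel) != 1:
                    raise ValueError(f"voxel {vox!r} trial {tr} not unique in {path}")
                arr[vi, :, ri] = sel[tcols].to_numpy()[0]
        series.append(arr)
        ids.append([str(v) for v in voxels])
    return PairedRoiDataset(
        x_series=series[0], y_series=series[1],
        roi_labels=(str(rois[0]), str(rois[1])),
        x_voxel_ids=ids[0], y_voxel_ids=ids[1],
    )


def estimates_to_edges(estimates, significant: np.ndarray | None = None) -> pd.DataFrame:
    """Tidy edge list (source, target, b, t, p, selected, significant)."""
    N = estimates.b_hat.shape[0]
    m, _ = estimates.partition
    names = [f"X{i}" for i in range(m)] + [f"Y{i}" for i in range(N - m)]
    rows = []
    for i in range(N):
        for j in range(N):
            rows.append({
                "source": names[j],
                "target": names[i],
                "b": estimates.b_hat[i, j],
                "t": estimates.t_scores[i, j],
                "p": estimates.p_values[i, j],
                "selected": bool(estimates.selected[i, j]),
                "significant": bool(significant[i, j]) if significant is not None else None,
            })
    return pd.DataFrame(rows)


def _versions() -> dict:
    import numpy, pandas, scipy, statsmodels

    return {
        "python": sys.version.split()[0],
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "statsmodels": statsmodels.__version__,
    }


def write_report(result: dict, path: str | Path, config: RunConfig | None = None) -> None:
    """JSON report with configuration echo and library versions."""
    payload = {
        "config": config.as_dict() if config is not None else None,
        "versions": _versions(),
        "result": result,
    }

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, np.bool_):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=default) + "\n")
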