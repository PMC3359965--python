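"""ROI-level summary statistics of directed connectivity.

Two scalar summaries condense a matrix of per-coefficient Granger-causality
scores into region-level quantities:

* ``f`` — the fraction of coefficients in a coupling block that are
  significant after multiple-comparison correction; a *density* measure.
* ``W`` — for each receiving voxel with at least one significant input,
  the signed sum of its significant scores, averaged over those receivers;
  a *strength* measure.  Because scores are signed, opposing inputs to the
  same receiver cancel, so W is sensitive to the balance of enhancing and
  suppressing influences as well as to input convergence.

Significance is controlled by Benjamini–Hochberg FDR over the full
coefficient matrix (one family per fitted model); per-block families are
available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import BLOCKS, PairedRoiDataset, submatrix_view

__all__ = [
    "SummaryStats",
    "fdr_mask",
    "f_statistic",
    "w_statistic",
    "block_summaries",
    "summarize_estimates",
    "correlation_connectivity",
]


@dataclass
class SummaryStats:
    """f and W per coupling block, with the significance settings used."""

    f: dict[str, float]
    W: dict[str, float]
    n_significant: dict[str, int]
    alpha: float | None = 0.05
    fdr_applied: bool = True
    include_diagonal: bool = True
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "f": dict(self.f),
            "W": dict(self.W),
            "n_significant": {k: int(v) for k, v in self.n_significant.items()},
            "alpha": self.alpha,
            "fdr_applied": self.fdr_applied,
            "include_diagonal": self.include_diagonal,
        }


def fdr_mask(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection mask at level ``q``.

    The whole array is one family; entries with p = 1 (e.g. predictors the
    selection stage never admitted) count toward the family size.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros_like(p, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)


def f_statistic(mask: np.ndarray) -> float:
    """Fraction of significant entries: count(True) / size."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("empty mask")
    return float(mask.mean())


def znormalize_scores(scores: np.ndarray) -> np.ndarray:
    """Z-score the non-zero, finite entries of a score matrix in place of a copy.

    Exact zeros mark entries that were never estimated (not pre-selected);
    they are excluded from the moment computation and stay zero.  Infinite
    sentinels (perfect fits) are likewise excluded, with a warning.
    """
    scores = np.array(scores, dtype=float)
    finite = np.isfinite(scores)
    if not finite.all():
        warnings.warn("infinite scores excluded from z-normalization", stacklevel=2)
    pop = finite & (scores != 0)
    if pop.sum() >= 2:
        sd = scores[pop].std(ddof=1)
        if sd > 0:
            scores[pop] = (scores[pop] - scores[pop].mean()) / sd
    return scores


def w_statistic(scores: np.ndarray, mask: np.ndarray, normalize: bool = False) -> float:
    """Average significant input strength over receiving voxels.

    ``scores`` is oriented receiver-rows × sender-columns.  Each receiver
    (row) with at least one significant entry contributes the sum of its
    significant scores; W is the mean of those row sums, or 0 when no
    receiver has a significant input.
    """
    scores = np.asarray(scores, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if scores.shape != mask.shape:
        raise ValueError("scores and mask must be congruent")
    if normalize:
        scores = znormalize_scores(scores)
    row_has = mask.any(axis=1)
    if not row_has.any():
        return 0.0
    row_sums = np.where(mask, scores, 0.0).sum(axis=1)
    return float(row_sums[row_has].mean())


def block_summaries(
    scores: np.ndarray,
    mask: np.ndarray,
    partition: tuple[int, int],
    normalize_w: bool = True,
    include_diagonal: bool = True,
) -> tuple[dict[str, float], dict[str, float], dict[str, int]]:
    """Per-block f, W and significant counts from a full score matrix.

    When ``normalize_w``, scores are z-normalized once over the full
    matrix's non-zero entries before the per-block W row sums, so truth
    summaries and estimates pass through the identical code path on the
    same scale.  (Normalizing each block over its own non-zero entries
    would be degenerate for truth summaries: the significant set then
    equals the normalization population and every block's W collapses to
    exactly zero.)  The diagonal (self-lag) entries of the within-region
    blocks are counted by default; ``include_diagonal=False`` removes them
    from both the numerator and the denominator of f and from the W row
    sums.
    """
    w_scores = znormalize_scores(scores) if normalize_w else np.asarray(scores, dtype=float)
    f, W, nsig = {}, {}, {}
    for block in BLOCKS:
        bmask = submatrix_view(np.asarray(mask, dtype=bool), partition, block)
        bscore = submatrix_view(w_scores, partition, block)
        if not include_diagonal and block in ("xx", "yy"):
            off = ~np.eye(bmask.shape[0], dtype=bool)
            f[block] = float(bmask[off].mean()) if off.any() else 0.0
            nsig[block] = int(bmask[off].sum())
            bmask = bmask & off
        else:
            f[block] = f_statistic(bmask)
            nsig[block] = int(bmask.sum())
        W[block] = w_statistic(bscore, bmask)
    return f, W, nsig


def summarize_estimates(
    estimates,
    q: float = 0.05,
    fdr: bool = True,
    family: str = "selected",
    normalize_w: bool = True,
    include_diagonal: bool = True,
) -> SummaryStats:
    """Summarize a fitted coefficient matrix into per-block f and W.

    ``estimates`` is a :class:`~voxgc.gcfit.CoefficientEstimates`.  The
    FDR family defaults to the hypotheses actually tested — the selected
    entries (``family="selected"``); for estimators without a selection
    stage this equals the full matrix.  ``family="full"`` forces the whole
    (m+n)² matrix into the family (never-tested entries counting with
    p = 1); ``family="per_block"`` corrects each coupling block separately.
    """
    p = estimates.p_values
    if fdr:
        if family == "selected":
            mask = np.zeros_like(p, dtype=bool)
            sel = np.asarray(estimates.selected, dtype=bool)
            if sel.any():
                mask[sel] = fdr_mask(p[sel], q)
        elif family == "full":
            mask = fdr_mask(p, q)
        elif family == "per_block":
            mask = np.zeros_like(p, dtype=bool)
            for block in BLOCKS:
                sub = submatrix_view(p, estimates.partition, block)
                submatrix_view(mask, estimates.partition, block)[:] = fdr_mask(sub, q)
        else:
            raise ValueError(f"unknown FDR family {family!r}")
    else:
        mask = p < q
    f, W, nsig = block_summaries(
        estimates.t_scores, mask, estimates.partition,
        normalize_w=normalize_w, include_diagonal=include_diagonal,
    )
    return SummaryStats(
        f=f, W=W, n_significant=nsig, alpha=q, fdr_applied=fdr,
        include_diagonal=include_diagonal,
    )


def correlation_connectivity(
    dataset: PairedRoiDataset,
    q: float = 0.05,
    restrict_to: np.ndarray | None = None,
    fdr: bool = True,
):
    """Zero-lag Pearson correlation between every voxel pair, with f and W.

    Observations pool all time points of all trials.  Significance uses the
    t transform of r with N−2 degrees of freedom, FDR-corrected over the
    family of unordered off-diagonal pairs (optionally restricted to a
    supplied selection mask).  f and W treat the symmetric correlation
    matrix as receiver-rows × sender-columns with the diagonal excluded;
    W uses the raw correlation coefficients (no z-normalization).

    Returns ``(corr, significant, stats)``.
    """
    z = dataset.stacked().reshape(dataset.m + dataset.n, -1)
    nobs = z.shape[1]
    if nobs < 3:
        raise ValueError("need at least 3 pooled observations for correlation tests")
    corr = np.corrcoef(z)
    N = corr.shape[0]

    iu = np.triu_indices(N, k=1)
    in_family = np.ones(len(iu[0]), dtype=bool)
    if restrict_to is not None:
        restrict_to = np.asarray(restrict_to, dtype=bool)
        sym = restrict_to | restrict_to.T
        in_family = sym[iu]
    r = np.clip(corr[iu], -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((nobs - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df=nobs - 2)
    p[np.abs(r) >= 1.0] = 0.0

    sig_pairs = np.zeros(len(p), dtype=bool)
    if in_family.any():
        fam_p = p[in_family]
        sig_pairs[in_family] = fdr_mask(fam_p, q) if fdr else fam_p < q
    significant = np.zeros((N, N), dtype=bool)
    significant[iu] = sig_pairs
    significant |= significant.T

    f, W, nsig = block_summaries(
        corr, significant, (dataset.m, dataset.n),
        normalize_w=False, include_diagonal=False,
    )
    stats_out = SummaryStats(
        f=f, W=W, n_significant=nsig, alpha=q, fdr_applied=fdr, include_diagonal=False,
    )
    return corr, significant, stats_out
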