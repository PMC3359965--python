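import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import voxgc as v
from voxgc.summarize import block_summaries, znormalize_scores


def bh_bruteforce(p, q):
    """Step-up BH by direct enumeration of the largest admissible k."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    mask = np.zeros(m, dtype=bool)
    mask[order[:k_star]] = True
    return mask


class TestFdrMask:
    def test_worked_example_all_rejected(self):
        mask = v.fdr_mask(np.array([0.001, 0.013, 0.02, 0.04]), q=0.05)
        assert mask.all()

    def test_all_ones_rejects_none(self):
        assert not v.fdr_mask(np.ones((3, 3))).any()

    def test_single_test_reduces_to_plain_level(self):
        assert v.fdr_mask(np.array([0.04]), q=0.05).all()
        assert not v.fdr_mask(np.array([0.06]), q=0.05).any()

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20),
           st.sampled_from([0.01, 0.05, 0.1, 0.25]))
    def test_matches_bruteforce_stepup(self, ps, q):
        p = np.array(ps)
        np.testing.assert_array_equal(v.fdr_mask(p, q), bh_bruteforce(p, q))


class TestFStatistic:
    @pytest.mark.parametrize("n_true, size, expected", [(3, 12, 0.25), (0, 8, 0.0), (6, 6, 1.0)])
    def test_fraction(self, n_true, size, expected):
        mask = np.zeros(size, dtype=bool)
        mask[:n_true] = True
        assert v.f_statistic(mask) == expected


class TestWStatistic:
    def test_worked_example(self):
        # receiver 1: {+2.5, −1.0}; receiver 2: {+3.0}; receiver 3: none
        scores = np.array([[2.5, -1.0, 0.0],
                           [3.0, 0.0, 0.0],
                           [0.0, 0.0, 0.0]])
        mask = scores != 0
        assert v.w_statistic(scores, mask) == pytest.approx(2.25)

    def test_balanced_inputs_cancel(self):
        scores = np.array([[2.0, -2.0]])
        assert v.w_statistic(scores, scores != 0) == 0.0

    def test_no_significant_inputs(self):
        assert v.w_statistic(np.ones((3, 3)), np.zeros((3, 3), dtype=bool)) == 0.0

    def test_linear_in_scores_given_mask(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=(5, 6))
        mask = rng.random((5, 6)) < 0.3
        w1 = v.w_statistic(scores, mask)
        w3 = v.w_statistic(3.0 * scores, mask)
        assert w3 == pytest.approx(3.0 * w1)

    def test_f_invariant_under_normalization(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=(6, 6)) * (rng.random((6, 6)) < 0.5)
        mask = scores != 0
        assert v.f_statistic(mask) == v.f_statistic(znormalize_scores(scores) != 0)

    def test_truth_and_estimate_share_code_path(self):
        # truth-W of a model equals w_statistic on its z-scored b values
        rng = np.random.default_rng(2)
        B = rng.normal(0, 0.1, (6, 6)) * (rng.random((6, 6)) < 0.4)
        model = v.MvarModel(coeffs=[B], partition=(3, 3))
        truth = v.model_truth_summary(model)
        f, W, _ = block_summaries(B, B != 0, (3, 3), normalize_w=True)
        for blk in ("xx", "yy", "yx", "xy"):
            assert truth.W[blk] == W[blk]
            assert truth.f[blk] == f[blk]


class TestSummarizeEstimates:
    def test_counts_match_f(self, small_dataset):
        _, data = small_dataset
        est = v.fit_pairwise_gc(data)
        stats = v.summarize_estimates(est, q=0.05)
        sizes = {"xx": 9, "yy": 16, "yx": 12, "xy": 12}
        for blk, size in sizes.items():
            assert stats.n_significant[blk] == pytest.approx(stats.f[blk] * size)

    def test_exclude_diagonal_changes_denominator(self, small_dataset):
        _, data = small_dataset
        est = v.fit_pairwise_gc(data)
        incl = v.summarize_estimates(est, include_diagonal=True)
        excl = v.summarize_estimates(est, include_diagonal=False)
        # self-lag AR terms are strongly significant, so excluding them lowers f
        assert excl.f["xx"] <= incl.f["xx"]

    def test_family_options_nest(self, small_dataset):
        _, data = small_dataset
        est = v.fit_lasso_gc(data, seed=4, split="none")
        n_sel = {
            fam: sum(v.summarize_estimates(est, family=fam).n_significant.values())
            for fam in ("selected", "full", "per_block")
        }
        # the full-matrix family (never-tested entries at p=1) is the strictest
        assert n_sel["full"] <= n_sel["selected"]


class TestCorrelationConnectivity:
    def test_diagonal_excluded_and_symmetric(self, small_dataset):
        _, data = small_dataset
        corr, sig, stats = v.correlation_connectivity(data)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        np.testing.assert_allclose(corr, corr.T, atol=1e-12)
        assert not sig[np.diag_indices(7)].any()
        assert stats.include_diagonal is False

    def test_duplicated_voxel_is_significant(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(1, 100))
        y = np.vstack([x[0] + rng.normal(0, 1e-6, 100), rng.normal(size=100)])
        data = v.PairedRoiDataset(x, y)
        corr, sig, _ = v.correlation_connectivity(data)
        assert corr[0, 1] == pytest.approx(1.0, abs=1e-6)
        assert sig[0, 1]

    def test_null_uncorrected_rate(self):
        null = v.MvarModel(coeffs=[np.zeros((10, 10))], partition=(5, 5), innovation_sd=0.1)
        rates = []
        for s in range(30):
            data = v.iterate_model(null, T=300, seed=400 + s)
            _, sig, _ = v.correlation_connectivity(data, fdr=False)
            iu = np.triu_indices(10, 1)
            rates.append(sig[iu].mean())
        assert np.mean(rates) == pytest.approx(0.05, abs=0.02)

    def test_restriction_shrinks_family(self, small_dataset):
        _, data = small_dataset
        restrict = np.zeros((7, 7), dtype=bool)
        restrict[0, 1] = True
        _, sig, _ = v.correlation_connectivity(data, restrict_to=restrict)
        allowed = np.zeros((7, 7), dtype=bool)
        allowed[0, 1] = allowed[1, 0] = True
        assert not sig[~allowed].any()
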