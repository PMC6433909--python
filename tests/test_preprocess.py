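import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ks_2samp

from methcrossover import FilterPolicy, filter_calls, histogram_transform, normalize_coverage
from methcrossover.io import MethylationCallSet


def _callset(sample_id, chrom, pos, coverage, n_meth=None):
    coverage = np.asarray(coverage)
    if n_meth is None:
        n_meth = coverage // 2
    return MethylationCallSet(
        sample_id,
        pd.DataFrame(
            {
                "chrom": chrom,
                "pos": pos,
                "strand": ".",
                "coverage": coverage,
                "n_meth": np.asarray(n_meth),
            }
        ),
    )


class TestFilterCalls:
    def test_low_coverage_removed(self):
        cs = _callset("s", ["chr1"] * 3, [10, 20, 30], [4, 5, 50])
        out = filter_calls(cs, FilterPolicy(max_coverage_quantile=1.0))
        assert set(out.data["pos"]) == {20, 30}

    def test_sex_and_mito_chromosomes_removed_by_default(self):
        cs = _callset("s", ["chr1", "chrX", "chrY", "chrM"], [1, 2, 3, 4], [10] * 4)
        out = filter_calls(cs, FilterPolicy())
        assert list(out.data["chrom"]) == ["chr1"]

    def test_top_quantile_outlier_removed(self):
        """10,000 sites, one far above the 99.9th percentile: only it drops."""
        rng = np.random.default_rng(0)
        coverage = rng.integers(5, 50, size=10_000)
        coverage[1234] = 10_000
        cs = _callset("s", "chr1", np.arange(10_000) * 10, coverage)
        hi = np.quantile(coverage, 0.999)
        expected = int(((coverage >= 5) & (coverage <= hi)).sum())
        out = filter_calls(cs, FilterPolicy())
        assert 1234 * 10 not in set(out.data["pos"])
        assert len(out) == expected == 9_999

    def test_filtering_is_idempotent(self, small_cohort):
        """Coverage-floor and chromosome filters are exactly idempotent;
        the percentile cap, recomputed from the surviving sites, may shave
        at most its nominal tail fraction again."""
        _, calls, _, _ = small_cohort
        policy = FilterPolicy(max_coverage_quantile=1.0)
        once = filter_calls(calls[0], policy)
        twice = filter_calls(once, policy)
        pd.testing.assert_frame_equal(once.data, twice.data)

        full = FilterPolicy()
        first = filter_calls(calls[0], full)
        second = filter_calls(first, full)
        assert len(first) - len(second) <= np.ceil(0.001 * len(first))

    def test_empty_result_warns(self):
        cs = _callset("s", ["chrX"], [1], [10])
        with pytest.warns(UserWarning, match="no sites"):
            out = filter_calls(cs, FilterPolicy())
        assert len(out) == 0


class TestNormalizeCoverage:
    def test_identical_samples_unchanged(self):
        a = _callset("a", "chr1", [1, 2, 3], [10, 10, 10])
        b = _callset("b", "chr1", [1, 2, 3], [10, 10, 10])
        out = normalize_coverage([a, b])
        for o, i in zip(out, (a, b)):
            pd.testing.assert_frame_equal(o.data, i.data)

    def test_scaling_toward_grand_median(self):
        """Medians 10 and 20 -> grand median 15 -> sample B scaled by 0.75."""
        a = _callset("a", "chr1", [1, 2, 3], [10, 10, 10], [5, 5, 5])
        b = _callset("b", "chr1", [1, 2, 3], [20, 20, 20], [10, 10, 10])
        out = normalize_coverage([a, b])
        assert list(out[0].data["coverage"]) == [15, 15, 15]
        assert list(out[1].data["coverage"]) == [15, 15, 15]  # 20 * 0.75
        assert list(out[1].data["n_meth"]) == [8, 8, 8]  # beta 0.5 kept (rounded)

    def test_beta_preserved_within_rounding(self, small_cohort):
        _, calls, _, _ = small_cohort
        out = normalize_coverage(calls)
        for before, after in zip(calls, out):
            db = (before.beta - after.beta).abs()
            assert (db <= 1.0 / after.data["coverage"]).all()


class TestHistogramTransform:
    def test_identity_when_distributions_match(self):
        rng = np.random.default_rng(1)
        cov = np.full(2000, 100)
        meth = rng.binomial(100, rng.uniform(0.05, 0.95, 2000))
        case = _callset("case", "chr1", np.arange(2000), cov, meth)
        ctrl = _callset("ctrl", "chr1", np.arange(2000), cov.copy(), meth.copy())
        (out,) = histogram_transform([case], [ctrl])
        # mapping through the pooled-control ECDF moves beta by at most one step
        assert (out.beta - case.beta).abs().max() <= 1.0 / 2000 + 1.0 / 100

    def test_shift_reduces_ks_distance(self):
        """Case betas shifted +0.1: the transform pulls them back onto control."""
        rng = np.random.default_rng(2)
        n = 5000
        cov = np.full(n, 200)
        p = rng.uniform(0.1, 0.7, n)
        ctrl = _callset("ctrl", "chr1", np.arange(n), cov, rng.binomial(200, p))
        case = _callset("case", "chr1", np.arange(n), cov.copy(), rng.binomial(200, p + 0.1))
        (out,) = histogram_transform([case], [ctrl])
        ks_before = ks_2samp(case.beta, ctrl.beta).statistic
        ks_after = ks_2samp(out.beta, ctrl.beta).statistic
        assert ks_after < ks_before

    def test_total_variation_after_transform(self):
        rng = np.random.default_rng(3)
        n = 5000
        cov = np.full(n, 200)
        p = rng.uniform(0.1, 0.7, n)
        ctrl = _callset("ctrl", "chr1", np.arange(n), cov, rng.binomial(200, p))
        case = _callset("case", "chr1", np.arange(n), cov.copy(), rng.binomial(200, p + 0.1))
        (out,) = histogram_transform([case], [ctrl])
        bins = np.linspace(0, 1, 21)
        h_case, _ = np.histogram(out.beta, bins=bins)
        h_ctrl, _ = np.histogram(ctrl.beta, bins=bins)
        tv = 0.5 * np.abs(h_case / n - h_ctrl / n).sum()
        assert tv <= 0.05

    def test_rank_order_preserved_up_to_count_rounding(self, small_cohort):
        """The quantile mapping itself is monotone; the only permitted
        inversions in stored betas come from rounding the mapped level to
        an integer methylated count at each site's own coverage."""
        _, calls, sheet, _ = small_cohort
        group_of = dict(zip(sheet["sample_id"], sheet["group"]))
        controls = [c for c in calls if group_of[c.sample_id] == "control"]
        cases = [c for c in calls if group_of[c.sample_id] == "obesity"]
        out = histogram_transform(cases, controls)
        for before, after in zip(cases, out):
            order = np.argsort(before.beta.to_numpy(), kind="stable")
            b = after.beta.to_numpy()[order]
            cov = after.data["coverage"].to_numpy()[order]
            slack = 0.5 / cov[:-1] + 0.5 / cov[1:] + 1e-12
            assert (np.diff(b) >= -slack).all()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        betas=st.lists(st.integers(min_value=0, max_value=50), min_size=3, max_size=40),
    )
    def test_monotonicity_property(self, betas):
        """beta1 <= beta2 implies mapped beta1 <= mapped beta2, any input."""
        cov = np.full(len(betas), 50)
        case = _callset("case", "chr1", np.arange(len(betas)) * 10, cov, np.array(betas))
        rng = np.random.default_rng(0)
        ctrl = _callset("ctrl", "chr1", np.arange(100), np.full(100, 50), rng.integers(0, 51, 100))
        (out,) = histogram_transform([case], [ctrl])
        order = np.argsort(case.beta.to_numpy(), kind="stable")
        assert (np.diff(out.beta.to_numpy()[order]) >= -1e-12).all()

    def test_degenerate_control_rejected(self):
        case = _callset("case", "chr1", [1, 2], [10, 10], [3, 7])
        ctrl = _callset("ctrl", "chr1", [1, 2], [10, 10], [5, 5])
        with pytest.raises(ValueError, match="degenerate"):
            histogram_transform([case], [ctrl])

    def test_empty_control_pool_rejected(self):
        case = _callset("case", "chr1", [1], [10])
        with pytest.raises(ValueError, match="empty"):
            histogram_transform([case], [])
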