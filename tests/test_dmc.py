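import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import chi2, kstest

from methcrossover import DmcThresholds, call_dmcs, significant_dmcs
from methcrossover.dmc import test_site as fit_site
from methcrossover.dmc import _lrt_pvalues
from methcrossover.io import MethylationCallSet


def _site(coverage, n_meth, group, age):
    return pd.DataFrame(
        {"coverage": coverage, "n_meth": n_meth, "group": group, "age": age}
    )


def _statsmodels_lrt(site):
    """Independent oracle: per-site GLM fit via statsmodels."""
    y = site["n_meth"].to_numpy(float)
    n = site["coverage"].to_numpy(float)
    case = (site["group"] != "control").to_numpy(float)
    X = np.column_stack([np.ones(len(site)), case, site["age"].to_numpy(float)])
    endog = np.column_stack([y, n - y])
    full = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
    null = sm.GLM(endog, X[:, [0, 2]], family=sm.families.Binomial()).fit()
    return float(chi2.sf(null.deviance - full.deviance, 1))


class TestTestSite:
    def test_identical_groups_give_null_result(self):
        site = _site([20] * 10, [10] * 10, ["control"] * 5 + ["obesity"] * 5, [40] * 10)
        p, diff = fit_site(site)
        assert diff == 0.0
        assert p > 0.99

    def test_complete_separation_still_yields_tiny_p(self):
        """Case fully methylated (20/20), control fully unmethylated (0/20)."""
        site = _site(
            [20] * 10, [20] * 5 + [0] * 5, ["obesity"] * 5 + ["control"] * 5, [40] * 10
        )
        p, diff = fit_site(site)
        assert diff == 100.0
        assert p < 1e-6
        # cross-check the LRT deviance against the statsmodels oracle
        assert p == pytest.approx(_statsmodels_lrt(site), rel=1e-3, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5, 6, 7])
    def test_agrees_with_statsmodels_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(8, 24))
        n = rng.integers(5, 60, m)
        site = _site(
            n,
            rng.binomial(n, rng.uniform(0.05, 0.95, m)),
            rng.choice(["control", "crc"], m).tolist(),
            rng.normal(45, 12, m),
        )
        if (site["group"] == "control").sum() < 3 or (site["group"] != "control").sum() < 3:
            site.loc[:2, "group"] = "control"
            site.loc[3:5, "group"] = "crc"
        p_mine, _ = fit_site(site)
        assert p_mine == pytest.approx(_statsmodels_lrt(site), rel=1e-6, abs=1e-12)

    def test_label_swap_negates_diff_and_keeps_p(self):
        rng = np.random.default_rng(10)
        n = rng.integers(10, 40, 12)
        site = _site(
            n,
            rng.binomial(n, 0.4),
            ["control"] * 6 + ["obesity"] * 6,
            rng.normal(45, 10, 12),
        )
        p1, d1 = fit_site(site)
        swapped = site.copy()
        swapped["group"] = ["obesity"] * 6 + ["control"] * 6
        p2, d2 = fit_site(swapped)
        assert d2 == pytest.approx(-d1, abs=1e-12)
        assert p2 == pytest.approx(p1, rel=1e-9)

    def test_age_shift_invariance(self):
        rng = np.random.default_rng(11)
        n = rng.integers(10, 40, 12)
        site = _site(
            n, rng.binomial(n, 0.4), ["control"] * 6 + ["obesity"] * 6, rng.normal(45, 10, 12)
        )
        p1, _ = fit_site(site)
        shifted = site.copy()
        shifted["age"] = shifted["age"] + 100.0
        p2, _ = fit_site(shifted)
        assert p2 == pytest.approx(p1, rel=1e-6)

    def test_null_pvalues_uniform(self):
        """10,000 null binomial sites: p ~ Uniform(0,1), KS < 0.05."""
        rng = np.random.default_rng(42)
        S = 10_000
        n = np.full((S, 10), 30.0)
        y = rng.binomial(30, 0.3, size=(S, 10)).astype(float)
        X = np.column_stack(
            [np.ones(10), np.r_[np.ones(5), np.zeros(5)], rng.normal(45, 10, 10)]
        )
        p, ok = _lrt_pvalues(y, n, n > 0, X, 1)
        assert ok.all()
        assert kstest(p, "uniform").statistic < 0.05


class TestCallDmcs:
    def test_effect_and_q_thresholds_enforced(self):
        table = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "pos": [1, 2, 3],
                "meth_diff": [9.9, 50.0, 15.0],
                "qvalue": [0.001, 0.06, 0.01],
            }
        )
        thr = DmcThresholds()
        sig = (table["meth_diff"].abs() >= thr.min_diff_pct) & (table["qvalue"] < thr.max_q)
        # below-effect site and above-q site are rejected regardless of the other criterion
        assert list(sig) == [False, False, True]

    def test_call_dmcs_respects_both_thresholds(self, small_cohort):
        _, calls, sheet, _ = small_cohort
        tab = call_dmcs(calls, sheet, "obesity")
        sig = significant_dmcs(tab)
        assert (sig["meth_diff"].abs() >= 10).all()
        assert (sig["qvalue"] < 0.05).all()
        not_sig = tab[tab["significant"] == 0]
        assert ((not_sig["meth_diff"].abs() < 10) | (not_sig["qvalue"] >= 0.05)).all()

    def test_direction_matches_sign(self, small_cohort):
        _, calls, sheet, _ = small_cohort
        tab = call_dmcs(calls, sheet, "crc")
        assert ((tab["meth_diff"] > 0) == (tab["direction"] == "hyper")).all()

    def test_sorted_by_position(self, small_cohort):
        _, calls, sheet, _ = small_cohort
        tab = call_dmcs(calls, sheet, "obesity")
        assert tab.equals(tab.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True))

    def test_min_per_group_skips_thin_sites(self, small_cohort):
        """Dropping a site from most control samples removes it from testing."""
        _, calls, sheet, _ = small_cohort
        group_of = dict(zip(sheet["sample_id"], sheet["group"]))
        target = (calls[0].data.loc[0, "chrom"], calls[0].data.loc[0, "pos"])
        mutated = []
        dropped = 0
        for c in calls:
            d = c.data
            if group_of[c.sample_id] == "control" and dropped < 4:
                d = d[~((d["chrom"] == target[0]) & (d["pos"] == target[1]))]
                dropped += 1
            mutated.append(MethylationCallSet(c.sample_id, d.reset_index(drop=True)))
        tab = call_dmcs(mutated, sheet, "obesity")
        assert not ((tab["chrom"] == target[0]) & (tab["pos"] == target[1])).any()

    def test_recovery_with_planted_sites(self, small_cohort):
        """Planted +/-0.35 effects are found; null sites mostly are not."""
        cfg, calls, sheet, truth = small_cohort
        tab = call_dmcs(calls, sheet, "obesity")
        planted = truth[truth["effect_obese"] != 0]
        hits = 0
        for r in planted.itertuples():
            in_reg = (
                (tab["chrom"] == r.chrom) & (tab["pos"] >= r.start) & (tab["pos"] < r.end)
            )
            hits += tab.loc[in_reg, "significant"].sum() >= 1
        assert hits / len(planted) >= 0.9

    def test_age_covariate_reduces_confounded_false_positives(self):
        """Age shifts methylation and differs by group: the covariate helps."""
        rng = np.random.default_rng(123)
        S, per = 800, 8
        ages = np.r_[rng.normal(40, 5, per), rng.normal(60, 5, per)]  # control vs case
        slope = 0.03
        base = rng.uniform(0.3, 0.7, S)
        logit = np.log(base / (1 - base))[:, None] + slope * (ages - 50.0)[None, :]
        p = 1 / (1 + np.exp(-logit))
        n = np.full((S, 2 * per), 30.0)
        y = rng.binomial(30, p).astype(float)
        X_age = np.column_stack(
            [np.ones(2 * per), np.r_[np.zeros(per), np.ones(per)], ages]
        )
        p_with, _ = _lrt_pvalues(y, n, n > 0, X_age, 1)
        p_without, _ = _lrt_pvalues(y, n, n > 0, X_age[:, [0, 1]], 1)
        assert (p_with < 0.05).mean() < (p_without < 0.05).mean()

    def test_missing_contrast_group_rejected(self, small_cohort):
        _, calls, sheet, _ = small_cohort
        bad_sheet = sheet[sheet["group"] != "crc"].reset_index(drop=True)
        with pytest.raises(ValueError, match="no samples in contrast"):
            call_dmcs(calls, bad_sheet, "crc")
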