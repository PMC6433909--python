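import numpy as np
import pandas as pd
import pytest

from methcrossover import (
    PlantedRegion,
    SimulationConfig,
    make_planted_regions,
    simulate_annotation,
    simulate_expression,
    simulate_methylation,
)


class TestConfigValidation:
    def test_group_below_three_rejected_with_explanation(self):
        with pytest.raises(ValueError, match="three individuals"):
            SimulationConfig(n_obese=2)

    def test_dispersion_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="phi"):
            SimulationConfig(dispersion=1.5)

    @pytest.mark.parametrize(
        "cls,eo,ec",
        [
            ("concordant_hyper", 0.3, -0.3),
            ("concordant_hypo", 0.3, 0.3),
            ("discordant", 0.3, 0.3),
            ("obesity_only", 0.3, 0.1),
        ],
    )
    def test_region_class_must_match_effect_signs(self, cls, eo, ec):
        with pytest.raises(ValueError, match="inconsistent"):
            PlantedRegion("chr1", 0, 300, 5, eo, ec, cls)

    def test_effect_magnitude_capped(self):
        with pytest.raises(ValueError, match="0.6"):
            PlantedRegion("chr1", 0, 300, 5, 0.7, 0.7, "concordant_hyper")


class TestMethylationCohort:
    def test_meth_never_exceeds_coverage(self, small_cohort):
        _, calls, _, _ = small_cohort
        for c in calls:
            assert (c.data["n_meth"] <= c.data["coverage"]).all()
            assert (c.data["coverage"] >= 1).all()

    def test_identical_coordinates_across_samples(self, small_cohort):
        _, calls, _, _ = small_cohort
        first = calls[0].data[["chrom", "pos"]]
        for c in calls[1:]:
            pd.testing.assert_frame_equal(c.data[["chrom", "pos"]], first)

    def test_fixed_seed_reproducible(self):
        cfg = SimulationConfig(n_control=3, n_obese=3, n_crc=3, n_chrom=1, cpg_per_chrom=50, seed=5)
        a_calls, a_sheet, _ = simulate_methylation(cfg)
        b_calls, b_sheet, _ = simulate_methylation(cfg)
        pd.testing.assert_frame_equal(a_sheet, b_sheet)
        for a, b in zip(a_calls, b_calls):
            pd.testing.assert_frame_equal(a.data, b.data)

    def test_truth_table_partitions_planted_regions(self, small_cohort):
        cfg, _, _, truth = small_cohort
        assert len(truth) == len(cfg.planted_regions)
        counts = truth["class"].value_counts()
        assert counts["concordant_hyper"] == 4
        assert counts["concordant_hypo"] == 4
        assert counts["obesity_only"] == 2
        assert counts["crc_only"] == 2
        assert counts["discordant"] == 2

    def test_pooled_fraction_unbiased_without_effects(self):
        """phi->0, flat beta=0.5 background: pooled methylation ~ 0.5."""
        cfg = SimulationConfig(
            n_control=10,
            n_obese=3,
            n_crc=3,
            n_chrom=1,
            cpg_per_chrom=500,
            coverage_mean=100,
            dispersion=1e-9,
            baseline_beta_mixture=((1.0, 5000.0, 5000.0),),
            age_slope=0.0,
            seed=7,
        )
        calls, _, _ = simulate_methylation(cfg)
        tot_m = sum(c.data["n_meth"].sum() for c in calls)
        tot_c = sum(c.data["coverage"].sum() for c in calls)
        assert abs(tot_m / tot_c - 0.5) < 0.005

    def test_group_effect_lands_where_planted(self, small_cohort):
        cfg, calls, sheet, truth = small_cohort
        group_of = dict(zip(sheet["sample_id"], sheet["group"]))
        reg = truth[truth["class"] == "concordant_hyper"].iloc[0]
        betas = {"control": [], "obesity": []}
        for c in calls:
            g = group_of[c.sample_id]
            if g not in betas:
                continue
            d = c.data[
                (c.data["chrom"] == reg["chrom"])
                & (c.data["pos"] >= reg["start"])
                & (c.data["pos"] < reg["end"])
            ]
            betas[g].append((d["n_meth"] / d["coverage"]).mean())
        diff = np.mean(betas["obesity"]) - np.mean(betas["control"])
        assert diff > 0.15  # planted +0.35 shift, allowing clipping/noise


class TestAnnotationGenerator:
    def test_genes_disjoint_with_exons(self):
        cfg = SimulationConfig(n_chrom=1, cpg_per_chrom=200, seed=3)
        ann, _ = simulate_annotation(cfg, genes_per_chrom=10)
        bg = [g for g in ann.genes if g.gene_id.startswith("bg_")]
        assert len(bg) == 10
        spans = sorted(g.span for g in bg)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 >= e1
        assert all(len(g.exons) >= 1 for g in ann.genes)

    def test_island_fraction_zero_gives_no_background_islands(self):
        cfg = SimulationConfig(n_chrom=1, cpg_per_chrom=200, seed=3)
        ann, _ = simulate_annotation(cfg, island_fraction=0.0)
        assert len(ann.islands) == 0

    def test_fixed_seed_reproducible(self, small_cohort):
        cfg, *_ = small_cohort
        a, ta = simulate_annotation(cfg)
        b, tb = simulate_annotation(cfg)
        assert a.genes == b.genes
        pd.testing.assert_frame_equal(a.islands, b.islands)
        pd.testing.assert_frame_equal(ta, tb)

    def test_every_planted_region_has_expected_subregion(self, small_cohort, small_annotation):
        cfg, *_ = small_cohort
        _, truth = small_annotation
        assert len(truth) == len(cfg.planted_regions)
        assert set(truth["expected_subregion"]) <= {"promoter", "exon", "intron", "intergenic"}


class TestExpressionGenerator:
    def test_zero_effects_give_balanced_conditions(self):
        counts, _ = simulate_expression(300, library_spread=0.0, seed=2)
        logm = np.log2(counts + 0.5)
        diff = logm[["DKO_1", "DKO_2"]].mean(axis=1) - logm[["WT_1", "WT_2"]].mean(axis=1)
        assert abs(diff.mean()) < 0.05

    def test_lfc_two_doubles_ratio_four(self):
        """A +2 log2 fold change yields ~4x counts at high expression."""
        eff = {f"gene{i + 1:04d}": 2.0 for i in range(1000)}
        counts, _ = simulate_expression(
            1000, effect_table=eff, mean_log2_range=(8.0, 8.0), library_spread=0.0, seed=4
        )
        ratio = counts[["DKO_1", "DKO_2"]].to_numpy().mean() / counts[["WT_1", "WT_2"]].to_numpy().mean()
        assert abs(ratio - 4.0) < 0.25

    def test_fixed_seed_reproducible(self):
        a, _ = simulate_expression(50, seed=9)
        b, _ = simulate_expression(50, seed=9)
        pd.testing.assert_frame_equal(a, b)
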