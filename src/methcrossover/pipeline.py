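"""End-to-end orchestration: simulate (or load) -> preprocess -> DMC x2
-> DMR x2 -> overlap -> annotate -> select -> enrich -> expression.

Every stage is a pure function of its inputs plus the config seed, so a
rerun with the same config reproduces every report byte for byte.  The
summary JSON aggregates the headline quantities: Venn counts, direction
quadrants, chi-square association, overlap fractions and selection
counts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann_mod
from . import dmc as dmc_mod
from . import dmr as dmr_mod
from . import enrichment as enr_mod
from . import expression as expr_mod
from . import io as io_mod
from . import overlap as ov_mod
from . import preprocess as pre_mod
from . import selection as sel_mod
from . import simulate as sim_mod

log = logging.getLogger("methcrossover")

_TOP_KEYS = {
    "seed", "simulate", "filter", "preprocess", "dmc", "dmr",
    "overlap", "select", "enrichment", "expression", "inputs",
}
_SIM_KEYS = {
    "n_control", "n_obese", "n_crc", "n_chrom", "cpg_per_chrom",
    "coverage_mean", "dispersion", "age_slope",
    "regions_per_class", "region_cpgs", "effect",
}
_FILTER_KEYS = {"min_coverage", "max_coverage_quantile", "excluded_chroms"}
_PRE_KEYS = {"do_histogram_transform", "normalize_coverage"}
_DMC_KEYS = {"min_diff_pct", "max_q", "min_per_group", "covariate"}
_DMR_KEYS = {"min_cpgs", "min_dmcs", "min_abs_mean_diff"}
_OV_KEYS = {"min_overlap_bp"}
_SEL_KEYS = {"alpha_margin"}
_ENR_KEYS = {"gmt"}
_EXPR_KEYS = {"n_genes", "lfc_magnitude"}
_INPUT_KEYS = {"coverage_files", "sample_sheet", "genes", "islands"}

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {
        "n_control": 8,
        "n_obese": 8,
        "n_crc": 8,
        "n_chrom": 3,
        "cpg_per_chrom": 400,
        "coverage_mean": 30,
        "dispersion": 0.02,
        "age_slope": 0.002,
        "regions_per_class": {
            "concordant_hyper": 8,
            "concordant_hypo": 8,
            "obesity_only": 4,
            "crc_only": 4,
            "discordant": 4,
        },
        "region_cpgs": 5,
        "effect": 0.35,
    },
    "filter": {"min_coverage": 5, "max_coverage_quantile": 0.999},
    "preprocess": {"do_histogram_transform": True, "normalize_coverage": True},
    "dmc": {"min_diff_pct": 10.0, "max_q": 0.05, "min_per_group": 3, "covariate": "age"},
    "dmr": {"min_cpgs": 3, "min_dmcs": 1, "min_abs_mean_diff": 5.0},
    "overlap": {"min_overlap_bp": 1},
    "select": {"alpha_margin": 0.1},
    "enrichment": {"gmt": None},
    "expression": {"n_genes": 200, "lfc_magnitude": 2.0},
}


def _check_keys(section: dict, allowed: set, name: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {name}: {sorted(unknown)}")


def load_config(source) -> dict:
    """Load and validate a pipeline config (YAML path or dict).

    Missing sections take defaults; unknown keys are rejected.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(source or {})
    _check_keys(user, _TOP_KEYS, "config")
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for section, allowed in (
        ("simulate", _SIM_KEYS), ("filter", _FILTER_KEYS), ("preprocess", _PRE_KEYS),
        ("dmc", _DMC_KEYS), ("dmr", _DMR_KEYS), ("overlap", _OV_KEYS),
        ("select", _SEL_KEYS), ("enrichment", _ENR_KEYS), ("expression", _EXPR_KEYS),
    ):
        if section in user:
            _check_keys(user[section] or {}, allowed, section)
            cfg[section].update(user[section] or {})
    if "inputs" in user and user["inputs"]:
        _check_keys(user["inputs"], _INPUT_KEYS, "inputs")
        cfg["inputs"] = user["inputs"]
    if "seed" in user:
        cfg["seed"] = int(user["seed"])
    return cfg


def build_sim_config(cfg: dict) -> sim_mod.SimulationConfig:
    s = cfg["simulate"]
    regions = sim_mod.make_planted_regions(
        s["regions_per_class"],
        n_chrom=s["n_chrom"],
        n_cpgs=s["region_cpgs"],
        effect=s["effect"],
    )
    return sim_mod.SimulationConfig(
        n_control=s["n_control"],
        n_obese=s["n_obese"],
        n_crc=s["n_crc"],
        n_chrom=s["n_chrom"],
        cpg_per_chrom=s["cpg_per_chrom"],
        coverage_mean=s["coverage_mean"],
        dispersion=s["dispersion"],
        age_slope=s["age_slope"],
        planted_regions=regions,
        seed=cfg["seed"],
    )


def _load_inputs(cfg):
    inp = cfg["inputs"]
    sheet = io_mod.read_sample_sheet(inp["sample_sheet"])
    callsets = [io_mod.read_coverage_file(p) for p in inp["coverage_files"]]
    annotation = io_mod.read_annotation(inp["genes"], inp["islands"])
    return callsets, sheet, annotation, pd.DataFrame(), None


def _toy_gene_sets(annotation, truth_genes) -> enr_mod.GeneSetCollection:
    """Deterministic toy collection: one term per chromosome plus one term
    holding the genes that carry planted regions."""
    universe = set(annotation.gene_ids())
    sets = {}
    by_chrom: dict[str, set] = {}
    for g in annotation.genes:
        by_chrom.setdefault(g.chrom, set()).add(g.gene_id)
    for chrom in sorted(by_chrom):
        sets[f"CHROM_{chrom}"] = (f"genes on {chrom}", frozenset(by_chrom[chrom]))
    planted = frozenset(g for g in truth_genes if g in universe)
    if planted:
        sets["PLANTED"] = ("genes carrying planted regions", planted)
    return enr_mod.GeneSetCollection(sets=sets, background=frozenset(universe))


def _expression_stage(cfg, selected_genes, subregion_of, outdir):
    """Simulate the two-condition verification matrix and test concordance.

    Expectation convention: promoter hypermethylation silences, so
    demethylation raises expression ("up"); gene-body (exon/intron)
    hypermethylation tracks expression, so demethylation lowers it
    ("down"); hypomethylated regions expect the opposite.
    """
    e = cfg["expression"]
    n_genes = max(e["n_genes"], len(selected_genes))
    expect = {}
    for gene, (subregion, direction) in subregion_of.items():
        promoter_like = subregion == "promoter"
        hyper = direction == "hyper"
        expect[gene] = "up" if (promoter_like == hyper) else "down"
    lfc_mag = e["lfc_magnitude"]
    effect = {}
    rename = {}
    gene_list = sorted(expect)
    for i, gene in enumerate(gene_list):
        sim_name = f"gene{i + 1:04d}"
        rename[sim_name] = gene
        effect[sim_name] = lfc_mag if expect[gene] == "up" else -lfc_mag
    counts, lfc = sim_mod.simulate_expression(
        n_genes, effect_table=effect, seed=cfg["seed"] + 7
    )
    counts = counts.rename(index=rename)
    mat = expr_mod.ExpressionMatrix(counts).normalize()
    logcpm = mat.log_cpm()
    io_mod.write_report(logcpm.round(6), outdir / "expression_log_cpm.tsv", index=True)
    if expect:
        report = expr_mod.concordance_report(
            logcpm, pd.Series(expect), baseline="WT"
        )
        io_mod.write_report(report.round(6), outdir / "expression_concordance.tsv", index=True)
    else:
        report = pd.DataFrame(columns=["concordance"])
    return report


def run_pipeline(config, outdir) -> dict:
    """Run every stage and write the report bundle to ``outdir``.

    Returns the summary dict (also written as summary.json).
    """
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg["seed"]}

    # ------------------------------------------------------------- inputs
    if "inputs" in cfg:
        callsets, sheet, annotation, truth, ann_truth = _load_inputs(cfg)
    else:
        sim_cfg = build_sim_config(cfg)
        callsets, sheet, truth = sim_mod.simulate_methylation(sim_cfg)
        annotation, ann_truth = sim_mod.simulate_annotation(sim_cfg)
    log.info("inputs: %d samples, %d sites each", len(callsets), len(callsets[0]))
    io_mod.write_sample_sheet(sheet, outdir / "sample_sheet.csv")
    io_mod.write_report(truth, outdir / "truth_regions.tsv")
    summary["n_samples"] = len(callsets)
    summary["n_sites_input"] = int(len(callsets[0])) if callsets else 0

    # --------------------------------------------------------- preprocess
    policy = pre_mod.FilterPolicy(**cfg["filter"])
    callsets = [pre_mod.filter_calls(c, policy) for c in callsets]
    if cfg["preprocess"]["normalize_coverage"]:
        callsets = pre_mod.normalize_coverage(callsets)
    group_of = dict(zip(sheet["sample_id"], sheet["group"]))
    if cfg["preprocess"]["do_histogram_transform"]:
        controls = [c for c in callsets if group_of[c.sample_id] == "control"]
        cases = [c for c in callsets if group_of[c.sample_id] != "control"]
        cases = pre_mod.histogram_transform(cases, controls)
        callsets = controls + cases
    summary["n_sites_after_filter"] = {c.sample_id: int(len(c)) for c in callsets}
    log.info("preprocess done")

    # ---------------------------------------------------------------- dmc
    thresholds = dmc_mod.DmcThresholds(
        min_diff_pct=cfg["dmc"]["min_diff_pct"],
        max_q=cfg["dmc"]["max_q"],
        min_per_group=cfg["dmc"]["min_per_group"],
    )
    dmc_tables, dmr_tables = {}, {}
    for contrast in ("obesity", "crc"):
        tab = dmc_mod.call_dmcs(
            callsets, sheet, contrast, thresholds, covariate=cfg["dmc"]["covariate"]
        )
        dmc_tables[contrast] = tab
        io_mod.write_report(tab.round(8), outdir / f"dmc_{contrast}.tsv")
        summary[f"n_tested_{contrast}"] = int(len(tab))
        summary[f"n_dmc_{contrast}"] = int(tab["significant"].sum())
        log.info("dmc %s: %d tested, %d significant", contrast, len(tab), tab["significant"].sum())

    # ---------------------------------------------------------------- dmr
    dmr_thresholds = dmr_mod.DmrThresholds(**cfg["dmr"])
    for contrast in ("obesity", "crc"):
        cutoff = dmr_mod.distance_cutoff(dmc_tables[contrast])
        regions = dmr_mod.call_dmrs(dmc_tables[contrast], cutoff, dmr_thresholds)
        dmr_tables[contrast] = regions
        io_mod.write_report(dmr_mod.dmr_bed_table(regions).round(8), outdir / f"dmr_{contrast}.tsv")
        summary[f"dmr_cutoff_bp_{contrast}"] = float(cutoff)
        summary[f"n_dmr_{contrast}"] = int(len(regions))
        log.info("dmr %s: cutoff %.1f bp, %d regions", contrast, cutoff, len(regions))

    # ------------------------------------------------------------ overlap
    dmc_ov = ov_mod.overlap_dmcs(
        dmc_mod.significant_dmcs(dmc_tables["obesity"]),
        dmc_mod.significant_dmcs(dmc_tables["crc"]),
    )
    dmr_ov = ov_mod.overlap_dmrs(
        dmr_tables["obesity"], dmr_tables["crc"],
        min_overlap_bp=cfg["overlap"]["min_overlap_bp"],
    )
    for tag, ov in (("dmc", dmc_ov), ("dmr", dmr_ov)):
        io_mod.write_report(ov_mod.venn_table(ov, "obesity", "crc"), outdir / f"{tag}_overlap_venn.tsv")
        io_mod.write_report(ov.quadrant.reset_index(), outdir / f"{tag}_quadrant.tsv")
        summary[f"{tag}_overlap"] = {
            "n_obesity_only": ov.n_a_only,
            "n_crc_only": ov.n_b_only,
            "n_overlap": ov.n_overlap,
            "quadrant": ov.quadrant.to_numpy().tolist(),
            "chi2": None if np.isnan(ov.chi2) else float(ov.chi2),
            "chi2_p": None if np.isnan(ov.chi2_p) else float(ov.chi2_p),
            "concordant_fraction": None
            if np.isnan(ov.concordant_fraction)
            else float(ov.concordant_fraction),
            "pct_of_obesity": (
                ov_mod.overlap_fraction(ov, "a") if ov.n_a else None
            ),
        }
    if dmr_ov.pairs is not None:
        io_mod.write_report(dmr_ov.pairs.round(8), outdir / "dmr_pairs.tsv")
    log.info(
        "overlap: %d DMCs, %d DMRs in both contrasts", dmc_ov.n_overlap, dmr_ov.n_overlap
    )

    # ----------------------------------------------------------- annotate
    pairs = dmr_ov.pairs if dmr_ov.pairs is not None else pd.DataFrame()
    ov_names = set(pairs["a_name"]) if len(pairs) else set()
    ov_regions = dmr_tables["obesity"][dmr_tables["obesity"]["name"].isin(ov_names)]
    sets = {
        "obesity_specific": dmr_tables["obesity"][~dmr_tables["obesity"]["name"].isin(ov_names)],
        "crc_specific": dmr_tables["crc"][
            ~dmr_tables["crc"]["name"].isin(set(pairs["b_name"]) if len(pairs) else set())
        ],
        "overlapping": ov_regions,
    }
    annotated = {k: ann_mod.annotate_features(v, annotation) for k, v in sets.items()}
    profiles = {}
    for kind in ("subregion", "island_context"):
        prof = ann_mod.distribution_profile(annotated, kind=kind)
        io_mod.write_report(prof, outdir / f"dmr_profile_{kind}.tsv")
        dist = ann_mod.profile_distances(prof)
        io_mod.write_report(dist.round(6).reset_index(names="set"), outdir / f"dmr_profile_{kind}_tv.tsv")
        profiles[kind] = {
            "tv_overlap_vs_obesity": float(dist.loc["overlapping", "obesity_specific"])
            if "overlapping" in dist.index
            else None,
            "tv_overlap_vs_crc": float(dist.loc["overlapping", "crc_specific"])
            if "overlapping" in dist.index
            else None,
        }
    summary["profiles"] = profiles

    # ------------------------------------------------------------- select
    ov_annotated = annotated["overlapping"]
    sel_matrix = sel_mod.dmr_subject_means(ov_regions, callsets)
    io_mod.write_report(sel_matrix.round(6).reset_index(names="name"), outdir / "dmr_subject_means.tsv")
    ann_series = pd.Series(
        ov_annotated["subregion"].to_numpy(), index=ov_annotated["name"].to_numpy()
    ) if len(ov_annotated) else pd.Series(dtype=object)
    sel = sel_mod.select(
        sel_matrix, sheet, alpha_margin=cfg["select"]["alpha_margin"], annotations=ann_series
    )
    io_mod.write_report(sel.round(8).reset_index(), outdir / "selection.tsv")
    io_mod.write_report(
        sel_mod.subject_dotplot_table(sel_matrix, sheet).round(6), outdir / "dmr_dotplot.tsv"
    )
    summary["n_overlap_dmr_tested"] = int(sel["kw_p"].notna().sum())
    summary["n_selected"] = int(sel["selected"].sum())
    summary["n_selected_annotated"] = (
        int(sel["selected_annotated"].sum()) if "selected_annotated" in sel else 0
    )
    log.info("selection: %d of %d DMRs selected", summary["n_selected"], len(sel))

    # ------------------------------------------------------------- enrich
    gene_of = dict(zip(ov_annotated.get("name", pd.Series(dtype=object)),
                       ov_annotated.get("gene_id", pd.Series(dtype=object))))
    selected_names = list(sel.index[sel.get("selected_annotated", sel["selected"])])
    query = sorted({g for n in selected_names if (g := gene_of.get(n)) is not None})
    if cfg["enrichment"]["gmt"]:
        collection = enr_mod.read_gmt(cfg["enrichment"]["gmt"])
    else:
        truth_genes = set(ann_truth["gene_id"].dropna()) if ann_truth is not None else set()
        collection = _toy_gene_sets(annotation, truth_genes)
    enrich = enr_mod.enrich_all(query, collection)
    io_mod.write_report(enrich.round(8), outdir / "enrichment.tsv")
    summary["n_enrichment_terms"] = int(len(enrich))
    summary["n_enriched_significant"] = int(enrich["significant"].sum())

    # --------------------------------------------------------- expression
    subregion_of = {}
    for n in selected_names:
        g = gene_of.get(n)
        if g is None:
            continue
        row = ov_annotated[ov_annotated["name"] == n].iloc[0]
        subregion_of[g] = (row["subregion"], row["direction"])
    report = _expression_stage(cfg, query, subregion_of, outdir)
    if len(report):
        vc = report["concordance"].value_counts()
        summary["expression_concordance"] = {k: int(vc.get(k, 0)) for k in ("agree", "disagree", "neutral")}
    else:
        summary["expression_concordance"] = {"agree": 0, "disagree": 0, "neutral": 0}

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("pipeline complete; reports in %s", outdir)
    return summary
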