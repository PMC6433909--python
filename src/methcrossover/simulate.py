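"""Synthetic whole-blood RRBS study generator.

Emulates the data the cross-contrast analysis consumes: a three-group
cohort (lean controls, obese subjects, colorectal-cancer patients) with
per-sample CpG methylation calls, a matching sample sheet, toy gene
models and CpG islands, and a small two-condition RNA-seq count matrix.

The methylation model is beta-binomial: each CpG has a background level
drawn from a bimodal mixture (most CpGs are either nearly unmethylated or
nearly fully methylated, as in real RRBS data), a planted case-group
effect inside designated regions, and an optional linear age effect on
the logit scale.  Read coverage is negative-binomial.  CpGs are laid out
in clusters so that nearest-neighbour distances are bimodal, which is the
structure the region-segmentation distance cutoff relies on.

Group sizes and ages default to the motivating cohort: 15 controls
(40 +/- 15 y), 10 obese (36 +/- 10 y), 15 CRC (53 +/- 9 y).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Gene, GenomeAnnotation, MethylationCallSet, merge_intervals

REGION_CLASSES = (
    "obesity_only",
    "crc_only",
    "concordant_hyper",
    "concordant_hypo",
    "discordant",
)

# RNG stream offsets: one independent stream per output, so regenerating a
# single artifact does not perturb the others.
_STREAM_LAYOUT = 0
_STREAM_SHEET = 1
_STREAM_METH = 2
_STREAM_ANNOT = 3
_STREAM_EXPR = 4


@dataclass(frozen=True)
class PlantedRegion:
    """A contiguous run of CpGs carrying a planted group effect.

    Effects are signed shifts of the methylation level (delta-beta) applied
    to the obese and/or CRC groups; the class label must be consistent with
    the effect signs and is carried into the truth table.
    """

    chrom: str
    start: int
    end: int
    n_cpgs: int
    effect_obese: float
    effect_crc: float
    region_class: str

    def __post_init__(self) -> None:
        if self.n_cpgs < 3:
            raise ValueError("planted region needs >= 3 CpGs")
        if self.end <= self.start:
            raise ValueError("planted region end <= start")
        if max(abs(self.effect_obese), abs(self.effect_crc)) > 0.6:
            raise ValueError("|effect| must be <= 0.6")
        eo, ec = self.effect_obese, self.effect_crc
        ok = {
            "obesity_only": eo != 0 and ec == 0,
            "crc_only": ec != 0 and eo == 0,
            "concordant_hyper": eo > 0 and ec > 0,
            "concordant_hypo": eo < 0 and ec < 0,
            "discordant": eo * ec < 0,
        }
        if self.region_class not in ok:
            raise ValueError(f"unknown region class {self.region_class!r}")
        if not ok[self.region_class]:
            raise ValueError(
                f"effects ({eo:+.2f}, {ec:+.2f}) inconsistent with class {self.region_class!r}"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    ``baseline_beta_mixture`` is a list of (weight, alpha, beta) Beta
    components for background methylation levels; the default is the
    usual bimodal RRBS shape (45% low, 45% high, 10% intermediate).
    ``dispersion`` is the beta-binomial overdispersion phi in (0, 1);
    phi -> 0 degenerates to pure binomial sampling.
    """

    n_control: int = 15
    n_obese: int = 10
    n_crc: int = 15
    age_mean_sd: dict = field(
        default_factory=lambda: {
            "control": (40.0, 15.0),
            "obesity": (36.0, 10.0),
            "crc": (53.0, 9.0),
        }
    )
    n_chrom: int = 4
    cpg_per_chrom: int = 1000
    coverage_mean: float = 30.0
    coverage_nb_k: float = 8.0  # NB size; var = mu + mu^2/k
    baseline_beta_mixture: tuple = ((0.45, 1.0, 8.0), (0.45, 8.0, 1.0), (0.10, 5.0, 5.0))
    planted_regions: tuple = ()
    dispersion: float = 0.05
    age_slope: float = 0.002  # per year, on logit(beta)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_control", "n_obese", "n_crc"):
            if getattr(self, name) < 3:
                raise ValueError(
                    f"{name} = {getattr(self, name)} < 3: the differential caller "
                    "requires at least three individuals per group"
                )
        if self.n_chrom < 1 or self.cpg_per_chrom < 1:
            raise ValueError("n_chrom and cpg_per_chrom must be >= 1")
        if not (0 < self.dispersion < 1):
            raise ValueError("dispersion phi must lie in (0, 1)")
        object.__setattr__(self, "planted_regions", tuple(self.planted_regions))
        for r in self.planted_regions:
            if not isinstance(r, PlantedRegion):
                raise TypeError("planted_regions must contain PlantedRegion objects")

    def with_regions(self, regions) -> "SimulationConfig":
        return replace(self, planted_regions=tuple(regions))


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config_seed), stream])


def make_planted_regions(
    n_per_class: dict[str, int],
    n_chrom: int,
    *,
    n_cpgs: int = 5,
    effect: float = 0.3,
    intra_gap: int = 50,
    spacing: int = 10_000,
    start: int = 2_000_000,
) -> list[PlantedRegion]:
    """Lay out planted regions round-robin across chromosomes.

    Regions begin at ``start`` (past the background CpG span), ``spacing``
    bp apart, each containing ``n_cpgs`` CpGs ``intra_gap`` bp apart.
    """
    regions = []
    counters = dict.fromkeys(range(1, n_chrom + 1), 0)
    i = 0
    for cls in REGION_CLASSES:
        for _ in range(n_per_class.get(cls, 0)):
            chrom_i = (i % n_chrom) + 1
            slot = counters[chrom_i]
            counters[chrom_i] += 1
            s = start + slot * spacing
            e = s + (n_cpgs - 1) * intra_gap + 2
            eo, ec = {
                "obesity_only": (effect, 0.0),
                "crc_only": (0.0, effect),
                "concordant_hyper": (effect, effect),
                "concordant_hypo": (-effect, -effect),
                "discordant": (effect, -effect),
            }[cls]
            regions.append(
                PlantedRegion(f"chr{chrom_i}", s, e, n_cpgs, eo, ec, cls)
            )
            i += 1
    return regions


# ---------------------------------------------------------------------------
# site layout
# ---------------------------------------------------------------------------


def _site_table(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic CpG layout: chrom, pos, baseline beta, region index.

    Background CpGs come in clusters (geometric size ~8, ~30 bp intra-
    cluster gaps, ~2 kb between clusters); planted-region CpGs are placed
    at their configured coordinates.
    """
    rng = _rng(config.seed, _STREAM_LAYOUT)
    rows = []
    for c in range(1, config.n_chrom + 1):
        chrom = f"chr{c}"
        pos = 1000
        placed = 0
        while placed < config.cpg_per_chrom:
            size = min(1 + rng.geometric(1 / 8.0), config.cpg_per_chrom - placed)
            for _ in range(size):
                rows.append((chrom, pos))
                pos += int(np.round(10 ** rng.normal(1.5, 0.15)))  # ~30 bp
                placed += 1
            pos += int(np.round(10 ** rng.normal(3.3, 0.2)))  # ~2 kb
        rows_c = [r for r in rows if r[0] == chrom]
        if rows_c and rows_c[-1][1] >= 2_000_000:
            raise ValueError("background CpG span collides with planted-region space")
    sites = pd.DataFrame(rows, columns=["chrom", "pos"])
    sites["region"] = -1

    planted_rows = []
    for ri, reg in enumerate(config.planted_regions):
        gap = max(1, (reg.end - reg.start - 2) // max(1, reg.n_cpgs - 1))
        for k in range(reg.n_cpgs):
            planted_rows.append((reg.chrom, reg.start + k * gap, ri))
    if planted_rows:
        planted = pd.DataFrame(planted_rows, columns=["chrom", "pos", "region"])
        sites = pd.concat([sites, planted], ignore_index=True)

    sites = sites.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if sites.duplicated(subset=["chrom", "pos"]).any():
        raise ValueError("planted regions collide with background CpGs")

    # background methylation level from the Beta mixture
    w = np.array([m[0] for m in config.baseline_beta_mixture], dtype=float)
    w = w / w.sum()
    comp = rng.choice(len(w), size=len(sites), p=w)
    a = np.array([m[1] for m in config.baseline_beta_mixture])[comp]
    b = np.array([m[2] for m in config.baseline_beta_mixture])[comp]
    sites["baseline"] = rng.beta(a, b)
    return sites


def simulate_sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rng = _rng(config.seed, _STREAM_SHEET)
    rows = []
    for group, n, prefix in (
        ("control", config.n_control, "ctl"),
        ("obesity", config.n_obese, "obe"),
        ("crc", config.n_crc, "crc"),
    ):
        mean, sd = config.age_mean_sd[group]
        ages = np.clip(np.round(rng.normal(mean, sd, size=n)), 18, 90).astype(int)
        for i in range(n):
            rows.append(
                (f"{prefix}{i + 1:02d}", group, int(ages[i]), "F" if i % 2 == 0 else "M")
            )
    return pd.DataFrame(rows, columns=["sample_id", "group", "age", "sex"])


def simulate_methylation(
    config: SimulationConfig,
) -> tuple[list[MethylationCallSet], pd.DataFrame, pd.DataFrame]:
    """Draw the full synthetic cohort.

    Returns (per-sample call sets, sample sheet, truth table).  The truth
    table has one row per planted region with its coordinates, member-CpG
    count, effects and class.
    """
    sites = _site_table(config)
    sheet = simulate_sample_sheet(config)
    rng = _rng(config.seed, _STREAM_METH)

    mean_age = float(sheet["age"].mean())
    n_sites = len(sites)
    baseline = sites["baseline"].to_numpy()
    region_idx = sites["region"].to_numpy()

    effects = {"control": np.zeros(n_sites), "obesity": np.zeros(n_sites), "crc": np.zeros(n_sites)}
    for ri, reg in enumerate(config.planted_regions):
        mask = region_idx == ri
        effects["obesity"][mask] = reg.effect_obese
        effects["crc"][mask] = reg.effect_crc

    phi = config.dispersion
    callsets = []
    for row in sheet.itertuples(index=False):
        p = np.clip(baseline + effects[row.group], 0.01, 0.99)
        if config.age_slope:
            logit = np.log(p / (1 - p)) + config.age_slope * (row.age - mean_age)
            p = 1.0 / (1.0 + np.exp(-logit))
            p = np.clip(p, 0.01, 0.99)
        cov = np.maximum(
            1,
            rng.negative_binomial(
                config.coverage_nb_k,
                config.coverage_nb_k / (config.coverage_nb_k + config.coverage_mean),
                size=n_sites,
            ),
        )
        if phi > 1e-8:
            conc = (1 - phi) / phi
            p_draw = rng.beta(p * conc, (1 - p) * conc)
        else:
            p_draw = p
        n_meth = rng.binomial(cov, p_draw)
        data = pd.DataFrame(
            {
                "chrom": sites["chrom"],
                "pos": sites["pos"],
                "strand": ".",
                "coverage": cov.astype(np.int64),
                "n_meth": n_meth.astype(np.int64),
            }
        )
        callsets.append(MethylationCallSet(row.sample_id, data))

    truth = pd.DataFrame(
        [
            (r.chrom, r.start, r.end, r.n_cpgs, r.effect_obese, r.effect_crc, r.region_class)
            for r in config.planted_regions
        ],
        columns=["chrom", "start", "end", "n_cpgs", "effect_obese", "effect_crc", "class"],
    )
    return callsets, sheet, truth


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_SUBREGION_CYCLE = ("promoter", "exon", "intron", "intergenic")


def simulate_annotation(
    config: SimulationConfig,
    *,
    genes_per_chrom: int = 10,
    island_fraction: float = 0.3,
) -> tuple[GenomeAnnotation, pd.DataFrame]:
    """Build toy gene models and CpG islands matched to the CpG layout.

    Each planted region is deliberately placed in a known gene subregion
    (cycling promoter/exon/intron/intergenic by region index) and the
    returned truth frame records that expected assignment together with
    the expected island context (even-indexed regions get an island).
    Background genes tile the background CpG span on alternating strands;
    islands additionally cover roughly ``island_fraction`` of background
    CpGs.
    """
    rng = _rng(config.seed, _STREAM_ANNOT)
    sites = _site_table(config)
    genes: list[Gene] = []
    island_rows: list[tuple[str, int, int]] = []

    # background genes: disjoint tiles across the background span
    for c in range(1, config.n_chrom + 1):
        chrom = f"chr{c}"
        span_end = int(sites.loc[(sites["chrom"] == chrom) & (sites["region"] == -1), "pos"].max())
        tile = max(6000, span_end // max(1, genes_per_chrom))
        for gi in range(genes_per_chrom):
            g0 = gi * tile + 2500
            g1 = g0 + tile - 3000
            if g1 - g0 < 600 or g1 > 1_990_000:
                break
            strand = "+" if gi % 2 == 0 else "-"
            mid = (g0 + g1) // 2
            exons = [(g0, mid - 150), (mid + 150, g1)]
            tss = g0 if strand == "+" else g1 - 1
            genes.append(Gene(f"bg_{chrom}_{gi + 1}", chrom, strand, tss, exons))

    # islands over a fraction of background CpG clusters
    bg = sites[sites["region"] == -1]
    for chrom, grp in bg.groupby("chrom"):
        pos = grp["pos"].to_numpy()
        breaks = np.where(np.diff(pos) > 300)[0]
        cluster_start = np.concatenate([[0], breaks + 1])
        cluster_end = np.concatenate([breaks, [len(pos) - 1]])
        for s_i, e_i in zip(cluster_start, cluster_end):
            if rng.random() < island_fraction:
                island_rows.append((chrom, int(pos[s_i]) - 10, int(pos[e_i]) + 10))

    # one dedicated gene / island per planted region, by construction
    expected = []
    for ri, reg in enumerate(config.planted_regions):
        sub = _SUBREGION_CYCLE[ri % len(_SUBREGION_CYCLE)]
        gid = None
        if sub == "promoter":
            gid = f"pr_{ri}"
            tss = reg.end + 100
            genes.append(Gene(gid, reg.chrom, "+", tss, [(tss, tss + 800)]))
        elif sub == "exon":
            gid = f"ex_{ri}"
            g0 = reg.start - 200
            genes.append(Gene(gid, reg.chrom, "+", g0, [(g0, reg.end + 200)]))
        elif sub == "intron":
            gid = f"in_{ri}"
            g0 = reg.start - 500
            g1 = reg.end + 500
            genes.append(
                Gene(gid, reg.chrom, "+", g0, [(g0, reg.start - 100), (reg.end + 100, g1)])
            )
        in_island = ri % 2 == 0
        if in_island:
            island_rows.append((reg.chrom, reg.start - 10, reg.end + 10))
        expected.append((ri, sub, gid, "island" if in_island else "open_sea"))

    islands = merge_intervals(
        pd.DataFrame(island_rows, columns=["chrom", "start", "end"])
        if island_rows
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )
    chrom_sizes = {f"chr{c}": 3_000_000 for c in range(1, config.n_chrom + 1)}
    annotation = GenomeAnnotation(genes=genes, islands=islands, chrom_sizes=chrom_sizes)
    truth = pd.DataFrame(
        expected, columns=["region", "expected_subregion", "gene_id", "expected_island_context"]
    )
    return annotation, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    n_genes: int,
    *,
    conditions: tuple[str, str] = ("WT", "DKO"),
    replicates: int = 2,
    effect_table: pd.Series | dict | None = None,
    mean_log2_range: tuple[float, float] = (3.0, 10.0),
    nb_dispersion: float = 0.05,
    library_spread: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial two-condition count matrix.

    ``effect_table`` maps gene id -> log2 fold change applied to the second
    condition; unlisted genes get 0.  Library sizes vary by up to
    +/- ``library_spread``.  Returns (counts, true lfc per gene).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = _rng(seed, _STREAM_EXPR)
    gene_ids = [f"gene{i + 1:04d}" for i in range(n_genes)]
    lfc = pd.Series(0.0, index=gene_ids, name="lfc")
    if effect_table is not None:
        eff = pd.Series(effect_table, dtype=float)
        lfc.loc[eff.index.intersection(lfc.index)] = eff
    base = 2.0 ** rng.uniform(*mean_log2_range, size=n_genes)
    k = 1.0 / nb_dispersion
    cols, counts = [], []
    for ci, cond in enumerate(conditions):
        mu_cond = base * (2.0 ** (lfc.to_numpy() * ci))
        for r in range(replicates):
            lib_factor = 1.0 + rng.uniform(-library_spread, library_spread)
            mu = np.maximum(mu_cond * lib_factor, 1e-8)
            counts.append(rng.negative_binomial(k, k / (k + mu)))
            cols.append(f"{cond}_{r + 1}")
    mat = pd.DataFrame(np.column_stack(counts), index=gene_ids, columns=cols).astype(np.int64)
    mat.index.name = "gene_id"
    return mat, lfc
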