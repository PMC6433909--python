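"""Genomic-context annotation of methylation features.

Every feature (a DMC as a 1-bp interval, or a DMR interval) is assigned
exactly one gene subregion -- promoter > exon > intron > intergenic, in
that precedence when a feature spans categories -- and exactly one
CpG-island context: island if it intersects an island, shore if it lies
within 2 kb of one, open sea otherwise.  The promoter is the 2 kb window
immediately upstream of the TSS on the gene's strand.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import GenomeAnnotation

PROMOTER_BP = 2000
SHORE_BP = 2000

SUBREGIONS = ("promoter", "exon", "intron", "intergenic")
ISLAND_CONTEXTS = ("island", "shore", "open_sea")


def promoter_interval(tss: int, strand: str) -> tuple[int, int]:
    """0-based half-open promoter window upstream of the TSS, strandwise."""
    if strand == "+":
        return max(0, tss - PROMOTER_BP), tss
    return tss + 1, tss + 1 + PROMOTER_BP


class _Index:
    """Per-chromosome interval trees over promoters, exons, gene spans, islands."""

    def __init__(self, annotation: GenomeAnnotation):
        self.promoters: dict[str, IntervalTree] = {}
        self.exons: dict[str, IntervalTree] = {}
        self.spans: dict[str, IntervalTree] = {}
        self.islands: dict[str, IntervalTree] = {}
        for g in annotation.genes:
            ps, pe = promoter_interval(g.tss, g.strand)
            if pe > ps:
                self.promoters.setdefault(g.chrom, IntervalTree()).addi(ps, pe, g.gene_id)
            for a, b in g.exons:
                self.exons.setdefault(g.chrom, IntervalTree()).addi(a, b, g.gene_id)
            s, e = g.span
            if e > s:
                self.spans.setdefault(g.chrom, IntervalTree()).addi(s, e, g.gene_id)
        for row in annotation.islands.itertuples(index=False):
            self.islands.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
        self.known_chroms = (
            set(self.promoters) | set(self.exons) | set(self.spans) | set(self.islands)
        )


def _best_hit(tree: IntervalTree | None, start: int, end: int):
    """(gene_id, overlap_bp) of the largest intersection, ties to smaller id."""
    if tree is None:
        return None, 0
    best_id, best_ov = None, 0
    for iv in sorted(tree.overlap(start, end), key=lambda iv: (iv.begin, str(iv.data))):
        ov = min(end, iv.end) - max(start, iv.begin)
        if ov > best_ov:
            best_id, best_ov = iv.data, ov
    return best_id, best_ov


def annotate_features(features: pd.DataFrame, annotation: GenomeAnnotation) -> pd.DataFrame:
    """Annotate intervals (chrom, start, end) or sites (chrom, pos).

    Returns the input with ``subregion``, ``island_context`` and
    ``gene_id`` columns appended.  Features on chromosomes absent from
    the annotation become intergenic open sea, with a warning.
    """
    feats = features.copy()
    if "start" not in feats.columns:
        feats["start"] = feats["pos"]
        feats["end"] = feats["pos"] + 1
    idx = _Index(annotation)
    sub, ctx, gid = [], [], []
    unknown = set()
    for row in feats.itertuples(index=False):
        chrom, start, end = row.chrom, int(row.start), int(row.end)
        if chrom not in idx.known_chroms:
            unknown.add(chrom)
            sub.append("intergenic")
            ctx.append("open_sea")
            gid.append(None)
            continue
        g_pr, ov_pr = _best_hit(idx.promoters.get(chrom), start, end)
        g_ex, ov_ex = _best_hit(idx.exons.get(chrom), start, end)
        g_sp, ov_sp = _best_hit(idx.spans.get(chrom), start, end)
        if ov_pr > 0:
            sub.append("promoter")
            gid.append(g_pr)
        elif ov_ex > 0:
            sub.append("exon")
            gid.append(g_ex)
        elif ov_sp > 0:
            sub.append("intron")
            gid.append(g_sp)
        else:
            sub.append("intergenic")
            gid.append(None)
        isl = idx.islands.get(chrom)
        if isl is not None and isl.overlap(start, end):
            ctx.append("island")
        elif isl is not None and isl.overlap(max(0, start - SHORE_BP), end + SHORE_BP):
            ctx.append("shore")
        else:
            ctx.append("open_sea")
    if unknown:
        warnings.warn(
            f"features on unknown chromosomes treated as intergenic: {sorted(unknown)}",
            stacklevel=2,
        )
    feats["subregion"] = sub
    feats["island_context"] = ctx
    feats["gene_id"] = gid
    return feats


def distribution_profile(
    annotated_sets: dict[str, pd.DataFrame], kind: str = "subregion"
) -> pd.DataFrame:
    """Hyper/hypo counts per category for each feature set.

    ``annotated_sets`` maps a set label (e.g. cancer-specific,
    obesity-specific, overlapping) to an annotated frame carrying
    ``direction`` and the category column.  Output is long-form:
    set, direction, category, count -- one row per combination, zeros
    included, so the counts per set always sum to the set size.
    """
    categories = SUBREGIONS if kind == "subregion" else ISLAND_CONTEXTS
    rows = []
    for label, feats in annotated_sets.items():
        for direction in ("hyper", "hypo"):
            d = feats[feats["direction"] == direction]
            vc = d[kind].value_counts()
            for cat in categories:
                rows.append((label, direction, cat, int(vc.get(cat, 0))))
    return pd.DataFrame(rows, columns=["set", "direction", "category", "count"])


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """TV distance between two probability vectors: 0.5 * sum |p - q|."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return 0.5 * float(np.abs(p / p.sum() - q / q.sum()).sum())


def profile_distances(profile: pd.DataFrame) -> pd.DataFrame:
    """Pairwise TV distances between the sets' normalized
    direction-by-category profiles."""
    pivot = profile.pivot_table(
        index="set", columns=["direction", "category"], values="count", fill_value=0
    )
    labels = list(pivot.index)
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            tv = total_variation(pivot.loc[a].to_numpy(), pivot.loc[b].to_numpy())
            mat.loc[a, b] = mat.loc[b, a] = tv
    return mat
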