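"""Cross-contrast intersection of DMCs/DMRs, direction-concordance
classification, and the chi-square association test.

A feature differentially methylated in both case-control contrasts is an
"overlapping" feature; the 2x2 quadrant table counts overlapping
features by direction in each contrast (hyper/hypo x hyper/hypo), and a
chi-square test of independence on that table measures whether the two
contrasts' directions are associated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

DIRECTIONS = ("hyper", "hypo")


@dataclass
class ContrastOverlap:
    """Venn counts, direction quadrants, and the association test."""

    n_a_only: int
    n_b_only: int
    n_overlap: int
    quadrant: pd.DataFrame  # rows: A hyper/hypo, cols: B hyper/hypo
    chi2: float  # nan when undefined
    chi2_p: float
    concordant_fraction: float
    pairs: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_a(self) -> int:
        return self.n_a_only + self.n_overlap

    @property
    def n_b(self) -> int:
        return self.n_b_only + self.n_overlap


def chi2_independence(table: np.ndarray, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2x2 table.

    Computed from the textbook statistic sum((O-E)^2/E) with 1 df;
    ``correction`` applies the Yates continuity correction.  Returns
    (nan, nan) when a margin is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = t.sum()
    if np.any(row == 0) or np.any(col == 0):
        warnings.warn("chi-square undefined: a margin of the quadrant table is zero", stacklevel=2)
        return float("nan"), float("nan")
    expected = np.outer(row, col) / n
    diff = np.abs(t - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float(np.sum(diff**2 / expected))
    return stat, float(chi2_dist.sf(stat, df=1))


def _build(n_a_only, n_b_only, quad, pairs=None, correction=False) -> ContrastOverlap:
    quadrant = pd.DataFrame(
        quad,
        index=pd.Index(DIRECTIONS, name="A"),
        columns=pd.Index(DIRECTIONS, name="B"),
        dtype=int,
    )
    n_overlap = int(quadrant.to_numpy().sum())
    stat, p = chi2_independence(quadrant.to_numpy(), correction=correction) if n_overlap else (float("nan"), float("nan"))
    conc = (
        (quadrant.iat[0, 0] + quadrant.iat[1, 1]) / n_overlap if n_overlap else float("nan")
    )
    return ContrastOverlap(
        n_a_only=int(n_a_only),
        n_b_only=int(n_b_only),
        n_overlap=n_overlap,
        quadrant=quadrant,
        chi2=stat,
        chi2_p=p,
        concordant_fraction=conc,
        pairs=pairs,
    )


def overlap_from_counts(
    n_a_only: int, n_b_only: int, quadrant, correction: bool = False
) -> ContrastOverlap:
    """Assemble a :class:`ContrastOverlap` from printed counts.

    ``quadrant`` is the 2x2 hyper/hypo direction table of the overlapping
    features (rows contrast A, columns contrast B); its total defines
    n_overlap.  Useful for re-deriving fractions and the association test
    from a study's reported numbers.
    """
    return _build(n_a_only, n_b_only, np.asarray(quadrant, dtype=int), correction=correction)


def overlap_dmcs(
    dmcs_a: pd.DataFrame, dmcs_b: pd.DataFrame, correction: bool = False
) -> ContrastOverlap:
    """Intersect two significant-DMC sets by exact (chrom, pos) site key.

    Direction in each contrast is taken independently from that
    contrast's methylation-difference sign.
    """
    a = dmcs_a[["chrom", "pos", "direction"]].rename(columns={"direction": "dir_a"})
    b = dmcs_b[["chrom", "pos", "direction"]].rename(columns={"direction": "dir_b"})
    merged = a.merge(b, on=["chrom", "pos"], how="inner")
    quad = np.zeros((2, 2), dtype=int)
    for i, da in enumerate(DIRECTIONS):
        for j, db in enumerate(DIRECTIONS):
            quad[i, j] = int(((merged["dir_a"] == da) & (merged["dir_b"] == db)).sum())
    return _build(len(a) - len(merged), len(b) - len(merged), quad, pairs=merged, correction=correction)


def overlap_dmrs(
    dmrs_a: pd.DataFrame,
    dmrs_b: pd.DataFrame,
    min_overlap_bp: int = 1,
    correction: bool = False,
) -> ContrastOverlap:
    """Pair regions across contrasts by interval intersection.

    Pairing is one-to-one and greedy by largest intersection (ties go to
    the leftmost B region), requiring at least ``min_overlap_bp`` shared
    basepairs on the same chromosome.  The returned ``pairs`` frame lists
    each matched pair with both mean methylation differences and the
    direction quadrant, in the shape of a cross-contrast scatter plot.
    """
    cand = []
    for chrom in sorted(set(dmrs_a["chrom"]) & set(dmrs_b["chrom"])):
        A = dmrs_a[dmrs_a["chrom"] == chrom]
        B = dmrs_b[dmrs_b["chrom"] == chrom]
        for ia, ra in A.iterrows():
            for ib, rb in B.iterrows():
                ov = min(ra["end"], rb["end"]) - max(ra["start"], rb["start"])
                if ov >= min_overlap_bp:
                    cand.append((ov, rb["start"], ia, ib))
    cand.sort(key=lambda t: (-t[0], t[1]))
    used_a, used_b, pairs = set(), set(), []
    for ov, _, ia, ib in cand:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        ra, rb = dmrs_a.loc[ia], dmrs_b.loc[ib]
        pairs.append(
            {
                "chrom": ra["chrom"],
                "a_start": ra["start"],
                "a_end": ra["end"],
                "b_start": rb["start"],
                "b_end": rb["end"],
                "overlap_bp": int(ov),
                "a_mean_meth_diff": ra["mean_meth_diff"],
                "b_mean_meth_diff": rb["mean_meth_diff"],
                "dir_a": ra["direction"],
                "dir_b": rb["direction"],
                "a_name": ra.get("name", str(ia)),
                "b_name": rb.get("name", str(ib)),
            }
        )
    pairs_df = pd.DataFrame(
        pairs,
        columns=[
            "chrom", "a_start", "a_end", "b_start", "b_end", "overlap_bp",
            "a_mean_meth_diff", "b_mean_meth_diff", "dir_a", "dir_b",
            "a_name", "b_name",
        ],
    )
    if len(pairs_df):
        pairs_df["quadrant"] = pairs_df["dir_a"] + "_" + pairs_df["dir_b"]
    quad = np.zeros((2, 2), dtype=int)
    for i, da in enumerate(DIRECTIONS):
        for j, db in enumerate(DIRECTIONS):
            if len(pairs_df):
                quad[i, j] = int(((pairs_df["dir_a"] == da) & (pairs_df["dir_b"] == db)).sum())
    return _build(
        len(dmrs_a) - len(pairs_df), len(dmrs_b) - len(pairs_df), quad,
        pairs=pairs_df, correction=correction,
    )


def overlap_fraction(overlap: ContrastOverlap, denominator: str = "a") -> float:
    """Percentage of one contrast's features that overlap the other.

    100 * n_overlap / (n_overlap + n_<denominator>_only).
    """
    if denominator not in ("a", "b"):
        raise ValueError("denominator must be 'a' or 'b'")
    total = overlap.n_a if denominator == "a" else overlap.n_b
    if total == 0:
        raise ValueError(f"denominator contrast {denominator!r} is empty")
    return 100.0 * overlap.n_overlap / total


def venn_table(overlap: ContrastOverlap, label_a: str = "A", label_b: str = "B") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set": [f"{label_a}_only", "overlap", f"{label_b}_only"],
            "count": [overlap.n_a_only, overlap.n_overlap, overlap.n_b_only],
        }
    )
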