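"""Nonparametric selection of candidate overlapping DMRs.

For every overlapping DMR, the coverage-weighted mean methylation level
across its member CpGs is computed per subject; a Kruskal-Wallis test
across the three groups and pairwise Mann-Whitney U tests then pick the
regions whose subject-level methylation separates the groups at the
marginal-significance level (p <= 0.1).  A second-stage filter keeps
regions located in the promoter or gene body (promoter/exon/intron).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kruskal, mannwhitneyu

from .dmc import CONTROL_GROUP

GENE_LINKED_SUBREGIONS = frozenset({"promoter", "exon", "intron"})
EXACT_MWU_MAX_N = 8


def dmr_subject_means(dmrs: pd.DataFrame, samples: list) -> pd.DataFrame:
    """Per-subject mean methylation of each DMR.

    The cell for (region, subject) is sum(n_meth)/sum(coverage) over the
    region's member CpGs covered in that subject -- a coverage-weighted
    mean beta -- or NaN when the subject covers none of them.  Rows are
    region names, columns sample ids.
    """
    mat = {}
    for s in samples:
        d = s.data.set_index(["chrom", "pos"])
        col = []
        for row in dmrs.itertuples(index=False):
            keys = [(row.chrom, int(p)) for p in row.members]
            hit = d.index.isin(keys)
            if hit.any():
                sub = d[hit]
                col.append(sub["n_meth"].sum() / sub["coverage"].sum())
            else:
                col.append(np.nan)
        mat[s.sample_id] = col
    return pd.DataFrame(mat, index=list(dmrs["name"]))


def _mwu_exact_with_ties(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided permutation p for U, tolerating tied values.

    Enumerates all group assignments of the pooled sample; extremeness is
    |U - nm/2| (U counts x>y pairs plus half the x==y pairs, so the null
    distribution stays symmetric under ties).
    """
    from itertools import combinations

    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    center = n * m / 2.0

    def u_stat(xs, ys):
        diff = xs[:, None] - ys[None, :]
        return float((diff > 0).sum() + 0.5 * (diff == 0).sum())

    u_obs = abs(u_stat(np.asarray(x, float), np.asarray(y, float)) - center)
    idx = np.arange(n + m)
    hits = total = 0
    for comb in combinations(range(n + m), n):
        sel = np.zeros(n + m, dtype=bool)
        sel[list(comb)] = True
        u = u_stat(pooled[sel], pooled[~sel])
        if abs(u - center) >= u_obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def _mwu_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact null distribution when both groups have <= 8 observations
    (scipy's tie-free exact method, or an in-package permutation
    enumeration when ties are present); tie-corrected normal
    approximation for larger groups.  All-tied data returns p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    small = len(x) <= EXACT_MWU_MAX_N and len(y) <= EXACT_MWU_MAX_N
    has_ties = np.unique(pooled).size < pooled.size
    if small and has_ties:
        return _mwu_exact_with_ties(x, y)
    method = "exact" if small else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def _kw_p(groups: list[np.ndarray]) -> float:
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(kruskal(*groups).pvalue)


def select(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    alpha_margin: float = 0.1,
    min_per_group: int = 3,
    annotations: pd.Series | None = None,
    require_subregions: frozenset = GENE_LINKED_SUBREGIONS,
) -> pd.DataFrame:
    """Rank-test every DMR row of the subject-means matrix.

    A region is ``selected`` when the Kruskal-Wallis p across control/
    obesity/CRC and both case-vs-control Mann-Whitney p-values are all at
    or below ``alpha_margin`` (no multiplicity correction at this stage).
    When ``annotations`` (region name -> subregion) is given,
    ``selected_annotated`` additionally requires a promoter/gene-body
    location.  Rows without ``min_per_group`` non-missing subjects in
    every group are untestable and get NaN p-values.
    """
    group_of = dict(zip(sheet["sample_id"], sheet["group"]))
    cols = {"control": [], "obesity": [], "crc": []}
    for sid in matrix.columns:
        g = group_of.get(sid)
        if g in cols:
            cols[g].append(sid)
    rows = []
    for name, row in matrix.iterrows():
        vals = {g: row[ids].dropna().to_numpy(float) for g, ids in cols.items()}
        if any(v.size < min_per_group for v in vals.values()):
            rows.append((name, np.nan, np.nan, np.nan, np.nan, False))
            continue
        kw = _kw_p([vals["control"], vals["obesity"], vals["crc"]])
        m_oc = _mwu_p(vals["obesity"], vals[CONTROL_GROUP])
        m_cc = _mwu_p(vals["crc"], vals[CONTROL_GROUP])
        m_co = _mwu_p(vals["crc"], vals["obesity"])
        selected = kw <= alpha_margin and m_oc <= alpha_margin and m_cc <= alpha_margin
        rows.append((name, kw, m_oc, m_cc, m_co, selected))
    out = pd.DataFrame(
        rows,
        columns=[
            "name", "kw_p", "mwu_obesity_control", "mwu_crc_control",
            "mwu_crc_obesity", "selected",
        ],
    ).set_index("name")
    if annotations is not None:
        ann = annotations.reindex(out.index)
        out["subregion"] = ann
        out["selected_annotated"] = out["selected"] & ann.isin(require_subregions)
    return out


def subject_dotplot_table(matrix: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Long-form per-subject DMR means (region, sample, group, mean beta)."""
    group_of = dict(zip(sheet["sample_id"], sheet["group"]))
    long = matrix.reset_index(names="name").melt(
        id_vars="name", var_name="sample_id", value_name="mean_beta"
    )
    long["group"] = long["sample_id"].map(group_of)
    return long.dropna(subset=["mean_beta"]).reset_index(drop=True)
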