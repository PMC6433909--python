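"""Distance-based segmentation of tested CpGs into differentially
methylated regions.

Consecutive tested CpGs are merged whenever their gap is at most a
basepair cutoff learned from the data: nearest-neighbour distances
between tested CpGs are strongly bimodal on the log10 scale (within-
cluster vs between-cluster), and the cutoff is the crossing point of a
two-component Gaussian mixture fit to the pooled log-distances.  Region
significance combines member-site p-values by a direction-signed
Stouffer z (opposing sites cancel), without a correlation correction.

A region is reported when it holds at least 3 CpGs, at least 1
significant DMC, and an absolute mean methylation difference above 5
percentage points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

FALLBACK_CUTOFF_BP = 100.0


@dataclass(frozen=True)
class DmrThresholds:
    min_cpgs: int = 3
    min_dmcs: int = 1
    min_abs_mean_diff: float = 5.0


def distance_cutoff(tested: pd.DataFrame, min_sites: int = 100) -> float:
    """Basepair merge cutoff from the bimodal inter-CpG distance profile.

    Fits a 2-component Gaussian mixture to pooled log10 nearest-neighbour
    distances (per chromosome) and returns 10**x at the density crossing
    between the two means.  Falls back to 100 bp when there are fewer
    than ``min_sites`` CpGs or the mixture is degenerate (means closer
    than 0.2 in log10).
    """
    if len(tested) < min_sites:
        warnings.warn(
            f"only {len(tested)} tested sites; using fallback cutoff "
            f"{FALLBACK_CUTOFF_BP:g} bp",
            stacklevel=2,
        )
        return FALLBACK_CUTOFF_BP
    dists = []
    for _, grp in tested.groupby("chrom"):
        pos = np.sort(grp["pos"].to_numpy())
        if pos.size > 1:
            dists.append(np.diff(pos))
    gaps = np.concatenate(dists) if dists else np.array([])
    gaps = gaps[gaps > 0]
    if gaps.size < 2:
        return FALLBACK_CUTOFF_BP
    # sorting makes the fit invariant to chromosome/input order
    logd = np.sort(np.log10(gaps.astype(float)))[:, None]
    gm = GaussianMixture(n_components=2, random_state=0, n_init=1).fit(logd)
    means = gm.means_.ravel()
    order = np.argsort(means)
    m1, m2 = means[order]
    if m2 - m1 < 0.2:
        warnings.warn("unimodal distance profile; using fallback cutoff", stacklevel=2)
        return FALLBACK_CUTOFF_BP
    s1, s2 = np.sqrt(gm.covariances_.ravel()[order])
    w1, w2 = gm.weights_.ravel()[order]
    x = _gaussian_crossing(m1, s1, w1, m2, s2, w2)
    return float(10.0 ** x)


def _gaussian_crossing(m1, s1, w1, m2, s2, w2):
    """Density-equality point of two weighted Gaussians, restricted to
    (m1, m2); falls back to the midpoint when no root lies between."""
    a = 0.5 / s2**2 - 0.5 / s1**2
    b = m1 / s1**2 - m2 / s2**2
    c = (
        0.5 * (m2**2 / s2**2 - m1**2 / s1**2)
        + np.log((w1 * s2) / (w2 * s1))
    )
    if abs(a) < 1e-12:
        roots = [-c / b] if abs(b) > 1e-12 else []
    else:
        disc = b**2 - 4 * a * c
        roots = [] if disc < 0 else [(-b + s * np.sqrt(disc)) / (2 * a) for s in (1, -1)]
    inside = [r for r in roots if m1 < r < m2]
    return min(inside, key=lambda r: abs(r - (m1 + m2) / 2)) if inside else 0.5 * (m1 + m2)


def segment_sites(positions: np.ndarray, cutoff: float) -> list[tuple[int, int]]:
    """Split sorted positions into runs with consecutive gaps <= cutoff.

    Returns (start_index, end_index) half-open index pairs.
    """
    if positions.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(positions) > cutoff)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks + 1, [positions.size]])
    return list(zip(starts.tolist(), ends.tolist()))


def call_dmrs(
    dmc_table: pd.DataFrame,
    cutoff: float,
    thresholds: DmrThresholds = DmrThresholds(),
) -> pd.DataFrame:
    """Segment all tested sites and keep regions passing the filters.

    ``dmc_table`` is the full tested-site table from the DMC caller (not
    just significant sites).  Region p combines member p-values by signed
    Stouffer; region q is Benjamini-Hochberg over all candidate regions
    before filtering.  Output intervals are 0-based half-open with every
    member CpG inside [start, end).
    """
    candidates = []
    for chrom, grp in dmc_table.groupby("chrom", sort=True):
        grp = grp.sort_values("pos", kind="mergesort")
        pos = grp["pos"].to_numpy()
        pv = np.clip(grp["pvalue"].to_numpy(float), 1e-300, 1.0)
        diff = grp["meth_diff"].to_numpy(float)
        sig = grp["significant"].to_numpy()
        for i0, i1 in segment_sites(pos, cutoff):
            k = i1 - i0
            z = norm.isf(pv[i0:i1] / 2.0) * np.sign(diff[i0:i1])
            Z = z.sum() / np.sqrt(k)
            candidates.append(
                {
                    "chrom": chrom,
                    "start": int(pos[i0]),
                    "end": int(pos[i1 - 1]) + 1,
                    "n_cpgs": int(k),
                    "n_dmcs": int(sig[i0:i1].sum()),
                    "mean_meth_diff": float(diff[i0:i1].mean()),
                    "region_p": float(2.0 * norm.sf(abs(Z))),
                    "members": pos[i0:i1].copy(),
                }
            )
    if not candidates:
        return pd.DataFrame(
            columns=[
                "chrom", "start", "end", "name", "n_cpgs", "n_dmcs",
                "mean_meth_diff", "direction", "region_p", "region_q", "members",
            ]
        )
    regions = pd.DataFrame(candidates)
    regions["region_q"] = multipletests(regions["region_p"], method="fdr_bh")[1]
    keep = (
        (regions["n_cpgs"] >= thresholds.min_cpgs)
        & (regions["n_dmcs"] >= thresholds.min_dmcs)
        & (regions["mean_meth_diff"].abs() > thresholds.min_abs_mean_diff)
    )
    regions = regions[keep].reset_index(drop=True)
    regions["direction"] = np.where(regions["mean_meth_diff"] > 0, "hyper", "hypo")
    regions["name"] = [
        f"dmr_{c}_{s}" for c, s in zip(regions["chrom"], regions["start"])
    ]
    cols = [
        "chrom", "start", "end", "name", "n_cpgs", "n_dmcs",
        "mean_meth_diff", "direction", "region_p", "region_q", "members",
    ]
    return regions[cols]


def dmr_bed_table(dmrs: pd.DataFrame) -> pd.DataFrame:
    """BED6+ view (drops the in-memory member-position arrays)."""
    return dmrs.drop(columns=["members"], errors="ignore")
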