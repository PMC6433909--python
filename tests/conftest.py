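import numpy as np
import pandas as pd
import pytest

from methcrossover import (
    SimulationConfig,
    make_planted_regions,
    simulate_annotation,
    simulate_methylation,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed cohort with planted regions of every class."""
    regions = make_planted_regions(
        {
            "concordant_hyper": 4,
            "concordant_hypo": 4,
            "obesity_only": 2,
            "crc_only": 2,
            "discordant": 2,
        },
        n_chrom=2,
        n_cpgs=5,
        effect=0.35,
    )
    cfg = SimulationConfig(
        n_control=6,
        n_obese=6,
        n_crc=6,
        n_chrom=2,
        cpg_per_chrom=300,
        coverage_mean=30,
        dispersion=0.02,
        planted_regions=regions,
        seed=11,
    )
    calls, sheet, truth = simulate_methylation(cfg)
    return cfg, calls, sheet, truth


@pytest.fixture(scope="session")
def small_annotation(small_cohort):
    cfg, *_ = small_cohort
    return simulate_annotation(cfg)


def brute_force_mwu_p(x, y) -> float:
    """Exact two-sided Mann-Whitney p by full enumeration of rank splits.

    p = P(|U - nm/2| >= |u_obs - nm/2|) under the permutation null;
    assumes no ties across the pooled sample.
    """
    from itertools import combinations

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    assert np.unique(pooled).size == pooled.size, "oracle assumes no ties"
    n, m = len(x), len(y)
    u_obs = sum((xi > yj) for xi in x for yj in y)
    center = n * m / 2.0
    hits = total = 0
    idx = range(n + m)
    for comb in combinations(idx, n):
        xs = pooled[list(comb)]
        ys = pooled[[i for i in idx if i not in comb]]
        u = sum((xi > yj) for xi in xs for yj in ys)
        if abs(u - center) >= abs(u_obs - center):
            hits += 1
        total += 1
    return hits / total


def reference_tmm(counts: pd.DataFrame, trim_m=0.30, trim_a=0.05) -> np.ndarray:
    """Independently coded TMM reference (plain loops, no shared helpers).

    Follows the published trimmed-mean-of-M-values recipe: reference
    sample by 75th count-proportion percentile closest to the mean,
    double trim on M and A, inverse-asymptotic-variance weights,
    geometric-mean-one rescaling.
    """
    mat = counts.to_numpy(float)
    nlib = mat.sum(axis=0)
    q75 = [np.quantile(mat[:, j] / nlib[j], 0.75) for j in range(mat.shape[1])]
    ref = int(np.argmin([abs(v - np.mean(q75)) for v in q75]))
    out = []
    for j in range(mat.shape[1]):
        if j == ref:
            out.append(1.0)
            continue
        Ms, As, ws = [], [], []
        for g in range(mat.shape[0]):
            o, r = mat[g, j], mat[g, ref]
            if o <= 0 or r <= 0:
                continue
            po, pr = o / nlib[j], r / nlib[ref]
            Ms.append(np.log2(po / pr))
            As.append(0.5 * np.log2(po * pr))
            ws.append((nlib[j] - o) / (nlib[j] * o) + (nlib[ref] - r) / (nlib[ref] * r))
        Ms, As, ws = map(np.asarray, (Ms, As, ws))
        n = len(Ms)
        if n == 0 or np.max(np.abs(Ms)) < 1e-6:
            out.append(1.0)
            continue
        rm = pd.Series(Ms).rank().to_numpy()
        ra = pd.Series(As).rank().to_numpy()
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        f = np.sum(Ms[keep] / ws[keep]) / np.sum(1.0 / ws[keep])
        out.append(2.0**f)
    out = np.asarray(out)
    return out / np.exp(np.mean(np.log(out)))
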