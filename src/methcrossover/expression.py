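"""Expression-side verification: TMM normalization, log-CPM, and
methylation-expression concordance.

The trimmed mean of M-values (TMM) scaling factor corrects for
composition bias between RNA-seq libraries: for each sample against a
reference, per-gene log2 expression ratios (M) and average log
abundances (A) are doubly trimmed (30% on M, 5% on A) and the factor is
two to the precision-weighted mean of the surviving M values, with the
factors rescaled to geometric mean 1.  Row-centered log-CPM of selected
genes then shows whether expression moves in the direction methylation
predicts when methylation is removed (e.g. wild-type vs DNMT-knockout
cells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Gene x sample counts with library sizes and TMM factors."""

    counts: pd.DataFrame
    factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts < 0).any().any():
            raise ValueError("negative counts")

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def normalize(self, **kwargs) -> "ExpressionMatrix":
        self.factors = tmm_factors(self.counts, **kwargs)
        return self

    def log_cpm(self, prior: float = 0.5) -> pd.DataFrame:
        if self.factors is None:
            self.normalize()
        return log_cpm(self.counts, self.factors, prior=prior)


def _quantile_factor(counts: np.ndarray, lib: np.ndarray, q: float = 0.75) -> np.ndarray:
    return np.array([np.quantile(counts[:, j] / lib[j], q) for j in range(counts.shape[1])])


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_column: str | None = None,
) -> pd.Series:
    """Per-sample TMM scaling factors (geometric mean 1).

    The reference is the sample whose 75th count-proportion percentile is
    closest to the mean across samples, unless ``ref_column`` pins it.
    Genes with zero counts in either the sample or the reference are
    excluded from each pairwise comparison; precision weights use the
    asymptotic binomial variance (1-p)/(n p) summed over the two
    libraries.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    mat = counts.to_numpy(float)
    if (mat.sum(axis=1) > 0).sum() < 50:
        warnings.warn("fewer than 50 expressed genes; TMM factors may be unstable", stacklevel=2)
    lib = mat.sum(axis=0)
    uq = _quantile_factor(mat, lib)
    if ref_column is not None:
        ref = list(counts.columns).index(ref_column)
    else:
        ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref:
            factors[j] = 1.0
            continue
        factors[j] = _tmm_pair(mat[:, j], lib[j], mat[:, ref], lib[ref], trim_m, trim_a)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _tmm_pair(obs, n_obs, ref, n_ref, trim_m, trim_a) -> float:
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        warnings.warn("sample shares no expressed genes with the reference; factor = 1", stacklevel=2)
        return 1.0
    o, r = obs[keep], ref[keep]
    po, pr = o / n_obs, r / n_ref
    M = np.log2(po / pr)
    A = 0.5 * np.log2(po * pr)
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    fin = np.isfinite(M) & np.isfinite(A) & np.isfinite(w)
    M, A, w = M[fin], A[fin], w[fin]
    if M.size == 0 or np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = M.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(M).rank().to_numpy()
    rank_a = pd.Series(A).rank().to_numpy()
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.sum(M[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    return float(2.0 ** f) if np.isfinite(f) else 1.0


def log_cpm(counts: pd.DataFrame, factors: pd.Series, prior: float = 0.5) -> pd.DataFrame:
    """log2(count / (lib_size * factor + 1) * 1e6 + prior).

    The pseudocount is added on the CPM scale, which makes the transform
    exactly invariant to a joint rescaling of counts and library sizes
    (a count-scale prior would shift zero-count genes by a full log2 unit
    when libraries scale).  A zero count in a 1e6-read library maps to
    log2(0.5) = -1.
    """
    lib = counts.sum(axis=0)
    eff = lib * factors.reindex(counts.columns)
    return np.log2(counts.div(eff + 1.0, axis=1) * 1e6 + prior)


def row_center(logcpm: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's mean across samples (heatmap scale='row' view,
    without the variance scaling)."""
    return logcpm.sub(logcpm.mean(axis=1), axis=0)


def concordance_report(
    logcpm: pd.DataFrame,
    expectation: pd.Series,
    condition_of: dict[str, str] | None = None,
    baseline: str | None = None,
) -> pd.DataFrame:
    """Does expression move as methylation predicts on demethylation?

    ``expectation`` maps gene -> "up" or "down": the expected direction
    of expression change from the baseline condition to the demethylated
    one (e.g. a gene whose promoter/body is hypermethylated in disease is
    expected to rise when methylation is removed).  ``condition_of`` maps
    sample -> condition; by default the prefix before the last "_" in
    each column name.  Returns per-gene row-centered condition means, the
    log-CPM difference, and an agree/disagree/neutral flag.
    """
    if condition_of is None:
        condition_of = {c: c.rsplit("_", 1)[0] for c in logcpm.columns}
    conds = list(dict.fromkeys(condition_of[c] for c in logcpm.columns))
    if len(conds) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {conds}")
    if baseline is None:
        baseline = conds[0]
    other = conds[1] if baseline == conds[0] else conds[0]
    centered = row_center(logcpm.loc[expectation.index])
    means = {
        cond: centered[[c for c in centered.columns if condition_of[c] == cond]].mean(axis=1)
        for cond in conds
    }
    delta = means[other] - means[baseline]
    flags = []
    for gene in expectation.index:
        d = delta[gene]
        exp = expectation[gene]
        if abs(d) < 1e-9:
            flags.append("neutral")
        elif (d > 0) == (exp == "up"):
            flags.append("agree")
        else:
            flags.append("disagree")
    return pd.DataFrame(
        {
            f"mean_centered_{baseline}": means[baseline],
            f"mean_centered_{other}": means[other],
            "delta_log_cpm": delta,
            "expected": expectation,
            "concordance": flags,
        }
    )
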