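"""Site filtering, between-sample coverage normalization, and the
histogram transformation that equalizes methylation-level distributions
to the control group."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import MethylationCallSet

#: chromosomes excluded from analysis by default: sex chromosomes and the
#: mitochondrion, under both UCSC-style and bare names.
DEFAULT_EXCLUDED_CHROMS = frozenset(
    {"chrX", "chrY", "chrM", "chrMT", "X", "Y", "M", "MT"}
)


@dataclass(frozen=True)
class FilterPolicy:
    """Per-sample site filters applied before differential testing.

    Sites with coverage below ``min_coverage`` (5X) or strictly above the
    per-sample ``max_coverage_quantile`` (99.9th percentile, linear
    interpolation) are dropped, as are all sites on excluded chromosomes.
    ``min_per_group`` is carried here for configuration but enforced at
    test time by the DMC caller, so samples stay independent.
    """

    min_coverage: int = 5
    max_coverage_quantile: float = 0.999
    excluded_chroms: frozenset = field(default_factory=lambda: DEFAULT_EXCLUDED_CHROMS)
    min_per_group: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.max_coverage_quantile <= 1):
            raise ValueError("max_coverage_quantile must be in (0, 1]")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        object.__setattr__(self, "excluded_chroms", frozenset(self.excluded_chroms))


def filter_calls(calls: MethylationCallSet, policy: FilterPolicy) -> MethylationCallSet:
    """Apply the coverage and chromosome filters to one sample."""
    d = calls.data
    keep = ~d["chrom"].isin(policy.excluded_chroms)
    d = d[keep]
    if len(d):
        hi = np.quantile(d["coverage"].to_numpy(), policy.max_coverage_quantile)
        d = d[(d["coverage"] >= policy.min_coverage) & (d["coverage"] <= hi)]
    if len(d) == 0:
        warnings.warn(f"{calls.sample_id}: no sites survive filtering", stacklevel=2)
    return MethylationCallSet(calls.sample_id, d.reset_index(drop=True))


def normalize_coverage(samples: list[MethylationCallSet]) -> list[MethylationCallSet]:
    """Scale each sample's coverage toward the cohort's grand median.

    Each sample's coverages are multiplied by (median of per-sample median
    coverages) / (its own median coverage), rounded, floored at 1;
    methylated counts are re-derived from the original beta so the
    methylation level is preserved up to rounding.
    """
    if len(samples) < 2:
        raise ValueError("coverage normalization needs at least 2 samples")
    medians = np.array([s.data["coverage"].median() for s in samples], dtype=float)
    grand = float(np.median(medians))
    out = []
    for s, med in zip(samples, medians):
        scale = grand / med if med > 0 else 1.0
        d = s.data.copy()
        beta = d["n_meth"] / d["coverage"]
        new_cov = np.maximum(1, np.round(d["coverage"] * scale)).astype(np.int64)
        new_meth = np.minimum(new_cov, np.round(beta * new_cov)).astype(np.int64)
        d["coverage"] = new_cov
        d["n_meth"] = new_meth
        out.append(MethylationCallSet(s.sample_id, d))
    return out


def histogram_transform(
    case_samples: list[MethylationCallSet],
    control_samples: list[MethylationCallSet],
) -> list[MethylationCallSet]:
    """Quantile-match each case sample's beta values to the pooled control
    beta distribution.

    For every case sample, each site's beta is replaced by the pooled-
    control quantile at that site's within-sample empirical quantile
    (average ranks, so tied betas map identically).  Coverage is
    unchanged; the methylated count is re-rounded from the mapped beta.
    The mapping is monotone non-decreasing, so within-sample rank order
    is preserved exactly.
    """
    if not control_samples:
        raise ValueError("control pool is empty")
    pool = np.sort(
        np.concatenate([(s.data["n_meth"] / s.data["coverage"]).to_numpy() for s in control_samples])
    )
    if pool.size == 0:
        raise ValueError("control pool has no sites")
    if pool[0] == pool[-1]:
        raise ValueError("degenerate control distribution: all beta values equal")
    out = []
    for s in case_samples:
        d = s.data.copy()
        beta = (d["n_meth"] / d["coverage"]).to_numpy()
        q = (rankdata(beta, method="average") - 0.5) / beta.size
        mapped = np.quantile(pool, q, method="linear")
        d["n_meth"] = np.minimum(
            d["coverage"], np.round(mapped * d["coverage"])
        ).astype(np.int64)
        out.append(MethylationCallSet(s.sample_id, d))
    return out
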