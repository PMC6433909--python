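"""Gene-set enrichment by the EASE score (modified one-sided Fisher test).

The EASE score is Fisher's exact test with one gene removed from the
query-term overlap before computing the tail -- equivalently, the
hypergeometric tail P(X >= k - 1) at unchanged margins.  It is
deliberately conservative: a single-gene overlap can never be called
(p = 1).  Term databases are user-supplied (GMT format); a toy
collection is used in tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

SIGNIFICANCE_P = 0.05


@dataclass
class GeneSetCollection:
    """Named gene sets over a background universe."""

    sets: dict[str, tuple[str, frozenset]]  # term_id -> (term_name, members)
    background: frozenset

    def __post_init__(self) -> None:
        self.background = frozenset(self.background)
        clean = {}
        for term_id, (name, members) in self.sets.items():
            members = frozenset(members)
            stray = members - self.background
            if stray:
                raise ValueError(
                    f"term {term_id!r} has members outside the background: {sorted(stray)[:5]}"
                )
            clean[term_id] = (name, members)
        self.sets = clean


def read_gmt(path, background: set | None = None) -> GeneSetCollection:
    """GMT: term_id <tab> term_name <tab> gene1 <tab> gene2 ...

    The background defaults to the union of all term members.
    """
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = (parts[1], frozenset(g for g in parts[2:] if g))
    if background is None:
        background = set().union(*(m for _, m in sets.values())) if sets else set()
    return GeneSetCollection(sets=sets, background=frozenset(background))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term_id, (name, members) in collection.sets.items():
            fh.write("\t".join([term_id, name, *sorted(members)]) + "\n")


def ease_pvalue(k: int, n_query: int, n_term: int, n_background: int) -> float:
    """EASE p from the 2x2 margins: P(X >= k - 1), X ~ Hypergeom(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(min(hypergeom.sf(k - 2, n_background, n_term, n_query), 1.0))


def ease_test(query, term_genes, background) -> tuple[float, int, list[str]]:
    """EASE p-value for one term.

    With N = |background|, K = |term|, n = |query| and overlap k, the
    p-value is P(X >= k - 1) for X ~ Hypergeom(N, K, n); k = 0 gives
    p = 1 by convention (and k = 1 gives p = 1 by construction).
    Returns (p, k, sorted overlap genes).
    """
    background = frozenset(background)
    term = frozenset(term_genes) & background
    q = frozenset(query)
    stray = q - background
    if stray:
        warnings.warn(
            f"{len(stray)} query genes not in background were dropped", stacklevel=2
        )
        q &= background
    k = len(q & term)
    return ease_pvalue(k, len(q), len(term), len(background)), k, sorted(q & term)


def enrich_all(query, collection: GeneSetCollection) -> pd.DataFrame:
    """EASE-test the query against every term; ascending p.

    ``gene_count`` is the raw (undecremented) overlap.  ``significant``
    flags terms with p < 0.05.
    """
    rows = []
    for term_id, (name, members) in collection.sets.items():
        p, k, genes = ease_test(query, members, collection.background)
        rows.append((term_id, name, k, p, ",".join(genes)))
    out = pd.DataFrame(rows, columns=["term_id", "term_name", "gene_count", "p", "genes"])
    out["significant"] = out["p"] < SIGNIFICANCE_P
    return out.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
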