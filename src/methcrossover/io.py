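"""Readers, writers and validated containers for the formats the pipeline touches.

All genomic coordinates are 0-based half-open internally.  The Bismark-style
coverage dialect on disk is 1-based with start == end per CpG; conversion
happens at the file boundary and nowhere else.  Every reader/writer pair
round-trips exactly, and all of them are gzip-transparent (pandas infers
compression from the ``.gz`` suffix).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("control", "obesity", "crc")
SEXES = ("F", "M", "unknown")

COVERAGE_COLUMNS = ["chrom", "start", "end", "meth_pct", "n_meth", "n_unmeth"]


class FormatError(ValueError):
    """A file violated the dialect or an internal invariant."""


# ---------------------------------------------------------------------------
# methylation calls
# ---------------------------------------------------------------------------


@dataclass
class MethylationCallSet:
    """Per-sample CpG methylation calls.

    ``data`` holds one row per site with columns ``chrom`` (str), ``pos``
    (0-based int), ``strand`` (one of ``+ - .``), ``coverage`` and ``n_meth``
    (read counts).  Rows are sorted by (chrom, pos) and unique per
    (chrom, pos, strand).
    """

    sample_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        d = self.data
        missing = {"chrom", "pos", "strand", "coverage", "n_meth"} - set(d.columns)
        if missing:
            raise FormatError(f"{self.sample_id}: missing columns {sorted(missing)}")
        if (d["coverage"] < 1).any():
            bad = d.index[d["coverage"] < 1][0]
            raise FormatError(
                f"{self.sample_id}: coverage < 1 at {d.at[bad, 'chrom']}:{d.at[bad, 'pos']}"
            )
        if (d["n_meth"] > d["coverage"]).any():
            bad = d.index[d["n_meth"] > d["coverage"]][0]
            raise FormatError(
                f"{self.sample_id}: methylated count exceeds coverage at "
                f"{d.at[bad, 'chrom']}:{d.at[bad, 'pos']}"
            )
        if (d["n_meth"] < 0).any():
            raise FormatError(f"{self.sample_id}: negative methylated count")
        dup = d.duplicated(subset=["chrom", "pos", "strand"])
        if dup.any():
            bad = d.index[dup][0]
            raise FormatError(
                f"{self.sample_id}: duplicate site "
                f"{d.at[bad, 'chrom']}:{d.at[bad, 'pos']}({d.at[bad, 'strand']})"
            )
        order = d.sort_values(["chrom", "pos"], kind="mergesort").index
        if not (order == d.index).all():
            self.data = d.loc[order].reset_index(drop=True)

    @property
    def beta(self) -> pd.Series:
        """Methylation level n_meth / coverage, in [0, 1]."""
        return self.data["n_meth"] / self.data["coverage"]

    def __len__(self) -> int:
        return len(self.data)

    def copy(self) -> "MethylationCallSet":
        return MethylationCallSet(self.sample_id, self.data.copy())


def read_coverage_file(path, sample_id: str | None = None) -> MethylationCallSet:
    """Read a Bismark-coverage-style TSV into a :class:`MethylationCallSet`.

    Columns: chrom, start (1-based), end (== start), methylation %,
    methylated count, unmethylated count.  The strand is not recorded in
    this dialect and is stored as ``.``.
    """
    if sample_id is None:
        sample_id = _stem(path)
    try:
        raw = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=COVERAGE_COLUMNS,
            dtype={"chrom": str},
            comment="#",
        )
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame(columns=COVERAGE_COLUMNS)
    if len(raw) == 0:
        warnings.warn(f"{path}: empty coverage file", stacklevel=2)
    for col in ("start", "end", "n_meth", "n_unmeth"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        if vals.isna().any():
            line = int(vals.index[vals.isna()][0]) + 1
            raise FormatError(f"{path}: malformed value in column '{col}' at line {line}")
        raw[col] = vals.astype(np.int64)
    if ((raw["n_meth"] < 0) | (raw["n_unmeth"] < 0)).any():
        line = int(raw.index[(raw["n_meth"] < 0) | (raw["n_unmeth"] < 0)][0]) + 1
        raise FormatError(f"{path}: negative count at line {line}")
    data = pd.DataFrame(
        {
            "chrom": raw["chrom"],
            "pos": raw["start"] - 1,  # 1-based inclusive -> 0-based
            "strand": ".",
            "coverage": raw["n_meth"] + raw["n_unmeth"],
            "n_meth": raw["n_meth"],
        }
    )
    return MethylationCallSet(sample_id, data)


def write_coverage_file(calls: MethylationCallSet, path) -> None:
    d = calls.data
    beta_pct = 100.0 * d["n_meth"] / d["coverage"]
    out = pd.DataFrame(
        {
            "chrom": d["chrom"],
            "start": d["pos"] + 1,
            "end": d["pos"] + 1,
            "meth_pct": beta_pct,
            "n_meth": d["n_meth"],
            "n_unmeth": d["coverage"] - d["n_meth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet CSV: sample_id, group, age, sex."""
    sheet = pd.read_csv(path, dtype={"sample_id": str})
    return validate_sample_sheet(sheet)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "group", "age", "sex"}
    missing = required - set(sheet.columns)
    if missing:
        raise FormatError(f"sample sheet missing columns {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample id {dup!r}")
    bad_group = ~sheet["group"].isin(GROUPS)
    if bad_group.any():
        raise FormatError(
            f"unknown group {sheet.loc[bad_group, 'group'].iloc[0]!r}; expected one of {GROUPS}"
        )
    bad_sex = ~sheet["sex"].isin(SEXES)
    if bad_sex.any():
        raise FormatError(
            f"unknown sex {sheet.loc[bad_sex, 'sex'].iloc[0]!r}; expected one of {SEXES}"
        )
    return sheet.reset_index(drop=True)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    validate_sample_sheet(sheet).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# gene models and CpG islands
# ---------------------------------------------------------------------------


@dataclass
class Gene:
    """A toy gene model: strand-aware TSS plus an exon chain.

    ``tx_start``/``tx_end`` default to the exon envelope; exons must lie
    inside the transcript span.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: list[tuple[int, int]]
    tx_start: int | None = None
    tx_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise FormatError(f"{self.gene_id}: gene has no exons")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for a, b in self.exons:
            if b <= a:
                raise FormatError(f"{self.gene_id}: exon end {b} <= start {a}")
        for (_, b1), (a2, _) in zip(self.exons, self.exons[1:]):
            if a2 < b1:
                raise FormatError(f"{self.gene_id}: overlapping exons")
        if self.tx_start is None:
            self.tx_start = self.exons[0][0]
        if self.tx_end is None:
            self.tx_end = self.exons[-1][1]
        if self.exons[0][0] < self.tx_start or self.exons[-1][1] > self.tx_end:
            raise FormatError(f"{self.gene_id}: exon outside gene span")

    @property
    def span(self) -> tuple[int, int]:
        return (self.tx_start, self.tx_end)


@dataclass
class GenomeAnnotation:
    """Gene models plus merged CpG-island intervals."""

    genes: list[Gene]
    islands: pd.DataFrame  # chrom, start, end (0-based half-open, merged)
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.islands = merge_intervals(self.islands)

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


def merge_intervals(bed: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/touching intervals per chromosome."""
    if len(bed) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    if (bed["end"] <= bed["start"]).any():
        bad = bed.index[bed["end"] <= bed["start"]][0]
        raise FormatError(
            f"interval end <= start: {bed.at[bad, 'chrom']}:"
            f"{bed.at[bad, 'start']}-{bed.at[bad, 'end']}"
        )
    out = []
    for chrom, grp in bed.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"]).astype(
        {"start": np.int64, "end": np.int64}
    )


def read_bed(path) -> pd.DataFrame:
    """BED3/BED6; returns chrom/start/end (+ name/score/strand if present)."""
    try:
        bed = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    names = ["chrom", "start", "end", "name", "score", "strand"][: bed.shape[1]]
    bed.columns = names
    bed["start"] = bed["start"].astype(np.int64)
    bed["end"] = bed["end"].astype(np.int64)
    if (bed["end"] <= bed["start"]).any():
        line = int(bed.index[bed["end"] <= bed["start"]][0]) + 1
        raise FormatError(f"{path}: interval end <= start at line {line}")
    return bed


def write_bed(records: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in records.columns]
    records[cols].to_csv(path, sep="\t", header=False, index=False)


GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "tx_start", "tx_end", "exon_starts", "exon_ends"]


def read_gene_models(path) -> list[Gene]:
    """refFlat-like TSV: gene_id, chrom, strand, tss, tx_start, tx_end,
    comma-joined exon_starts / exon_ends."""
    tab = pd.read_csv(path, sep="\t", header=None, names=GENE_COLUMNS, dtype={"chrom": str})
    genes = []
    for row in tab.itertuples(index=False):
        starts = [int(x) for x in str(row.exon_starts).rstrip(",").split(",")]
        ends = [int(x) for x in str(row.exon_ends).rstrip(",").split(",")]
        if len(starts) != len(ends):
            raise FormatError(f"{row.gene_id}: exon_starts/exon_ends length mismatch")
        genes.append(
            Gene(
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                strand=str(row.strand),
                tss=int(row.tss),
                exons=list(zip(starts, ends)),
                tx_start=int(row.tx_start),
                tx_end=int(row.tx_end),
            )
        )
    return genes


def write_gene_models(genes: list[Gene], path) -> None:
    rows = [
        (
            g.gene_id,
            g.chrom,
            g.strand,
            g.tss,
            g.tx_start,
            g.tx_end,
            ",".join(str(a) for a, _ in g.exons),
            ",".join(str(b) for _, b in g.exons),
        )
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_COLUMNS).to_csv(path, sep="\t", header=False, index=False)


def read_annotation(genes_path, islands_path) -> GenomeAnnotation:
    genes = read_gene_models(genes_path)
    islands = read_bed(islands_path)[["chrom", "start", "end"]]
    return GenomeAnnotation(genes=genes, islands=islands)


# ---------------------------------------------------------------------------
# counts and generic reports
# ---------------------------------------------------------------------------


def read_counts(path) -> pd.DataFrame:
    """Gene x sample integer count matrix, gene ids in the first column."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if (counts < 0).any().any():
        raise FormatError(f"{path}: negative count")
    return counts.astype(np.int64)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def write_report(table: pd.DataFrame, path, index: bool = False) -> None:
    """Write any result table as TSV (column headers kept)."""
    table.to_csv(path, sep="\t", index=index)


def _stem(path) -> str:
    name = str(path).rsplit("/", 1)[-1]
    for suffix in (".gz", ".cov", ".tsv", ".txt"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return name
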