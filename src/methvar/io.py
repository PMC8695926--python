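"""Readers and writers for the tabular formats the pipeline touches.

Formats handled here:

* per-CpG methylation call tables (methratio-style TSV: one row per cytosine
  with methylated / total read counts),
* BED-like gene annotation files (0-based half-open on disk, converted to the
  internal 1-based inclusive convention at the boundary),
* sample sheets (sample id, tissue, location, condition, dataset, path),
* gene x sample methylation matrices with "NA" as the missing-value token.

Also provides the bisulfite conversion-rate QC, estimated from non-CpG
cytosines (assumed unmethylated), pooled across sites.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from os import PathLike
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CpGSiteRecord",
    "GeneModel",
    "SampleRecord",
    "TableFormatError",
    "read_methylation_table",
    "write_methylation_table",
    "collapse_strands",
    "read_gene_bed",
    "write_gene_bed",
    "read_sample_sheet",
    "compute_conversion_rate",
    "read_methylation_matrix",
    "write_methylation_matrix",
]

#: columns a methylation call table must provide
SITE_COLUMNS = ["scaffold", "position", "strand", "context", "meth_count", "total_count"]

CPG_CONTEXT = "CpG"
NON_CPG_CONTEXTS = ("CHG", "CHH")


class TableFormatError(ValueError):
    """A file did not conform to the expected tabular dialect."""


@dataclass(frozen=True)
class CpGSiteRecord:
    """One cytosine's counts in one sample.

    ``position`` is the 1-based coordinate of the C on the plus strand.
    ``ratio`` is ``meth_count / total_count`` and is undefined (NaN) when
    coverage is zero.
    """

    scaffold: str
    position: int
    strand: str
    context: str
    meth_count: int
    total_count: int

    def __post_init__(self) -> None:
        if self.meth_count < 0 or self.total_count < 0:
            raise ValueError("counts must be non-negative")
        if self.meth_count > self.total_count:
            raise ValueError(
                f"meth_count {self.meth_count} exceeds total_count {self.total_count}"
            )
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")

    @property
    def ratio(self) -> float:
        if self.total_count == 0:
            return float("nan")
        return self.meth_count / self.total_count


@dataclass(frozen=True)
class GeneModel:
    """A gene interval in the internal 1-based inclusive convention."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str = "."
    n_fraction: float = 0.0
    is_housekeeping: bool = False
    te_overlap: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if not 0.0 <= self.n_fraction <= 1.0:
            raise ValueError(f"gene {self.gene_id}: n_fraction outside [0, 1]")

    def contains(self, position: int) -> bool:
        """1-based inclusive membership test."""
        return self.start <= position <= self.end


@dataclass(frozen=True)
class SampleRecord:
    """One sequencing sample and its design labels."""

    sample_id: str
    tissue: str
    location: str
    condition: str = "wild"
    dataset: str = "capture"
    path: str | None = None


GENE_COLUMNS = [
    "gene_id",
    "scaffold",
    "start",
    "end",
    "strand",
    "n_fraction",
    "is_housekeeping",
    "te_overlap",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_methylation_table(
    path: str | PathLike,
    context: str | None = CPG_CONTEXT,
    merge_strands: bool = True,
) -> pd.DataFrame:
    """Read a methratio-style per-cytosine call table.

    Parameters
    ----------
    path
        Tab-separated file with a header naming at least
        ``scaffold, position, strand, context, meth_count, total_count``.
    context
        Keep only rows in this sequence context (``"CpG"``, ``"CHG"``,
        ``"CHH"``); ``None`` keeps every row.
    merge_strands
        For symmetric CpG dyads, add minus-strand counts at position ``p + 1``
        into the plus-strand record at ``p`` so that each CpG site yields a
        single ratio. Non-CpG contexts are never merged.

    Returns
    -------
    DataFrame with the six required columns plus a ``ratio`` column
    (NaN where coverage is zero). Zero-coverage rows are retained.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"scaffold": str, "strand": str, "context": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TableFormatError(f"{path}: cannot parse as TSV ({exc})") from exc
    _require_columns(df, SITE_COLUMNS, path)
    df = df[SITE_COLUMNS].copy()

    for col in ("position", "meth_count", "total_count"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round())
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
            raise TableFormatError(f"{path}: line {row}: non-integer value in column '{col}'")
        df[col] = numeric.astype(np.int64)

    bad = (df["meth_count"] > df["total_count"]) | (df["meth_count"] < 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise TableFormatError(f"{path}: line {row}: meth_count exceeds total_count")
    if (df["position"] < 1).any():
        row = int(np.flatnonzero((df["position"] < 1).to_numpy())[0]) + 2
        raise TableFormatError(f"{path}: line {row}: positions are 1-based and must be >= 1")

    if context is not None:
        df = df[df["context"] == context].reset_index(drop=True)
    if merge_strands:
        df = collapse_strands(df)
    total = df["total_count"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        df["ratio"] = np.where(total > 0, df["meth_count"].to_numpy() / total, np.nan)
    return df


def collapse_strands(sites: pd.DataFrame) -> pd.DataFrame:
    """Merge minus-strand records of symmetric CpG dyads into the plus strand.

    A CpG on the plus strand at position ``p`` pairs with the complementary
    CpG on the minus strand at ``p + 1``; their counts are summed and reported
    at ``p``. Minus-strand CpG records without a plus partner are re-anchored
    to ``p`` on the plus strand. Non-CpG rows pass through untouched.
    """
    is_cpg = sites["context"] == CPG_CONTEXT
    cpg = sites[is_cpg].copy()
    rest = sites[~is_cpg]
    if cpg.empty:
        return sites.reset_index(drop=True)
    minus = cpg["strand"] == "-"
    cpg.loc[minus, "position"] = cpg.loc[minus, "position"] - 1
    cpg["strand"] = "+"
    merged = (
        cpg.groupby(["scaffold", "position"], as_index=False, sort=True)
        .agg(
            strand=("strand", "first"),
            context=("context", "first"),
            meth_count=("meth_count", "sum"),
            total_count=("total_count", "sum"),
        )
    )
    merged = merged[SITE_COLUMNS]
    out = pd.concat([merged, rest[SITE_COLUMNS]], ignore_index=True)
    return out.sort_values(["scaffold", "position"], kind="mergesort").reset_index(drop=True)


def write_methylation_table(sites: pd.DataFrame, path: str | PathLike) -> None:
    """Write a per-cytosine call table in the dialect ``read_methylation_table`` expects."""
    cols = [c for c in SITE_COLUMNS if c in sites.columns]
    _require_columns(sites, SITE_COLUMNS, path)
    sites[cols].to_csv(path, sep="\t", index=False)


def read_gene_bed(path: str | PathLike) -> pd.DataFrame:
    """Read gene intervals from a BED-like file.

    On disk the intervals are 0-based half-open; internally they become
    1-based inclusive (``start = bed_start + 1``, ``end = bed_end``).
    Columns beyond ``chrom start end name`` are interpreted positionally as
    ``score`` (ignored), ``strand``, ``n_fraction``, ``is_housekeeping``,
    ``te_overlap``; absent columns default to ``.`` / 0 / false.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise TableFormatError(
                    f"{path}: line {lineno}: expected at least 4 BED columns, got {len(fields)}"
                )
            scaffold, bed_start, bed_end, name = fields[:4]
            try:
                bed_start, bed_end = int(bed_start), int(bed_end)
            except ValueError as exc:
                raise TableFormatError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if bed_end <= bed_start:
                raise TableFormatError(
                    f"{path}: line {lineno}: empty or inverted interval "
                    f"({bed_start}, {bed_end}) for {name}"
                )
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            n_fraction = float(fields[6]) if len(fields) > 6 else 0.0
            is_hk = _parse_flag(fields[7], path, lineno) if len(fields) > 7 else False
            te = _parse_flag(fields[8], path, lineno) if len(fields) > 8 else False
            gene = GeneModel(
                gene_id=name,
                scaffold=scaffold,
                start=bed_start + 1,
                end=bed_end,
                strand=strand,
                n_fraction=n_fraction,
                is_housekeeping=is_hk,
                te_overlap=te,
            )
            rows.append(dataclasses.asdict(gene))
    df = pd.DataFrame(rows, columns=GENE_COLUMNS)
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise TableFormatError(f"{path}: duplicate gene id {dup!r}")
    return df


def _parse_flag(token: str, path, lineno: int) -> bool:
    if token in ("0", "1"):
        return token == "1"
    if token.lower() in ("true", "false"):
        return token.lower() == "true"
    raise TableFormatError(f"{path}: line {lineno}: boolean flag must be 0/1, got {token!r}")


def write_gene_bed(genes: pd.DataFrame, path: str | PathLike) -> None:
    """Write genes back to the 0-based half-open BED dialect ``read_gene_bed`` reads."""
    with open(path, "w") as fh:
        for g in genes.itertuples(index=False):
            fh.write(
                "\t".join(
                    [
                        str(g.scaffold),
                        str(g.start - 1),
                        str(g.end),
                        str(g.gene_id),
                        "0",
                        g.strand if g.strand in ("+", "-") else ".",
                        f"{g.n_fraction:.6g}",
                        "1" if g.is_housekeeping else "0",
                        "1" if g.te_overlap else "0",
                    ]
                )
                + "\n"
            )


def read_sample_sheet(path: str | PathLike) -> pd.DataFrame:
    """Read a sample sheet TSV: sample_id, tissue, location, condition, dataset[, path]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["sample_id", "tissue", "location"], path)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise TableFormatError(f"{path}: duplicate sample id {dup!r}")
    for col, default in (("condition", "wild"), ("dataset", "capture")):
        if col not in df.columns:
            df[col] = default
    return df


def compute_conversion_rate(sites: pd.DataFrame) -> float:
    """Bisulfite conversion rate from non-CpG cytosines, pooled across sites.

    Non-CpG cytosines are assumed unmethylated in this species, so any
    apparent methylation there reflects conversion failure. Returns
    ``1 - sum(meth_count) / sum(total_count)`` over CHG/CHH rows. Pooling
    (rather than averaging per-site rates) keeps low-coverage sites from
    dominating the estimate.
    """
    non_cpg = sites[sites["context"].isin(NON_CPG_CONTEXTS)]
    total = int(non_cpg["total_count"].sum())
    if total == 0:
        raise ValueError("conversion rate undefined: no non-CpG coverage")
    return 1.0 - int(non_cpg["meth_count"].sum()) / total


# -- methylation matrix TSV -------------------------------------------------

_NCPG_COLUMN = "n_cpgs_used"


def write_methylation_matrix(matrix, path: str | PathLike) -> None:
    """Write a gene x sample matrix as TSV (genes as rows, "NA" for missing).

    The per-gene count of qualifying CpGs is carried in an ``n_cpgs_used``
    column so the file round-trips losslessly with ``read_methylation_matrix``.
    """
    values = matrix.values
    if values.empty:
        raise ValueError("refusing to write an empty methylation matrix")
    out = values.copy()
    out.insert(0, _NCPG_COLUMN, matrix.n_cpgs_used.reindex(values.index).astype("Int64"))
    out.to_csv(path, sep="\t", index_label="gene_id", na_rep="NA", float_format="%.6f")


def read_methylation_matrix(path: str | PathLike):
    """Read a matrix written by :func:`write_methylation_matrix`."""
    from .aggregate import MethylationMatrix

    df = pd.read_csv(path, sep="\t", index_col="gene_id", na_values=["NA"])
    if _NCPG_COLUMN in df.columns:
        n_cpgs = df.pop(_NCPG_COLUMN).fillna(0).astype(int)
    else:
        n_cpgs = pd.Series(0, index=df.index, dtype=int)
    return MethylationMatrix(values=df.astype(float), n_cpgs_used=n_cpgs)
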