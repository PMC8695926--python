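"""Variable-gene discovery and the core-set filtering cascade.

Two stages mirror the study design:

1. *Discovery* (whole-genome stage): keep genes whose cross-sample variance
   of average methylation exceeds a cutoff, then drop genes that are
   consistently methylated or unmethylated (mean ratio > 0.8 or < 0.2).
2. *Core-set filtering* (capture stage): from the pre-selected variable
   genes, drop genes with > 50% Ns in their sequence, genes without a
   computable average (coverage qualification encoded as missingness),
   genes in the bottom decile of methylation variance, and genes with an
   overall mean level < 0.1 or > 0.9.

Every stage is recorded in a :class:`FilterReport` so the cascade is fully
auditable and deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from os import PathLike

import numpy as np
import pandas as pd

from .aggregate import MethylationMatrix

__all__ = [
    "FilterStage",
    "FilterReport",
    "gene_variance",
    "discover_variable_genes",
    "core_set_filter",
]


@dataclass(frozen=True)
class FilterStage:
    name: str
    criterion: str
    n_before: int
    n_after: int
    removed: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_after > self.n_before:
            raise ValueError(f"stage {self.name}: n_after > n_before")
        if self.n_before - self.n_after != len(self.removed):
            raise ValueError(f"stage {self.name}: removed ids inconsistent with counts")


@dataclass
class FilterReport:
    """Ordered audit trail of a filtering cascade."""

    stages: list[FilterStage] = field(default_factory=list)

    def add(self, name: str, criterion: str, before: list[str], after: list[str]) -> list[str]:
        kept = set(after)
        removed = tuple(g for g in before if g not in kept)
        stage = FilterStage(name, criterion, len(before), len(after), removed)
        if self.stages and self.stages[-1].n_after != stage.n_before:
            raise ValueError("stage counts do not chain")
        self.stages.append(stage)
        return after

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.name,
                    "criterion": s.criterion,
                    "n_before": s.n_before,
                    "n_after": s.n_after,
                }
                for s in self.stages
            ]
        )

    def write_tsv(self, path: str | PathLike) -> None:
        """Serialize stage summary plus per-stage removed-gene lists."""
        df = self.to_frame()
        df["removed_genes"] = [",".join(s.removed) for s in self.stages]
        df.to_csv(path, sep="\t", index=False)

    def __str__(self) -> str:  # cascade summary for logs / CLI
        lines = ["stage\tcriterion\tn_before\tn_after"]
        for s in self.stages:
            lines.append(f"{s.name}\t{s.criterion}\t{s.n_before}\t{s.n_after}")
        return "\n".join(lines)


def gene_variance(values) -> float:
    """Sample variance (n-1 denominator) over non-missing values of one gene row."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("gene variance needs at least 2 non-missing values")
    return float(v.var(ddof=1))


def _row_variances(values: pd.DataFrame) -> pd.Series:
    """nan-aware per-gene sample variance; NaN where < 2 values are present."""
    return values.var(axis=1, ddof=1, skipna=True)


def discover_variable_genes(
    matrix: MethylationMatrix,
    var_cutoff: float = 0.006,
    band: tuple[float, float] = (0.2, 0.8),
) -> tuple[list[str], list[str], FilterReport]:
    """Select variably methylated genes from a gene x sample matrix.

    Stage 1 keeps genes with cross-sample variance strictly above
    ``var_cutoff`` (genes with fewer than two non-missing values have no
    variance and cannot pass). Stage 2 removes genes that are consistently
    methylated or unmethylated: mean ratio strictly above ``band[1]`` or
    strictly below ``band[0]``.

    Returns ``(variable_gene_ids, consistently_methylated_ids, report)``;
    both lists preserve the matrix's gene order.
    """
    low, high = band
    if low >= high:
        raise ValueError(f"degenerate band: low {low} >= high {high}")
    if matrix.values.shape[1] < 2:
        raise ValueError("discovery needs a matrix over at least 2 samples")

    genes = list(matrix.values.index)
    variances = _row_variances(matrix.values)
    means = matrix.values.mean(axis=1, skipna=True)

    report = FilterReport()
    passing = [g for g in genes if np.isfinite(variances[g]) and variances[g] > var_cutoff]
    report.add("variance_cutoff", f"variance > {var_cutoff}", genes, passing)

    consistent = [g for g in passing if means[g] > high or means[g] < low]
    variable = [g for g in passing if not (means[g] > high or means[g] < low)]
    report.add("mean_ratio_band", f"{low} <= mean ratio <= {high}", passing, variable)
    return variable, consistent, report


def core_set_filter(
    matrix: MethylationMatrix,
    genes: pd.DataFrame,
    max_n_fraction: float = 0.5,
    bottom_variance_quantile: float = 0.10,
    level_band: tuple[float, float] = (0.1, 0.9),
) -> tuple[list[str], FilterReport]:
    """Filter a pre-selected variable gene set down to the analysis core set.

    Applied in order:

    a. drop genes whose sequence is more than ``max_n_fraction`` Ns;
    b. drop genes without a computable average — i.e. fewer than two
       non-missing matrix values (coverage qualification upstream encodes
       "insufficient qualifying CpGs" as missingness);
    c. drop genes in the bottom ``bottom_variance_quantile`` of methylation
       variance among genes remaining at this point (nearest-rank boundary;
       ties at the boundary value are all removed);
    d. drop genes with an overall mean level strictly below ``level_band[0]``
       or strictly above ``level_band[1]``.

    ``matrix`` should already be restricted to the variable gene set.
    Survivors preserve the matrix's gene order; the result is invariant to
    input gene order.
    """
    gene_ids = list(matrix.values.index)
    if not gene_ids:
        raise ValueError("core_set_filter: empty input gene set")
    ann = genes.set_index("gene_id")
    unknown = [g for g in gene_ids if g not in ann.index]
    if unknown:
        raise ValueError(f"genes missing from annotation: {', '.join(unknown[:5])}")

    report = FilterReport()
    current = gene_ids
    keep = [g for g in current if ann.loc[g, "n_fraction"] <= max_n_fraction]
    current = report.add(
        "n_content", f"n_fraction <= {max_n_fraction}", current, keep
    )

    non_missing = matrix.values.notna().sum(axis=1)
    keep = [g for g in current if non_missing[g] >= 2]
    current = report.add(
        "computable_average",
        ">= 5 qualifying CpGs in enough samples (>= 2 non-missing values)",
        current,
        keep,
    )

    variances = _row_variances(matrix.values)
    if current:
        n = len(current)
        k = math.ceil(bottom_variance_quantile * n) if bottom_variance_quantile > 0 else 0
        if k > 0:
            ordered = sorted(current, key=lambda g: (variances[g], g))
            boundary = variances[ordered[k - 1]]
            keep = [g for g in current if variances[g] > boundary]
        else:
            keep = list(current)
    else:
        keep = []
    current = report.add(
        "bottom_variance",
        f"variance above bottom {bottom_variance_quantile:.0%} (nearest rank, ties removed)",
        current,
        keep,
    )

    low, high = level_band
    means = matrix.values.mean(axis=1, skipna=True)
    keep = [g for g in current if low <= means[g] <= high]
    current = report.add("mean_level_band", f"{low} <= mean level <= {high}", current, keep)
    return current, report
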