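"""Coverage qualification and gene-level average methylation.

A CpG site qualifies only if it is covered at >= ``min_coverage`` reads in
*every* sample of the analysis set; a gene gets an average methylation value
in a sample only if it contains >= ``min_sites`` qualifying CpGs. Genes
failing the site rule are missing (NaN), which downstream filters treat as
"no computable average". The gene average is the unweighted arithmetic mean
of per-CpG ratios (all qualifying CpGs count equally, regardless of depth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["MethylationMatrix", "qualifying_cpg_sites", "gene_average_methylation", "build_matrix"]


@dataclass
class MethylationMatrix:
    """Gene x sample average methylation with missingness.

    ``values`` is indexed by gene id with one column per sample; entries are
    in [0, 1] or NaN. ``n_cpgs_used`` records, per gene, how many CpG sites
    qualified across the analysis set (0 for all-missing genes).
    """

    values: pd.DataFrame
    n_cpgs_used: pd.Series

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("methylation values must lie in [0, 1]")
        self.n_cpgs_used = self.n_cpgs_used.reindex(self.values.index).fillna(0).astype(int)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def restrict(self, gene_ids: Iterable[str]) -> "MethylationMatrix":
        """Matrix restricted to a gene set, preserving input matrix order."""
        keep = [g for g in self.values.index if g in set(gene_ids)]
        return MethylationMatrix(self.values.loc[keep], self.n_cpgs_used.loc[keep])

    def subset_samples(self, sample_ids: Iterable[str]) -> "MethylationMatrix":
        return MethylationMatrix(self.values[list(sample_ids)], self.n_cpgs_used)


def _coverage_ratio_frames(
    tables: Mapping[str, pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align per-sample site tables into site x sample coverage and ratio frames.

    Sites absent from a sample are treated as zero coverage there.
    """
    cov = {}
    ratio = {}
    for sample_id, df in tables.items():
        idx = pd.MultiIndex.from_arrays(
            [df["scaffold"].to_numpy(), df["position"].to_numpy()], names=["scaffold", "position"]
        )
        total = df["total_count"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(total > 0, df["meth_count"].to_numpy(dtype=float) / total, np.nan)
        cov[sample_id] = pd.Series(total, index=idx)
        ratio[sample_id] = pd.Series(r, index=idx)
    cov_df = pd.DataFrame(cov).fillna(0.0)
    ratio_df = pd.DataFrame(ratio).reindex(cov_df.index)
    return cov_df.sort_index(), ratio_df.sort_index()


def qualifying_cpg_sites(
    tables: Mapping[str, pd.DataFrame], min_coverage: int = 5
) -> set[tuple[str, int]]:
    """Sites covered at >= ``min_coverage`` in every sample of the analysis set.

    The qualifying set is the intersection across samples, so adding a sample
    can only shrink it.
    """
    if not tables:
        raise ValueError("qualifying_cpg_sites needs at least one sample")
    cov, _ = _coverage_ratio_frames(tables)
    mask = (cov >= min_coverage).all(axis=1)
    return set(cov.index[mask])


def gene_average_methylation(
    qualified_sites: pd.DataFrame, gene, min_sites: int = 5
) -> float:
    """Unweighted mean ratio over qualifying CpGs inside one gene, one sample.

    ``qualified_sites`` must already be restricted to the qualifying set for
    the analysis (columns ``scaffold``, ``position``, ``ratio``). Returns NaN
    when the gene holds fewer than ``min_sites`` qualifying CpGs — missing is
    a value here, not an error. Interval membership is 1-based inclusive and
    ignores gene strand.
    """
    in_gene = (
        (qualified_sites["scaffold"] == gene.scaffold)
        & (qualified_sites["position"] >= gene.start)
        & (qualified_sites["position"] <= gene.end)
    )
    ratios = qualified_sites.loc[in_gene, "ratio"].to_numpy(dtype=float)
    ratios = ratios[np.isfinite(ratios)]
    if ratios.size < min_sites:
        return float("nan")
    return float(ratios.mean())


def build_matrix(
    samples: Iterable[str] | pd.DataFrame,
    genes: pd.DataFrame,
    tables: Mapping[str, pd.DataFrame],
    min_coverage: int = 5,
    min_sites: int = 5,
) -> MethylationMatrix:
    """Aggregate per-CpG calls into a gene x sample methylation matrix.

    Parameters
    ----------
    samples
        The analysis set: sample ids (or a sample sheet with a ``sample_id``
        column). Coverage qualification is computed jointly over exactly
        these samples.
    genes
        Gene table as returned by :func:`methvar.io.read_gene_bed`.
    tables
        Mapping sample id -> per-CpG call table
        (:func:`methvar.io.read_methylation_table` output).
    """
    if isinstance(samples, pd.DataFrame):
        sample_ids = list(samples["sample_id"])
    else:
        sample_ids = list(samples)
    if not sample_ids:
        raise ValueError("empty analysis set")
    missing = [s for s in sample_ids if s not in tables]
    if missing:
        raise ValueError(f"no call table for sample(s): {', '.join(missing)}")
    if genes["gene_id"].duplicated().any():
        dup = genes.loc[genes["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene id {dup!r}")

    cov, ratio = _coverage_ratio_frames({s: tables[s] for s in sample_ids})
    qual = (cov >= min_coverage).all(axis=1).to_numpy()

    scaffolds = cov.index.get_level_values("scaffold").to_numpy()
    positions = cov.index.get_level_values("position").to_numpy()
    ratio_arr = ratio.to_numpy()  # sites x samples; defined wherever qualified

    # per-scaffold sorted position index for interval lookup
    by_scaffold: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for scf in np.unique(scaffolds):
        rows = np.flatnonzero(scaffolds == scf)
        order = np.argsort(positions[rows], kind="mergesort")
        by_scaffold[scf] = (positions[rows][order], rows[order])

    n_samples = len(sample_ids)
    out = np.full((len(genes), n_samples), np.nan)
    n_used = np.zeros(len(genes), dtype=int)
    for i, g in enumerate(genes.itertuples(index=False)):
        entry = by_scaffold.get(g.scaffold)
        if entry is None:
            continue
        pos_sorted, row_idx = entry
        lo = np.searchsorted(pos_sorted, g.start, side="left")
        hi = np.searchsorted(pos_sorted, g.end, side="right")
        rows = row_idx[lo:hi]
        rows = rows[qual[rows]]
        n_used[i] = rows.size
        if rows.size >= min_sites:
            out[i] = ratio_arr[rows].mean(axis=0)

    values = pd.DataFrame(out, index=pd.Index(genes["gene_id"], name="gene_id"), columns=sample_ids)
    return MethylationMatrix(values=values, n_cpgs_used=pd.Series(n_used, index=values.index))
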