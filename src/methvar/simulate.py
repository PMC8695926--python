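"""Synthetic per-CpG bisulfite methylation datasets with ground truth.

The generator emulates the data structure the analysis assumes: a few
hundred genes, each carrying a cluster of CpG sites on a synthetic
scaffold; per-gene baseline methylation drawn from a bimodal-plus-
intermediate beta mixture (most genes near 0 or 1, a variably methylated
minority in between); a minority of genes carrying *localized* tissue- or
location-specific effects — a logit-scale shift applied to a contiguous
window of CpGs for the affected sample group; negative-binomial sequencing
coverage; binomial methylated counts; and a small bisulfite non-conversion
error that inflates apparent methylation of unmethylated cytosines. A
configurable number of non-CpG (CHH) cytosines with true methylation zero
is included so conversion-rate QC can be exercised end to end.

Everything is driven by one seeded generator: identical parameters and seed
give byte-identical output. The ground truth (per-gene effect assignments
and per-CpG true ratios per group) is returned alongside the data so
recovery of planted effects can be scored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from os import PathLike
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import io as mio

__all__ = [
    "SimulationParams",
    "TruthTable",
    "SimulatedDataset",
    "logit_shift",
    "simulate_dataset",
    "recovery_scores",
]


def logit_shift(r: float, delta: float) -> float:
    """Shift a methylation ratio by ``delta`` on the logit scale.

    Returns ``expit(logit(r) + delta)``; strictly increasing in ``delta``
    and maps (0, 1) onto (0, 1). The endpoints are fixed points of the
    logit and therefore outside the domain.
    """
    r = np.asarray(r, dtype=float)
    if np.any((r <= 0) | (r >= 1)):
        raise ValueError("logit_shift requires 0 < r < 1")
    out = expit(logit(r) + delta)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic methylome.

    Defaults mirror the study conditions: two tissues sampled at four
    locations with 12 animals per tissue-location cell, a few hundred
    capture-target genes of ~30 CpGs, ~30X mean coverage with variance
    about twice the mean, 2% bisulfite non-conversion, and localized
    effects (10-CpG windows, logit shift 1.0) in a minority of genes.
    """

    n_genes: int = 360
    cpgs_per_gene_mean: float = 30.0
    baseline_weights: tuple[float, float, float] = (0.45, 0.20, 0.35)
    baseline_betas: tuple[tuple[float, float], ...] = ((0.5, 5.0), (2.0, 2.0), (5.0, 0.5))
    frac_tissue_genes: float = 0.10
    frac_location_genes: float = 0.10
    effect_delta: float = 1.0
    dmr_width: int = 10
    coverage_mean: float = 30.0
    coverage_dispersion: float = 30.0  # NB size; variance = mean + mean^2 / size
    non_conversion: float = 0.02
    samples_per_group: int = 12
    n_locations: int = 4
    tissues: tuple[str, ...] = ("hepatopancreas", "abdominal_muscle")
    locations: tuple[str, ...] | None = None  # default: Reilingen, Singlis, Andragnaroa, Ihosy...
    frac_high_n: float = 0.05
    hk_rate: float = 0.10
    hk_effect_enrichment: float = 2.0
    n_noncpg_sites: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.baseline_weights) - 1.0) > 1e-9:
            raise ValueError("baseline mixture weights must sum to 1")
        if len(self.baseline_betas) != len(self.baseline_weights):
            raise ValueError("one beta parameter pair per mixture component")
        if self.dmr_width < 1:
            raise ValueError("dmr_width must be >= 1")
        if self.samples_per_group < 1:
            raise ValueError("samples_per_group must be >= 1")
        if not 0.0 <= self.non_conversion < 1.0:
            raise ValueError("non_conversion must lie in [0, 1)")
        if self.frac_tissue_genes + self.frac_location_genes > 1.0:
            raise ValueError("effect fractions sum above 1")
        if self.n_genes < 1 or self.n_locations < 1 or not self.tissues:
            raise ValueError("n_genes, n_locations and tissues must be positive")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage parameters must be positive")

    def location_names(self) -> tuple[str, ...]:
        if self.locations is not None:
            if len(self.locations) != self.n_locations:
                raise ValueError("locations list length must equal n_locations")
            return tuple(self.locations)
        stock = ["Reilingen", "Singlis", "Andragnaroa", "Ihosy"]
        names = stock[: self.n_locations]
        names += [f"loc{i + 1}" for i in range(len(names), self.n_locations)]
        return tuple(names)


# baseline levels are clipped into this open interval so logit shifts stay defined
_LEVEL_EPS = 5e-3

#: the mixture component index treated as "intermediate"
_INTERMEDIATE = 1


@dataclass
class TruthTable:
    """Ground truth of a simulated dataset.

    ``genes`` has one row per gene: ``baseline_level``, ``effect_class``
    (none / tissue / location), ``affected_group``, ``shift`` (signed logit
    shift, 0 for null genes) and the CpG-index interval of the planted
    window (``dmr_start_idx``/``dmr_end_idx``, inclusive; -1 for none).
    ``true_ratios`` holds the per-CpG true methylation per tissue-location
    group cell (columns ``"<tissue>|<location>"``), indexed by
    (scaffold, position).
    """

    genes: pd.DataFrame
    true_ratios: pd.DataFrame

    def effect_genes(self, effect_class: str) -> set[str]:
        sel = self.genes["effect_class"] == effect_class
        return set(self.genes.loc[sel, "gene_id"])

    def write(self, outdir: str | PathLike) -> None:
        outdir = Path(outdir)
        self.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        self.true_ratios.to_csv(outdir / "truth_ratios.tsv", sep="\t")


@dataclass
class SimulatedDataset:
    """In-memory simulated dataset plus ground truth.

    ``sites`` describes every simulated cytosine (CpG sites carry their
    gene id; non-CpG QC sites have an empty gene id); ``meth`` and ``cov``
    are sites x samples count arrays aligned to ``sites`` rows and
    ``samples`` rows.
    """

    params: SimulationParams
    sites: pd.DataFrame
    genes: pd.DataFrame
    samples: pd.DataFrame
    meth: np.ndarray
    cov: np.ndarray
    truth: TruthTable

    def site_table(self, sample_id: str) -> pd.DataFrame:
        """Methratio-style call table for one sample (CpG + non-CpG rows)."""
        j = list(self.samples["sample_id"]).index(sample_id)
        df = self.sites[["scaffold", "position", "strand", "context"]].copy()
        df["meth_count"] = self.meth[:, j]
        df["total_count"] = self.cov[:, j]
        total = df["total_count"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            df["ratio"] = np.where(total > 0, df["meth_count"].to_numpy() / total, np.nan)
        return df

    def site_tables(self, context: str | None = "CpG") -> dict[str, pd.DataFrame]:
        """Per-sample call tables, optionally restricted to one context."""
        out = {}
        for sid in self.samples["sample_id"]:
            df = self.site_table(sid)
            if context is not None:
                df = df[df["context"] == context].reset_index(drop=True)
            out[sid] = df
        return out

    def write(self, outdir: str | PathLike) -> dict[str, Path]:
        """Write the dataset in the formats the readers expect.

        Per-sample call TSVs, gene BED, sample sheet (with ``path`` column)
        and the truth tables. Returns the artifact paths.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        samples = self.samples.copy()
        paths = []
        for sid in samples["sample_id"]:
            p = outdir / f"{sid}.methratio.tsv"
            self.site_table(sid).drop(columns="ratio").to_csv(p, sep="\t", index=False)
            paths.append(str(p))
        samples["path"] = paths
        sheet = outdir / "samples.tsv"
        samples.to_csv(sheet, sep="\t", index=False)
        bed = outdir / "genes.bed"
        mio.write_gene_bed(self.genes, bed)
        self.truth.write(outdir)
        return {"sample_sheet": sheet, "gene_bed": bed, "outdir": outdir}


def simulate_dataset(params: SimulationParams | None = None, **overrides) -> SimulatedDataset:
    """Draw a complete synthetic dataset under ``params``.

    Deterministic given ``params.seed``. See the module docstring for the
    generative model. Keyword overrides are applied on top of ``params``
    (or the defaults) for convenience.
    """
    if params is None:
        params = SimulationParams(**overrides)
    elif overrides:
        params = dataclasses.replace(params, **overrides)
    rng = np.random.default_rng(params.seed)
    locations = params.location_names()
    tissues = params.tissues
    groups = [f"{t}|{l}" for t in tissues for l in locations]

    # -- gene structure ----------------------------------------------------
    n = params.n_genes
    n_cpgs = np.maximum(5, rng.poisson(params.cpgs_per_gene_mean, size=n))
    gene_ids = np.array([f"g{i + 1:05d}" for i in range(n)])
    scaffold = "scf1"
    positions_per_gene: list[np.ndarray] = []
    starts = np.empty(n, dtype=int)
    ends = np.empty(n, dtype=int)
    cursor = 1000
    for i in range(n):
        spacings = rng.integers(10, 60, size=n_cpgs[i])
        pos = cursor + np.cumsum(spacings)
        positions_per_gene.append(pos)
        starts[i] = pos[0] - 50
        ends[i] = pos[-1] + 50
        cursor = ends[i] + 500

    # -- baseline mixture and effect assignment ----------------------------
    component = rng.choice(len(params.baseline_weights), size=n, p=params.baseline_weights)
    baseline = np.empty(n)
    for ci, (a, b) in enumerate(params.baseline_betas):
        mask = component == ci
        baseline[mask] = rng.beta(a, b, size=int(mask.sum()))
    baseline = np.clip(baseline, _LEVEL_EPS, 1 - _LEVEL_EPS)

    n_tissue = int(round(params.frac_tissue_genes * n))
    n_location = int(round(params.frac_location_genes * n))
    # effects are planted in intermediate-level genes: the study's signatures
    # live inside the variably methylated (intermediate) fraction; a shift on
    # a ~0/~1 gene would be removed by the level-band filter before testing
    intermediate = np.flatnonzero(component == _INTERMEDIATE)
    others = np.flatnonzero(component != _INTERMEDIATE)
    pool = np.concatenate([rng.permutation(intermediate), rng.permutation(others)])
    effect_idx = pool[: n_tissue + n_location]
    tissue_idx = np.sort(effect_idx[:n_tissue])
    location_idx = np.sort(effect_idx[n_tissue:])

    effect_class = np.array(["none"] * n, dtype=object)
    effect_class[tissue_idx] = "tissue"
    effect_class[location_idx] = "location"
    affected_group = np.array([""] * n, dtype=object)
    shift = np.zeros(n)
    dmr_lo = np.full(n, -1)
    dmr_hi = np.full(n, -1)
    affected_group[tissue_idx] = tissues[0]
    affected_group[location_idx] = rng.choice(locations, size=location_idx.size)
    signs = rng.choice([-1.0, 1.0], size=effect_idx.size)
    shift[tissue_idx] = signs[:n_tissue] * params.effect_delta
    shift[location_idx] = signs[n_tissue:] * params.effect_delta
    for i in np.concatenate([tissue_idx, location_idx]):
        width = min(params.dmr_width, n_cpgs[i])
        lo = int(rng.integers(0, n_cpgs[i] - width + 1))
        dmr_lo[i], dmr_hi[i] = lo, lo + width - 1

    # -- annotation flags ---------------------------------------------------
    n_fraction = rng.uniform(0.0, 0.10, size=n)
    high_n = rng.random(n) < params.frac_high_n
    n_fraction[high_n] = rng.uniform(0.55, 0.95, size=int(high_n.sum()))
    hk_prob = np.full(n, params.hk_rate)
    hk_prob[effect_class != "none"] = min(1.0, params.hk_rate * params.hk_effect_enrichment)
    is_hk = rng.random(n) < hk_prob
    te_overlap = rng.random(n) < 0.10
    gene_strand = rng.choice(["+", "-"], size=n)

    # -- per-CpG true ratios per group --------------------------------------
    all_pos = np.concatenate(positions_per_gene)
    site_gene = np.repeat(np.arange(n), n_cpgs)
    n_sites = all_pos.size
    true_by_group = np.tile(baseline[site_gene][:, None], (1, len(groups)))
    offsets = np.concatenate([[0], np.cumsum(n_cpgs)])
    group_tissue = np.array([g.split("|")[0] for g in groups])
    group_location = np.array([g.split("|")[1] for g in groups])
    for i in np.concatenate([tissue_idx, location_idx]):
        rows = np.arange(offsets[i] + dmr_lo[i], offsets[i] + dmr_hi[i] + 1)
        if effect_class[i] == "tissue":
            cols = np.flatnonzero(group_tissue == affected_group[i])
        else:
            cols = np.flatnonzero(group_location == affected_group[i])
        shifted = logit_shift(baseline[i], shift[i])
        true_by_group[np.ix_(rows, cols)] = shifted

    # -- samples -------------------------------------------------------------
    sample_rows = []
    for t in tissues:
        for l in locations:
            for r in range(params.samples_per_group):
                sample_rows.append(
                    {
                        "sample_id": f"{t[:3]}_{l}_{r + 1:02d}",
                        "tissue": t,
                        "location": l,
                        "condition": "wild",
                        "dataset": "capture",
                    }
                )
    samples = pd.DataFrame(sample_rows)
    sample_group_col = np.array(
        [groups.index(f"{t}|{l}") for t, l in zip(samples["tissue"], samples["location"])]
    )
    n_samples = len(samples)

    # -- observed counts -----------------------------------------------------
    r_true = true_by_group[:, sample_group_col]  # sites x samples
    eps = params.non_conversion
    p_obs = r_true + (1.0 - r_true) * eps
    size = params.coverage_dispersion
    nb_p = size / (size + params.coverage_mean)
    cov = rng.negative_binomial(size, nb_p, size=(n_sites, n_samples))
    meth = rng.binomial(cov, p_obs)

    # -- non-CpG QC sites (true methylation zero) ----------------------------
    m = params.n_noncpg_sites
    if m > 0:
        chh_pos = np.arange(1, m + 1) * 7 + 3  # arbitrary fixed layout on its own scaffold
        chh_cov = rng.negative_binomial(size, nb_p, size=(m, n_samples))
        chh_meth = rng.binomial(chh_cov, eps)
    else:
        chh_pos = np.empty(0, dtype=int)
        chh_cov = np.empty((0, n_samples), dtype=int)
        chh_meth = np.empty((0, n_samples), dtype=int)

    sites = pd.DataFrame(
        {
            "scaffold": np.concatenate([np.full(n_sites, scaffold), np.full(m, "scf_chh")]),
            "position": np.concatenate([all_pos, chh_pos]),
            "strand": "+",
            "context": np.concatenate([np.full(n_sites, "CpG"), np.full(m, "CHH")]),
            "gene_id": np.concatenate([gene_ids[site_gene], np.full(m, "")]),
        }
    )
    meth = np.vstack([meth, chh_meth])
    cov = np.vstack([cov, chh_cov])

    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "scaffold": scaffold,
            "start": starts,
            "end": ends,
            "strand": gene_strand,
            "n_fraction": np.round(n_fraction, 6),
            "is_housekeeping": is_hk,
            "te_overlap": te_overlap,
        }
    )
    truth_genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "baseline_level": baseline,
            "baseline_component": component,
            "effect_class": effect_class,
            "affected_group": affected_group,
            "shift": shift,
            "dmr_start_idx": dmr_lo,
            "dmr_end_idx": dmr_hi,
        }
    )
    true_ratios = pd.DataFrame(
        true_by_group,
        index=pd.MultiIndex.from_arrays(
            [np.full(n_sites, scaffold), all_pos], names=["scaffold", "position"]
        ),
        columns=groups,
    )
    return SimulatedDataset(
        params=params,
        sites=sites,
        genes=genes,
        samples=samples,
        meth=meth,
        cov=cov,
        truth=TruthTable(genes=truth_genes, true_ratios=true_ratios),
    )


def recovery_scores(
    called_genes: Iterable[str], truth: TruthTable, effect_class: str
) -> tuple[float, float]:
    """Precision and recall of a called gene set against the planted truth.

    Precision is 1.0 by convention when nothing is called; recall is 1.0
    (vacuously) when no gene carries the queried effect class.
    """
    called = set(called_genes)
    known = set(truth.genes["gene_id"])
    unknown = called - known
    if unknown:
        raise ValueError(f"called gene(s) absent from truth: {sorted(unknown)[:5]}")
    true_set = truth.effect_genes(effect_class)
    hits = len(called & true_set)
    precision = hits / len(called) if called else 1.0
    recall = hits / len(true_set) if true_set else 1.0
    return precision, recall
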