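"""Rank-based differential methylation, FDR correction and DMR scanning.

The gene-level tests are the nonparametric pair the study design calls for:
a two-sample Wilcoxon rank-sum test for the tissue contrast (hepatopancreas
vs. abdominal muscle) and a Kruskal-Wallis test for the multi-group location
contrast, both followed by Benjamini-Hochberg correction across the genes
actually tested. The rank statistics are implemented here from first
principles — exact Wilcoxon p-values by enumeration of the rank-sum
distribution for small tie-free samples, tie-corrected normal / chi-square
approximations otherwise — so their behaviour is fully specified and
verifiable against brute-force enumeration.

Region-level signal is summarized by a deliberately simple run-based DMR
scanner over per-CpG group-mean tracks: maximal runs of CpGs whose largest
between-group difference clears a threshold, tolerating short sub-threshold
gaps. It is a transparent stand-in for smoothing-based DMR callers and is
not expected to reproduce their output.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2
from scipy.stats import norm as _norm
from scipy.stats import rankdata

from .aggregate import MethylationMatrix, _coverage_ratio_frames

__all__ = [
    "RankTestResult",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "benjamini_hochberg",
    "differential_genes",
    "overlap_genes",
    "per_cpg_profile",
    "DmrRegion",
    "scan_dmrs",
    "ConcordanceResult",
    "amplicon_concordance",
]


class RankTestResult(NamedTuple):
    statistic: float
    p_value: float
    method: str
    degenerate: bool = False


def _clean(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return v[np.isfinite(v)]


@lru_cache(maxsize=256)
def _rank_sum_counts(n_x: int, n_total: int) -> np.ndarray:
    """counts[w] = number of size-``n_x`` subsets of ranks 1..n_total summing to w.

    Classic subset-sum dynamic programme; for tie-free data the null
    distribution of the rank sum depends only on (n_x, n_total).
    """
    max_w = n_x * n_total
    f = np.zeros((n_x + 1, max_w + 1), dtype=np.float64)
    f[0, 0] = 1.0
    for r in range(1, n_total + 1):
        for j in range(min(r, n_x), 0, -1):
            f[j, r:] += f[j - 1, :-r]
    return f[n_x]


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    exact_limit: int = 20,
    continuity: bool = True,
) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum test.

    The statistic is the rank sum W of the first group, with midranks for
    ties. The p-value is exact (two-sided as twice the smaller tail of the
    enumerated null distribution, capped at 1) when the pooled data are
    tie-free and ``n_x + n_y <= exact_limit``; otherwise a normal
    approximation with tie-corrected variance and, by default, a continuity
    correction is used.
    """
    x, y = _clean(x), _clean(y)
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_rank_sum: both groups must be nonempty")
    n_x, n_y = x.size, y.size
    n = n_x + n_y
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[:n_x].sum())
    mu = n_x * (n + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if not has_ties and n <= exact_limit:
        counts = _rank_sum_counts(n_x, n)
        total = counts.sum()
        wi = int(round(w))
        lower = counts[: wi + 1].sum() / total
        upper = counts[wi:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        return RankTestResult(w, p, "exact")

    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var = n_x * n_y / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all pooled values identical
        return RankTestResult(w, 1.0, "normal", degenerate=True)
    diff = w - mu
    if continuity:
        diff -= 0.5 * np.sign(diff)
    z = diff / np.sqrt(var)
    p = min(1.0, 2.0 * float(_norm.sf(abs(z))))
    return RankTestResult(w, p, "normal")


def kruskal_wallis(groups: Iterable[Sequence[float]]) -> RankTestResult:
    """Kruskal-Wallis H test with midranks and tie correction.

    The p-value comes from the chi-square approximation with k-1 degrees of
    freedom. When every pooled value is identical the tie-correction
    denominator vanishes; the test then returns H = 0, p = 1 flagged as
    degenerate rather than dividing by zero.
    """
    cleaned = [_clean(g) for g in groups]
    cleaned = [g for g in cleaned if g.size > 0]
    k = len(cleaned)
    if k < 2:
        raise ValueError("kruskal_wallis: needs >= 2 nonempty groups")
    n = sum(g.size for g in cleaned)
    if n < 3:
        raise ValueError("kruskal_wallis: needs >= 3 observations in total")
    pooled = np.concatenate(cleaned)
    ranks = rankdata(pooled)
    h = 0.0
    offset = 0
    for g in cleaned:
        r = ranks[offset : offset + g.size]
        h += g.size * (r.mean() - (n + 1) / 2.0) ** 2
        offset += g.size
    h *= 12.0 / (n * (n + 1))

    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float((tie_counts**3 - tie_counts).sum()) / (n**3 - n)
    if correction <= 0:  # all values identical
        return RankTestResult(0.0, 1.0, "chi2", degenerate=True)
    h /= correction
    p = float(_chi2.sf(h, k - 1))
    return RankTestResult(float(h), p, "chi2")


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    With the p-values sorted ascending as p_(1) <= ... <= p_(m),
    q_(i) = min_{j >= i} ( p_(j) * m / j ), clamped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("benjamini_hochberg expects a 1-d collection")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def differential_genes(
    matrix: MethylationMatrix,
    labels: Mapping[str, str] | pd.Series,
    test: str = "kruskal_wallis",
    alpha: float = 0.05,
    min_per_group: int = 2,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene rank test across sample groups with BH correction.

    Parameters
    ----------
    matrix
        Gene x sample methylation matrix (the analysis stratum: e.g. the
        hepatopancreas samples for a location contrast).
    labels
        Sample id -> group name for every matrix column.
    test
        ``"wilcoxon"`` (exactly two groups) or ``"kruskal_wallis"``.
    alpha
        Significance level applied to q-values.
    min_per_group
        Genes where any group drops below this many non-missing values are
        skipped and reported in the second return value; BH is applied across
        the genes actually tested.

    Returns
    -------
    (results, skipped): a DataFrame with one row per tested gene — columns
    ``gene_id, test, statistic, p_value, q_value, significant, alpha`` plus
    one ``mean_<group>`` column per group — and the list of skipped gene ids.
    """
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    unlabeled = [s for s in matrix.sample_ids if s not in labels.index]
    if unlabeled:
        raise ValueError(f"unlabeled sample(s): {', '.join(unlabeled[:5])}")
    groups = sorted(labels.loc[matrix.sample_ids].unique())
    if len(groups) < 2:
        raise ValueError("differential_genes needs >= 2 groups")
    if test == "wilcoxon" and len(groups) != 2:
        raise ValueError("wilcoxon requires exactly 2 groups")
    if test not in ("wilcoxon", "kruskal_wallis"):
        raise ValueError(f"unknown test {test!r}")

    cols_by_group = {
        g: [s for s in matrix.sample_ids if labels[s] == g] for g in groups
    }
    rows = []
    skipped: list[str] = []
    for gene_id, row in matrix.values.iterrows():
        per_group = [_clean(row[cols_by_group[g]]) for g in groups]
        if any(v.size < min_per_group for v in per_group):
            skipped.append(gene_id)
            continue
        if test == "wilcoxon":
            res = wilcoxon_rank_sum(per_group[0], per_group[1])
        else:
            res = kruskal_wallis(per_group)
        entry = {
            "gene_id": gene_id,
            "test": test,
            "statistic": res.statistic,
            "p_value": res.p_value,
        }
        for g, v in zip(groups, per_group):
            entry[f"mean_{g}"] = float(v.mean())
        rows.append(entry)

    results = pd.DataFrame(rows)
    if not results.empty:
        results["q_value"] = benjamini_hochberg(results["p_value"].to_numpy())
        # strict threshold; alpha = 1 disables filtering (q is capped at 1)
        results["significant"] = (
            results["q_value"] < alpha if alpha < 1 else np.ones(len(results), dtype=bool)
        )
        results["alpha"] = alpha
    return results, skipped


def overlap_genes(set_a: Iterable[str], set_b: Iterable[str]) -> tuple[set[str], int, int]:
    """Intersection of two gene sets plus the sizes of the exclusive parts."""
    a, b = set(set_a), set(set_b)
    inter = a & b
    return inter, len(a - b), len(b - a)


def per_cpg_profile(
    gene,
    tables: Mapping[str, pd.DataFrame],
    labels: Mapping[str, str] | pd.Series,
    min_coverage: int = 5,
) -> pd.DataFrame:
    """Per-CpG, per-group mean methylation track inside one gene.

    Sites qualify if covered at >= ``min_coverage`` in every sample of the
    analysis set. Returns a DataFrame indexed by CpG position (ascending)
    with one column per group.
    """
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    cov, ratio = _coverage_ratio_frames(tables)
    qual = (cov >= min_coverage).all(axis=1)
    scf = ratio.index.get_level_values("scaffold")
    pos = ratio.index.get_level_values("position")
    in_gene = qual & (scf == gene.scaffold) & (pos >= gene.start) & (pos <= gene.end)
    sub = ratio[in_gene.to_numpy()]
    if sub.empty:
        raise ValueError(f"gene {gene.gene_id}: no qualifying CpG sites")
    sub.index = sub.index.get_level_values("position")
    out = {}
    for g in sorted(labels.loc[list(tables)].unique()):
        cols = [s for s in sub.columns if labels[s] == g]
        out[g] = sub[cols].mean(axis=1)
    return pd.DataFrame(out).sort_index()


@dataclass(frozen=True)
class DmrRegion:
    """A run of contiguous CpGs with a consistent between-group difference."""

    scaffold: str
    start: int  # 1-based inclusive
    end: int
    n_cpgs: int  # above-threshold CpGs in the run
    mean_abs_difference: float
    groups: tuple[str, ...]


def scan_dmrs(
    tracks: pd.DataFrame,
    scaffold: str = "",
    min_sites: int = 5,
    min_delta: float = 0.1,
    max_gap: int = 2,
) -> list[DmrRegion]:
    """Run-based scan for differentially methylated regions.

    ``tracks`` holds per-CpG group-mean methylation (index: position,
    ascending; one column per group), as produced by :func:`per_cpg_profile`.
    A CpG is *above threshold* when the largest pairwise difference between
    group means at that CpG is >= ``min_delta``. Maximal runs of
    above-threshold CpGs are reported, tolerating gaps of at most
    ``max_gap`` consecutive below-threshold CpGs inside a run; runs with
    fewer than ``min_sites`` above-threshold CpGs are discarded. Region
    coordinates span the first to last above-threshold CpG. Deterministic;
    reported regions never overlap.
    """
    if isinstance(tracks, Mapping):
        series = list(tracks.values())
        if any(not s.index.equals(series[0].index) for s in series[1:]):
            raise ValueError("scan_dmrs: tracks are not aligned on the same CpG positions")
        tracks = pd.DataFrame(dict(tracks))
    if tracks.shape[1] < 2:
        raise ValueError("scan_dmrs: needs tracks for >= 2 groups")
    if tracks.isna().any().any():
        raise ValueError("scan_dmrs: tracks contain missing values — not aligned")
    positions = tracks.index.to_numpy()
    values = tracks.to_numpy(dtype=float)
    # max pairwise group difference == max - min across groups
    delta = values.max(axis=1) - values.min(axis=1)
    above = np.flatnonzero(delta >= min_delta)
    groups = tuple(tracks.columns)

    regions: list[DmrRegion] = []
    if above.size == 0:
        return regions
    run: list[int] = [above[0]]
    for idx in above[1:]:
        if idx - run[-1] - 1 <= max_gap:
            run.append(idx)
        else:
            regions.extend(_emit_run(run, positions, delta, scaffold, groups, min_sites))
            run = [idx]
    regions.extend(_emit_run(run, positions, delta, scaffold, groups, min_sites))
    return regions


def _emit_run(run, positions, delta, scaffold, groups, min_sites):
    if len(run) < min_sites:
        return []
    idx = np.asarray(run)
    return [
        DmrRegion(
            scaffold=scaffold,
            start=int(positions[idx[0]]),
            end=int(positions[idx[-1]]),
            n_cpgs=len(run),
            mean_abs_difference=float(delta[idx].mean()),
            groups=groups,
        )
    ]


def dmrs_to_bed(regions: Sequence[DmrRegion], path) -> None:
    """Write DMRs as BED (0-based half-open on disk)."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            fh.write(
                f"{r.scaffold}\t{r.start - 1}\t{r.end}\tdmr_{i + 1}"
                f"\t{r.mean_abs_difference:.4f}\t.\t{r.n_cpgs}\n"
            )


class ConcordanceResult(NamedTuple):
    pearson_r: float
    mean_abs_diff: float
    n_shared_cpgs: int


def amplicon_concordance(capture: pd.Series, amplicon: pd.Series) -> ConcordanceResult:
    """Agreement between capture-based and amplicon-based per-CpG ratios.

    Both inputs are position-indexed methylation tracks; statistics are
    computed over position-matched CpGs only.
    """
    shared = capture.index.intersection(amplicon.index)
    if len(shared) < 3:
        raise ValueError(f"amplicon_concordance: only {len(shared)} shared CpGs (< 3)")
    a = capture.loc[shared].to_numpy(dtype=float)
    b = amplicon.loc[shared].to_numpy(dtype=float)
    mad = float(np.abs(a - b).mean())
    if a.std() == 0 or b.std() == 0:
        r = float("nan")  # correlation undefined for a constant track
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    return ConcordanceResult(r, mad, len(shared))
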