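"""Config-driven orchestration of the full analysis.

``run_pipeline`` wires the stages together: read inputs -> aggregate per-CpG
calls into a gene x sample matrix -> variable-gene discovery and core-set
filtering -> stratified differential methylation (tissue contrast within one
location, location contrast within one tissue) -> ordination and separation
scoring. Every artifact is a TSV/JSON file in the output directory and a run
manifest records the package version, the echoed configuration, its hash and
the seed, so identical config + inputs give identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as mio
from .aggregate import build_matrix
from .diffmeth import differential_genes
from .select import FilterReport, core_set_filter, discover_variable_genes
from .signatures import pca_embed, separation_score

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "read_config"]


@dataclass
class PipelineConfig:
    """All paths and thresholds of one analysis run."""

    sample_sheet: str = ""
    gene_bed: str = ""
    outdir: str = "methvar_out"
    min_coverage: int = 5
    min_sites: int = 5
    var_cutoff: float = 0.006
    band_low: float = 0.2
    band_high: float = 0.8
    level_low: float = 0.1
    level_high: float = 0.9
    max_n_fraction: float = 0.5
    bottom_variance_quantile: float = 0.10
    alpha: float = 0.05
    # WGBS-style variance discovery is off by default: a capture dataset is
    # already restricted to pre-selected variable genes, and its cross-sample
    # variance sits on a different scale than whole-genome data
    run_discovery: bool = False
    # contrast strata; empty string = pick automatically / skip if impossible
    tissue_contrast_location: str = ""
    location_contrast_tissue: str = ""
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.band_low < self.band_high <= 1):
            raise ValueError("band thresholds must satisfy 0 <= low < high <= 1")
        if not (0 <= self.level_low < self.level_high <= 1):
            raise ValueError("level band thresholds must satisfy 0 <= low < high <= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.min_coverage < 1 or self.min_sites < 1:
            raise ValueError("min_coverage and min_sites must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def read_config(path) -> PipelineConfig:
    """Parse a flat ``key = value`` config file into a :class:`PipelineConfig`."""
    fields = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}
    values: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected 'key = value'")
            key, _, val = (t.strip() for t in line.partition("="))
            if key not in fields:
                raise ValueError(f"{path}: line {lineno}: unknown config key {key!r}")
            values[key] = val
    cfg = PipelineConfig()
    for key, val in values.items():
        current = getattr(cfg, key)
        if isinstance(current, bool):
            parsed = val.lower() in ("1", "true", "yes")
        elif isinstance(current, int):
            parsed = int(val)
        elif isinstance(current, float):
            parsed = float(val)
        else:
            parsed = val
        setattr(cfg, key, parsed)
    cfg.validate()
    return cfg


def _pick_tissue_stratum(samples: pd.DataFrame, config: PipelineConfig) -> str | None:
    """Location used for the tissue contrast: configured, else largest with both tissues."""
    if config.tissue_contrast_location:
        return config.tissue_contrast_location
    counts = samples.groupby("location")["tissue"].agg(["nunique", "count"])
    eligible = counts[counts["nunique"] >= 2].sort_values("count", ascending=False)
    return None if eligible.empty else str(eligible.index[0])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis described by ``config``.

    Returns a manifest dict (also written to ``<outdir>/manifest.json``)
    listing artifacts and headline numbers. Raises with a stage-tagged
    message on failure.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("methvar")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    artifacts: dict[str, str] = {}
    summary: dict = {}
    try:
        # -- inputs -------------------------------------------------------
        stage = "inputs"
        samples = mio.read_sample_sheet(config.sample_sheet)
        if "path" not in samples.columns:
            raise ValueError("sample sheet needs a 'path' column with call-table paths")
        genes = mio.read_gene_bed(config.gene_bed)
        tables = {
            row.sample_id: mio.read_methylation_table(row.path)
            for row in samples.itertuples(index=False)
        }
        logger.info("read %d samples, %d genes", len(samples), len(genes))

        # conversion-rate QC from non-CpG cytosines where available
        qc_rows = []
        for row in samples.itertuples(index=False):
            full = mio.read_methylation_table(row.path, context=None)
            try:
                rate = mio.compute_conversion_rate(full)
            except ValueError:
                rate = float("nan")
            qc_rows.append({"sample_id": row.sample_id, "conversion_rate": rate})
        qc = pd.DataFrame(qc_rows)
        qc.to_csv(outdir / "conversion_rates.tsv", sep="\t", index=False)
        artifacts["conversion_rates"] = str(outdir / "conversion_rates.tsv")

        # -- aggregation ---------------------------------------------------
        stage = "aggregate"
        matrix = build_matrix(
            samples, genes, tables, config.min_coverage, config.min_sites
        )
        mio.write_methylation_matrix(matrix, outdir / "methylation_matrix.tsv")
        artifacts["matrix"] = str(outdir / "methylation_matrix.tsv")

        # -- selection cascade --------------------------------------------
        stage = "select"
        if config.run_discovery:
            variable, consistent, disc_report = discover_variable_genes(
                matrix, config.var_cutoff, (config.band_low, config.band_high)
            )
            disc_stages = list(disc_report.stages)
        else:
            variable, disc_stages = list(matrix.values.index), []
        core, core_report = core_set_filter(
            matrix.restrict(variable),
            genes,
            config.max_n_fraction,
            config.bottom_variance_quantile,
            (config.level_low, config.level_high),
        )
        full_report = FilterReport(stages=disc_stages + list(core_report.stages))
        full_report.write_tsv(outdir / "filter_report.tsv")
        (outdir / "core_genes.txt").write_text("\n".join(core) + "\n")
        artifacts["filter_report"] = str(outdir / "filter_report.tsv")
        artifacts["core_genes"] = str(outdir / "core_genes.txt")
        summary["n_variable_genes"] = len(variable)
        summary["n_core_genes"] = len(core)
        logger.info("cascade:\n%s", full_report)

        core_matrix = matrix.restrict(core)

        # -- tissue contrast (within one location) -------------------------
        stage = "diff_tissue"
        stratum = _pick_tissue_stratum(samples, config)
        if stratum is not None:
            sub = samples[samples["location"] == stratum]
            if sub["tissue"].nunique() == 2:
                labels = sub.set_index("sample_id")["tissue"]
                contrast_matrix = build_matrix(
                    sub, genes, tables, config.min_coverage, config.min_sites
                ).restrict(core)
                res, skipped = differential_genes(
                    contrast_matrix, labels, test="wilcoxon", alpha=config.alpha
                )
                res.to_csv(outdir / "tissue_differential.tsv", sep="\t", index=False)
                artifacts["tissue_differential"] = str(outdir / "tissue_differential.tsv")
                sig = list(res.loc[res["significant"], "gene_id"]) if not res.empty else []
                summary["tissue_contrast_location"] = stratum
                summary["n_tissue_significant"] = len(sig)
                summary["n_tissue_skipped"] = len(skipped)
                if len(sig) >= 2:
                    emb = pca_embed(contrast_matrix, gene_set=sig, k=2)
                    emb.to_frame(labels).to_csv(outdir / "tissue_pca.tsv", sep="\t")
                    artifacts["tissue_pca"] = str(outdir / "tissue_pca.tsv")
                    summary["tissue_separation_score"] = separation_score(emb, labels)

        # -- location contrast (within one tissue) --------------------------
        stage = "diff_location"
        tissue = config.location_contrast_tissue or samples["tissue"].value_counts().idxmax()
        sub = samples[samples["tissue"] == tissue]
        if sub["location"].nunique() >= 2:
            labels = sub.set_index("sample_id")["location"]
            contrast_matrix = build_matrix(
                sub, genes, tables, config.min_coverage, config.min_sites
            ).restrict(core)
            res, skipped = differential_genes(
                contrast_matrix, labels, test="kruskal_wallis", alpha=config.alpha
            )
            res.to_csv(outdir / "location_differential.tsv", sep="\t", index=False)
            artifacts["location_differential"] = str(outdir / "location_differential.tsv")
            sig = list(res.loc[res["significant"], "gene_id"]) if not res.empty else []
            summary["location_contrast_tissue"] = tissue
            summary["n_location_significant"] = len(sig)
            summary["n_location_skipped"] = len(skipped)
            if len(sig) >= 2:
                emb = pca_embed(contrast_matrix, gene_set=sig, k=2)
                emb.to_frame(labels).to_csv(outdir / "location_pca.tsv", sep="\t")
                artifacts["location_pca"] = str(outdir / "location_pca.tsv")
                summary["location_separation_score"] = separation_score(emb, labels)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()

    manifest = {
        "tool": "methvar",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "artifacts": artifacts,
        "summary": summary,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
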