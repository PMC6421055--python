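"""End-to-end pipeline: simulate/ingest → validate → normalize → DE →
delta-score → enrichment → qPCR/phenotype, with a plain-text run manifest.

A single global seed is fanned out to per-stage child seeds by fixed offsets
so that each stage is independently reproducible from the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .io_design import (
    read_counts, read_design, read_go_map, read_ct_table, read_phenotype_table,
    write_counts, write_design, write_go_map, write_table, ValidationError,
)
from .model import AluminumResponseModel
from .normalize import compute_cpm
from .qpcr import phenotype_decline
from .simulate import (
    SimulationConfig, simulate_counts, simulate_ct_table, simulate_go_map, write_truth,
)

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets (stage-level reproducibility from one seed)
SEED_OFFSETS = {"counts": 0, "go_map": 101, "ct": 202}


@dataclass
class PipelineConfig:
    """Paths and tunables of a full run."""

    outdir: str = "altox_out"
    counts: str | None = None           # input counts TSV; simulated when None
    design: str | None = None
    go_map: str | None = None
    ct_table: str | None = None
    phenotype: str | None = None
    simulate: bool = True
    n_genes: int = 2000
    seed: int = 42
    cpm_threshold: float = 1.5
    min_samples: int | None = None
    pseudo: float = 0.5
    top_sizes: tuple[int, ...] = (50, 100, 300)
    alpha: float = 0.05
    enrich_method: str = "hypergeom"
    n_qpcr_genes: int = 7
    ct_noise_sd: float = 0.3

    def validate(self) -> None:
        for name in ("cpm_threshold", "pseudo", "alpha"):
            if getattr(self, name) is not None and getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not self.simulate and (self.counts is None or self.design is None):
            raise ValidationError("need counts and design paths unless simulating")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "stages": {},
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True, default=str).encode()
    ).hexdigest()[:16]

    stage = "ingest"
    try:
        truth = None
        if config.simulate and config.counts is None:
            sim_cfg = SimulationConfig(
                n_genes=config.n_genes, seed=config.seed + SEED_OFFSETS["counts"]
            )
            cm, design, truth = simulate_counts(sim_cfg)
            write_counts(cm, out / "counts.tsv")
            write_design(design, out / "design.tsv")
            write_truth(truth, out / "truth.tsv")
        else:
            cm = read_counts(config.counts)
            design = read_design(config.design)
        design.validate_against(cm)
        manifest["stages"]["ingest"] = {"n_genes": cm.n_genes, "n_samples": cm.n_samples}

        stage = "fit"
        model = AluminumResponseModel(
            cm, design, cpm_threshold=config.cpm_threshold,
            min_samples=config.min_samples, pseudo=config.pseudo,
        )
        results = model.fit()
        manifest["stages"]["filter"] = {"n_genes": results.n_genes_tested}
        write_table(
            pd.DataFrame({
                "sample_id": results.normalization.factors.index,
                "tmm_factor": results.normalization.factors.to_numpy(),
            }),
            out / "factors.tsv",
        )
        cpm = compute_cpm(results.filtered_counts, results.normalization, effective=True)
        cpm.index.name = "gene_id"
        cpm.round(4).to_csv(out / "cpm.tsv", sep="\t")

        stage = "de"
        for name, table in results.de_tables.items():
            write_table(table, out / f"de_{name}.tsv")
        manifest["stages"]["de"] = {
            name: {"n_genes": len(t), "n_sig_fdr05": int((t["fdr"] < 0.05).sum())}
            for name, t in results.de_tables.items()
        }

        stage = "delta"
        write_table(results.delta_table, out / "delta_scores.tsv")
        manifest["stages"]["delta"] = {"n_genes": len(results.delta_table)}

        stage = "enrich"
        if config.go_map is not None:
            annot = read_go_map(config.go_map)
        elif config.simulate and truth is not None:
            annot, planted = simulate_go_map(
                truth, seed=config.seed + SEED_OFFSETS["go_map"]
            )
            write_go_map(annot, out / "go_map.tsv")
            manifest["stages"].setdefault("simulate", {})["planted_go_term"] = planted
        else:
            annot = None
        if annot is not None:
            enr = results.enrich(annot, grouping="all", method=config.enrich_method,
                                 sizes=config.top_sizes, alpha=config.alpha)
            write_table(enr, out / "enrich_all.tsv")
            manifest["stages"]["enrich"] = {"n_rows": len(enr)}

        stage = "qpcr"
        if config.ct_table is not None:
            ct = read_ct_table(config.ct_table)
        elif config.simulate and truth is not None:
            responders = truth.loc[truth["gene_class"] != "null", "gene_id"]
            tested = set(results.filtered_counts.gene_ids)
            selected = [g for g in responders if g in tested][: config.n_qpcr_genes]
            ct = simulate_ct_table(
                truth, selected, design, noise_sd=config.ct_noise_sd,
                seed=config.seed + SEED_OFFSETS["ct"],
            )
            write_table(ct, out / "ct.tsv")
        else:
            ct = None
        if ct is not None:
            records, (rho, pval, n_pairs) = results.validate_qpcr(ct)
            write_table(records, out / "ddct.tsv")
            manifest["stages"]["qpcr"] = {
                "spearman_rho": round(rho, 4), "p_value": round(pval, 6),
                "n_pairs": n_pairs,
            }

        stage = "phenotype"
        if config.phenotype is not None:
            pheno = read_phenotype_table(config.phenotype)
            decline = phenotype_decline(pheno)
            write_table(decline, out / "decline.tsv")
            manifest["stages"]["phenotype"] = {"n_rows": len(decline)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
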