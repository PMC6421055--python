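"""Model/Results surface tying the analysis stages together.

:class:`AluminumResponseModel` is built from a count matrix and a study
design (2 tolerance groups × 2 conditions); ``fit()`` runs expression
filtering, TMM normalization, per-grouping fold-change/exact-test tables and
the delta-score divergence ranking, and returns an
:class:`AluminumResponseResults` carrying all estimates plus ``summary()``,
enrichment and qPCR-validation methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .io_design import (
    CountMatrix,
    StudyDesign,
    GOAnnotationMap,
    read_counts,
    read_design,
)
from . import de, divergence, enrichment, normalize, qpcr


class AluminumResponseModel:
    """Divergence analysis of a stress-response RNA-seq count matrix.

    Parameters
    ----------
    counts, design
        Validated count matrix and design (strict sample-id equality).
    cpm_threshold, min_samples
        Expression filter: keep genes with raw CPM ≥ threshold in at least
        `min_samples` samples (default 2, the replicate-group size).
    pseudo
        CPM pseudocount added to both arm means before the fold-change ratio.
    dispersion
        Optional fixed common NB dispersion; estimated per grouping by the
        method of moments when None.
    """

    def __init__(
        self,
        counts: CountMatrix,
        design: StudyDesign,
        cpm_threshold: float = 1.5,
        min_samples: int | None = None,
        pseudo: float = 0.5,
        dispersion: float | None = None,
    ):
        design.validate_against(counts)
        self.counts = counts
        self.design = design
        self.cpm_threshold = cpm_threshold
        self.min_samples = min_samples
        self.pseudo = pseudo
        self.dispersion = dispersion

    @classmethod
    def from_files(cls, counts_path, design_path, **kwargs) -> "AluminumResponseModel":
        return cls(read_counts(counts_path), read_design(design_path), **kwargs)

    def fit(self, groupings: Sequence[str] | None = None) -> "AluminumResponseResults":
        """Run filtering, normalization, per-grouping DE, and delta-scores."""
        filtered = normalize.filter_low_expression(
            self.counts, self.cpm_threshold, self.min_samples
        )
        norm = normalize.tmm_factors(filtered)
        if groupings is None:
            grouping_objs = self.design.standard_groupings()
        else:
            grouping_objs = [self.design.grouping(n) for n in groupings]
        tables = {
            g.name: de.de_table(
                filtered, g, norm, pseudo=self.pseudo, dispersion=self.dispersion
            )
            for g in grouping_objs
        }
        genotype_tables = {
            name: t for name, t in tables.items() if name in self.design.genotypes
        }
        delta = None
        if set(genotype_tables) == set(self.design.genotypes):
            lfc = divergence.logfc_matrix_from_tables(genotype_tables)
            delta = divergence.delta_scores(lfc, self.design)
        return AluminumResponseResults(
            model=self,
            filtered_counts=filtered,
            normalization=norm,
            de_tables=tables,
            delta_table=delta,
        )


@dataclass
class AluminumResponseResults:
    """Fitted tables of the divergence analysis."""

    model: AluminumResponseModel
    filtered_counts: CountMatrix
    normalization: normalize.NormalizationResult
    de_tables: dict[str, pd.DataFrame]
    delta_table: pd.DataFrame | None = None
    _enrichments: dict = field(default_factory=dict, repr=False)

    @property
    def n_genes_tested(self) -> int:
        return self.filtered_counts.n_genes

    def top_divergent(self, k: int = 50) -> pd.DataFrame:
        if self.delta_table is None:
            raise ValueError("delta-score table requires per-genotype groupings")
        return divergence.top_divergent(self.delta_table, k)

    def enrich(
        self,
        annot: GOAnnotationMap,
        grouping: str = "all",
        method: str = "hypergeom",
        weights: Mapping[str, float] | None = None,
        sizes: Sequence[int] = enrichment.DEFAULT_TOP_SIZES,
        alpha: float = 0.05,
    ) -> pd.DataFrame:
        """GO over-representation for the top lists of one grouping's DE table."""
        table = self.de_tables[grouping]
        res = enrichment.enrich_top_lists(
            table, annot, universe=list(table["gene_id"]), sizes=sizes,
            alpha=alpha, method=method, weights=weights,
        )
        self._enrichments[grouping] = res
        return res

    def validate_qpcr(
        self, ct_table: pd.DataFrame, reference_gene: str = "ETIF3E"
    ) -> tuple[pd.DataFrame, tuple[float, float, int]]:
        """ΔΔCt per (gene, genotype) and its Spearman agreement with the
        per-genotype sequencing log2FC."""
        records = qpcr.ddct_table(ct_table, self.model.design, reference_gene)
        frames = []
        for genotype in self.model.design.genotypes:
            if genotype in self.de_tables:
                t = self.de_tables[genotype][["gene_id", "unit", "log2fc"]]
                frames.append(t)
        seq = pd.concat(frames, ignore_index=True)
        stats_tuple = qpcr.validate_correlation(records, seq)
        return records, stats_tuple

    def summary(self, k_top: int = 10) -> str:
        """Plain-text summary of the fitted analysis."""
        lines = []
        lines.append("Aluminum-response divergence analysis")
        lines.append("=" * 53)
        lines.append(f"genes tested (post CPM filter): {self.n_genes_tested}"
                     f" of {self.model.counts.n_genes}")
        lines.append(f"samples: {self.model.counts.n_samples}; "
                     f"TMM reference: {self.normalization.reference_sample}")
        lines.append("")
        lines.append("TMM factors:")
        for sid, f in self.normalization.factors.items():
            lines.append(f"  {sid:24s} {f:8.4f}")
        lines.append("")
        lines.append("significant genes (FDR < 0.05) per comparison:")
        for name, t in self.de_tables.items():
            n_sig = int((t["fdr"] < 0.05).sum())
            lines.append(f"  {name:24s} {n_sig:6d}")
        if self.delta_table is not None:
            lines.append("")
            lines.append(f"top {k_top} genes by delta-score (divergence between "
                         "tolerance groups):")
            cols = ["gene_id", "c_res", "c_sens", "mean_res", "mean_sens", "s_delta"]
            top = self.top_divergent(k_top)[cols]
            header = "  " + "  ".join(f"{c:>10s}" for c in cols)
            lines.append(header)
            for _, r in top.iterrows():
                lines.append(
                    f"  {r.gene_id:>10s}  {r.c_res:10.3f}  {r.c_sens:10.3f}  "
                    f"{r.mean_res:10.3f}  {r.mean_sens:10.3f}  {r.s_delta:10.3f}"
                )
        return "\n".join(lines)
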