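"""ΔΔCt relative expression, qPCR-vs-sequencing validation, and phenotype declines.

ΔΔCt follows the standard comparative-Ct scheme with a condition-invariant
reference gene: technical replicates are averaged per (gene, sample),
biological replicates per condition, then

    ΔCt = mean Ct_target − mean Ct_reference        (per condition)
    ΔΔCt = ΔCt_stress − ΔCt_control,

so that −ΔΔCt estimates the log2 fold change under 100% amplification
efficiency. Validation correlates −ΔΔCt with the sequencing log2FC over the
matched (gene, genotype) pairs using Spearman's rank coefficient (exact
permutation p-value up to n = 10 pairs, normal approximation above).

Phenotype declines summarise the field trial: per (cultivar, trait), the
stress mean as a percentage of the control mean, rounded half-up to one
decimal.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_design import StudyDesign, ValidationError, DEFAULT_REFERENCE_GENE


@dataclass
class DdctRecord:
    target_gene: str
    genotype: str
    dct_control: float
    dct_stress: float
    #: amplification efficiency as a fraction (1.0 = perfect doubling);
    #: values < 1 rescale −ΔΔCt by log2(1 + efficiency)
    efficiency: float = 1.0

    @property
    def ddct(self) -> float:
        return self.dct_stress - self.dct_control

    @property
    def log2_rel_expr(self) -> float:
        """−ΔΔCt (efficiency-corrected): the qPCR log2 fold-change estimate."""
        return -self.ddct * float(np.log2(1.0 + self.efficiency))


def ddct(
    ct: pd.DataFrame,
    target: str,
    genotype: str,
    design: StudyDesign,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    efficiency: float = 1.0,
) -> DdctRecord:
    """ΔΔCt of one target gene in one genotype."""
    if not 0.0 < efficiency <= 1.0:
        raise ValidationError("efficiency must be in (0, 1]")
    # technical replicates → per-sample mean Ct
    per_sample = ct.groupby(["target_gene", "sample_id"])["ct"].mean()

    def _mean_ct(gene: str, condition: str) -> float:
        samples = design.samples(genotype=genotype, condition=condition)
        vals = [per_sample[(gene, s)] for s in samples if (gene, s) in per_sample.index]
        if not vals:
            raise ValidationError(
                f"gene {gene!r} not measured under {condition} in genotype {genotype!r}"
            )
        return float(np.mean(vals))

    dct_control = _mean_ct(target, "control") - _mean_ct(reference_gene, "control")
    dct_stress = _mean_ct(target, "stress") - _mean_ct(reference_gene, "stress")
    return DdctRecord(target, genotype, dct_control, dct_stress, efficiency)


def ddct_table(
    ct: pd.DataFrame,
    design: StudyDesign,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    efficiency: float = 1.0,
) -> pd.DataFrame:
    """ΔΔCt for every (target gene, genotype) present in the Ct table."""
    targets = [g for g in ct["target_gene"].unique() if g != reference_gene]
    rows = []
    for genotype in design.genotypes:
        for target in targets:
            rec = ddct(ct, target, genotype, design, reference_gene, efficiency)
            rows.append(
                {"target_gene": rec.target_gene, "genotype": rec.genotype,
                 "dct_control": rec.dct_control, "dct_stress": rec.dct_stress,
                 "ddct": rec.ddct, "log2_rel_expr": rec.log2_rel_expr}
            )
    return pd.DataFrame(rows)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (n ≤ 10)."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    observed = abs(rho)
    count = 0
    total = 0
    # |rho| is computed per permutation of one rank vector; chunked to bound memory
    chunk: list[tuple] = []

    def _flush(chunk_perm: list[tuple]) -> int:
        # correlation of rx with each permuted ry
        perms = np.array(chunk_perm, dtype=float)
        rx_c = rx - rx.mean()
        ry_c = perms - perms.mean(axis=1, keepdims=True)
        num = ry_c @ rx_c
        den = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum(axis=1))
        r = num / den
        return int(np.sum(np.abs(r) >= observed - 1e-12))

    for perm in itertools.permutations(ry):
        chunk.append(perm)
        total += 1
        if len(chunk) >= 50000:
            count += _flush(chunk)
            chunk = []
    if chunk:
        count += _flush(chunk)
    return count / total


def validate_correlation(
    ddct_records: pd.DataFrame, seq_logfc: pd.DataFrame
) -> tuple[float, float, int]:
    """Spearman correlation between qPCR −ΔΔCt and sequencing log2FC.

    `seq_logfc` needs columns gene_id, genotype (or unit) and log2fc; pairs
    are matched on (gene, genotype). Returns (rho, p_value, n_pairs).
    """
    seq = seq_logfc.rename(columns={"unit": "genotype"}) if "unit" in seq_logfc.columns \
        else seq_logfc
    merged = ddct_records.merge(
        seq[["gene_id", "genotype", "log2fc"]],
        left_on=["target_gene", "genotype"],
        right_on=["gene_id", "genotype"],
    )
    n = len(merged)
    if n < 3:
        raise ValidationError(f"need ≥3 matched (gene, genotype) pairs, got {n}")
    x = merged["log2_rel_expr"].to_numpy()
    y = merged["log2fc"].to_numpy()
    rho = float(stats.spearmanr(x, y).statistic)
    if n <= 10:
        p = _spearman_exact_p(x, y, rho)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p, n


def _round_half_up(x: float, decimals: int = 1) -> float:
    scale = 10 ** decimals
    return math.floor(x * scale + 0.5) / scale


def phenotype_decline(table: pd.DataFrame) -> pd.DataFrame:
    """Stress mean as a percentage of the control mean per (cultivar, trait).

    decline_pct = round_half_up(100 × stress_mean / control_mean, 1).
    """
    pivot = table.pivot_table(
        index=["cultivar", "trait"], columns="condition", values="mean"
    )
    if (pivot["control"] <= 0).any():
        raise ValidationError("control means must be positive")
    rows = []
    for (cultivar, trait), row in pivot.iterrows():
        rows.append(
            {"cultivar": cultivar, "trait": trait,
             "stress_mean": float(row["stress"]), "control_mean": float(row["control"]),
             "decline_pct": _round_half_up(100.0 * row["stress"] / row["control"])}
        )
    return pd.DataFrame(rows)
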