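"""Consistency scores and the delta-score ranking of divergent responses.

The goal is to single out genes whose aluminum response differs between the
resistant and the sensitive tolerance group while being coherent *within*
each group. Three ingredients are combined per gene:

1. a consistency score per group,

       C = |Σ_i log2FC_i| / (n · max_i |log2FC_i|),

   over the n genotypes of the group — maximal (1) when the per-genotype
   changes are unidirectional and equal, zero when they cancel exactly, and
   scale-free so magnitude enters only through the next factor. A group
   whose changes are all exactly zero is taken as perfectly consistent
   (C = 1); divergence is then carried entirely by the third factor.

2. the larger of the two absolute group-mean log2FCs, carrying the magnitude
   of the response;

3. the squared difference of the group means, weighting between-group
   divergence twice as strongly (on the log scale) as the other components.

The delta-score is their product,

    S_Δ = C_res · C_sens · max(|mean_res|, |mean_sens|) · (mean_res − mean_sens)²,

and genes are ranked by decreasing S_Δ. S_Δ is symmetric under swapping the
group labels and scales as λ³ when every log2FC is scaled by λ > 0.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_design import StudyDesign, ValidationError


def consistency_score(logfc: Sequence[float]) -> float:
    """C = |Σ logfc_i| / (n · max|logfc_i|); C = 1 when all values are 0."""
    arr = np.asarray(list(logfc), dtype=float)
    if arr.size == 0:
        raise ValidationError("consistency_score requires at least one value")
    if not np.isfinite(arr).all():
        raise ValidationError("consistency_score requires finite values")
    peak = np.max(np.abs(arr))
    if peak == 0.0:
        return 1.0
    return float(np.abs(arr.sum()) / (arr.size * peak))


def delta_score(res_logfc: Sequence[float], sens_logfc: Sequence[float]) -> float:
    """S_Δ for one gene from its per-genotype log2FCs in the two groups."""
    c_res = consistency_score(res_logfc)
    c_sens = consistency_score(sens_logfc)
    mean_res = float(np.mean(res_logfc))
    mean_sens = float(np.mean(sens_logfc))
    return (
        c_res * c_sens * max(abs(mean_res), abs(mean_sens)) * (mean_res - mean_sens) ** 2
    )


def delta_scores(
    genotype_logfc: pd.DataFrame,
    design: StudyDesign,
) -> pd.DataFrame:
    """Delta-score table over all genes, sorted by decreasing S_Δ.

    Parameters
    ----------
    genotype_logfc
        DataFrame indexed by gene id with one column per genotype holding
        that genotype's log2FC (columns may be genotype names or
        ``logfc_<genotype>``).
    design
        Supplies the genotype → tolerance-group partition.

    Returns a table with per-genotype log2FC, C_res, C_sens, group means,
    S_delta and 1-based rank; ties in S_Δ break by descending
    |mean_res − mean_sens| then gene id.
    """
    cols = {}
    for genotype in design.genotypes:
        if genotype in genotype_logfc.columns:
            cols[genotype] = genotype_logfc[genotype]
        elif f"logfc_{genotype}" in genotype_logfc.columns:
            cols[genotype] = genotype_logfc[f"logfc_{genotype}"]
        else:
            raise ValidationError(f"no log2FC column for genotype {genotype!r}")
    lfc = pd.DataFrame(cols)
    if lfc.isna().any().any():
        bad = list(lfc.index[lfc.isna().any(axis=1)])[:5]
        raise ValidationError(f"gene(s) missing a genotype log2FC: {bad}")

    res = design.genotypes_in("resistant")
    sens = design.genotypes_in("sensitive")
    res_m = lfc[res].to_numpy()
    sens_m = lfc[sens].to_numpy()

    c_res = _consistency_vec(res_m)
    c_sens = _consistency_vec(sens_m)
    mean_res = res_m.mean(axis=1)
    mean_sens = sens_m.mean(axis=1)
    s_delta = (
        c_res * c_sens * np.maximum(np.abs(mean_res), np.abs(mean_sens))
        * (mean_res - mean_sens) ** 2
    )

    out = pd.DataFrame({"gene_id": lfc.index})
    for genotype in design.genotypes:
        out[f"logfc_{genotype}"] = lfc[genotype].to_numpy()
    out["c_res"] = c_res
    out["c_sens"] = c_sens
    out["mean_res"] = mean_res
    out["mean_sens"] = mean_sens
    out["s_delta"] = s_delta
    out["_absdiff"] = np.abs(mean_res - mean_sens)
    out = out.sort_values(
        ["s_delta", "_absdiff", "gene_id"], ascending=[False, False, True],
        kind="mergesort",
    ).drop(columns="_absdiff")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def _consistency_vec(m: np.ndarray) -> np.ndarray:
    peak = np.max(np.abs(m), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.abs(m.sum(axis=1)) / (m.shape[1] * peak)
    c[peak == 0.0] = 1.0
    return c


def top_divergent(records: pd.DataFrame, k: int) -> pd.DataFrame:
    """First k records of a delta-score table (already deterministically ordered)."""
    if k < 1:
        raise ValidationError("k must be ≥ 1")
    if k > len(records):
        warnings.warn(
            f"requested top {k} of only {len(records)} records; returning all",
            stacklevel=2,
        )
        k = len(records)
    return records.iloc[:k].reset_index(drop=True)


def logfc_matrix_from_tables(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Assemble the gene × genotype log2FC matrix from per-genotype DE tables."""
    cols = {}
    for genotype, table in tables.items():
        cols[genotype] = table.set_index("gene_id")["log2fc"]
    return pd.DataFrame(cols)
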