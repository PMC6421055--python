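"""Fold changes and a conditional negative-binomial exact test.

Fold change is defined directly on expression levels: the ratio of mean CPM
under aluminum stress to mean CPM under control conditions (with a small
pseudocount so the ratio is defined at zero), and log2FC is its binary
logarithm. Fold changes are computed per comparison unit — a pooled group of
genotypes or a single genotype.

Significance comes from a conditional NB exact test, a documented analogue
of the classic two-group exact test for overdispersed counts: counts are
scaled to a common effective library size, a single common dispersion φ
(variance = μ + φμ²) is estimated across genes by the method of moments, and
for each gene the stress-arm total is compared with its conditional
distribution given the gene's grand total. Because a sum of i.i.d. NB(μ, φ)
variables over n replicates is NB with size n/φ, that conditional law is
beta-binomial with shape parameters n_stress/φ and n_control/φ; at φ = 0 it
degenerates to the binomial split. Two-sided p-values double the smaller
tail, capped at 1. Equivalence with any particular software's dispersion
machinery is not claimed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_design import CountMatrix, ComparisonGrouping, ValidationError
from .normalize import NormalizationResult, compute_cpm


def fold_changes(
    cpm: pd.DataFrame, grouping: ComparisonGrouping, pseudo: float = 0.5
) -> pd.DataFrame:
    """Per-gene FC and log2FC for one comparison grouping.

    FC_g = (mean stress CPM_g + pseudo) / (mean control CPM_g + pseudo).
    """
    for arm, ids in (("stress", grouping.stress_samples),
                     ("control", grouping.control_samples)):
        missing = [s for s in ids if s not in cpm.columns]
        if missing:
            raise ValidationError(f"{arm} arm samples absent from CPM: {missing}")
    mean_stress = cpm[grouping.stress_samples].mean(axis=1)
    mean_control = cpm[grouping.control_samples].mean(axis=1)
    fc = (mean_stress + pseudo) / (mean_control + pseudo)
    return pd.DataFrame(
        {
            "gene_id": cpm.index,
            "unit": grouping.name,
            "mean_cpm_stress": mean_stress.to_numpy(),
            "mean_cpm_control": mean_control.to_numpy(),
            "fc": fc.to_numpy(),
            "log2fc": np.log2(fc.to_numpy()),
        }
    ).reset_index(drop=True)


def _equalized_counts(
    cm: CountMatrix, samples: list[str], norm: NormalizationResult
) -> np.ndarray:
    """Counts rescaled to the common (geometric-mean) effective library size."""
    eff = norm.effective_library_sizes.loc[samples].to_numpy(dtype=float)
    common = np.exp(np.mean(np.log(eff)))
    raw = cm.counts[samples].to_numpy(dtype=float)
    return raw * (common / eff)[None, :]


def estimate_common_dispersion(pseudo_counts: np.ndarray, arm_sizes: list[int]) -> float:
    """Method-of-moments common NB dispersion across genes.

    Per gene, the within-arm sample mean μ̂ and unbiased variance s² are
    pooled across arms; φ is the ratio estimator Σ(s² − μ̂·w)/Σ(μ̂² ·w) over
    genes, clipped at 0, which solves Var = μ + φμ² in aggregate. Arms with a
    single replicate contribute no variance information.
    """
    start = 0
    num = 0.0
    den = 0.0
    for n_arm in arm_sizes:
        block = pseudo_counts[:, start:start + n_arm]
        start += n_arm
        if n_arm < 2:
            continue
        mu = block.mean(axis=1)
        s2 = block.var(axis=1, ddof=1)
        ok = mu > 0
        num += float(np.sum(s2[ok] - mu[ok]))
        den += float(np.sum(mu[ok] ** 2))
    if den <= 0:
        return 0.0
    return max(0.0, num / den)


def exact_test(
    cm: CountMatrix,
    grouping: ComparisonGrouping,
    norm: NormalizationResult | None = None,
    dispersion: float | None = None,
) -> pd.Series:
    """Two-sided conditional exact-test p-values, one per gene.

    `dispersion` overrides the method-of-moments estimate (0 forces the
    binomial limit). p ∈ (0, 1].
    """
    if norm is None:
        norm = NormalizationResult.identity(cm)
    stress, control = grouping.stress_samples, grouping.control_samples
    n_s, n_c = len(stress), len(control)
    eq = _equalized_counts(cm, stress + control, norm)
    if eq[:, :n_s].sum() == 0 or eq[:, n_s:].sum() == 0:
        raise ValidationError(f"grouping {grouping.name!r}: an arm has zero total count")
    if dispersion is None:
        dispersion = estimate_common_dispersion(eq, [n_s, n_c])

    s_stress = np.rint(eq[:, :n_s].sum(axis=1)).astype(np.int64)
    s_control = np.rint(eq[:, n_s:].sum(axis=1)).astype(np.int64)
    totals = s_stress + s_control

    pvals = np.ones(cm.n_genes)
    for i in range(cm.n_genes):
        pvals[i] = _conditional_two_sided(s_stress[i], totals[i], n_s, n_c, dispersion)
    return pd.Series(pvals, index=cm.counts.index, name="p_value")


def _conditional_two_sided(x: int, t: int, n_stress: int, n_control: int, phi: float) -> float:
    """P of a split as extreme as x of t, doubling the smaller tail."""
    if t == 0:
        return 1.0
    if phi <= 0:
        p_arm = n_stress / (n_stress + n_control)
        lower = stats.binom.cdf(x, t, p_arm)
        upper = stats.binom.sf(x - 1, t, p_arm)
    else:
        a = n_stress / phi
        b = n_control / phi
        lower = stats.betabinom.cdf(x, t, a, b)
        upper = stats.betabinom.sf(x - 1, t, a, b)
    return float(min(1.0, 2.0 * min(lower, upper)))


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    return multipletests(pvals, method="fdr_bh")[1]


def rank_by_significance(table: pd.DataFrame) -> pd.DataFrame:
    """Order a fold-change table by decreasing statistical significance.

    Ascending p-value, ties broken by descending |log2FC| then gene id; a BH
    FDR column is appended. The ordering is invariant to input row order.
    """
    if "p_value" not in table.columns:
        raise ValidationError("rank_by_significance requires a p_value column")
    out = table.copy()
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    out["_abs_lfc"] = out["log2fc"].abs()
    out = out.sort_values(
        ["p_value", "_abs_lfc", "gene_id"], ascending=[True, False, True],
        kind="mergesort",
    ).drop(columns="_abs_lfc")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def de_table(
    cm: CountMatrix,
    grouping: ComparisonGrouping,
    norm: NormalizationResult | None = None,
    pseudo: float = 0.5,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Fold changes + exact-test p-values + FDR, ranked by significance."""
    if norm is None:
        norm = NormalizationResult.identity(cm)
    cpm = compute_cpm(cm, norm, effective=True)
    fc = fold_changes(cpm, grouping, pseudo=pseudo)
    pvals = exact_test(cm, grouping, norm, dispersion=dispersion)
    fc = fc.merge(pvals.rename("p_value"), left_on="gene_id", right_index=True)
    return rank_by_significance(fc)
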