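"""CPM computation, low-expression filtering, and TMM normalization.

TMM (trimmed mean of M-values) computes one scaling factor per sample from
doubly trimmed, precision-weighted log2 count-ratios (M-values) against a
reference sample, so that composition differences between libraries do not
masquerade as differential expression. The implementation follows the
published algorithm: reference = sample whose 75th-percentile count fraction
is closest to the mean across samples; per sample, M and A statistics over
genes positive in both sample and reference; a double trim (30% on M, 5% on
A by default); and a weighted mean of the surviving M-values with inverse
asymptotic (delta-method) binomial variances as weights. Factors are
re-centred to geometric mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_design import CountMatrix, ValidationError


@dataclass
class NormalizationResult:
    """Per-sample TMM factors and derived effective library sizes."""

    factors: pd.Series  # geometric mean 1
    library_sizes: pd.Series
    reference_sample: str

    @property
    def effective_library_sizes(self) -> pd.Series:
        return self.library_sizes * self.factors

    @staticmethod
    def identity(cm: CountMatrix) -> "NormalizationResult":
        """Unit factors (no between-sample normalization)."""
        f = pd.Series(1.0, index=cm.counts.columns)
        return NormalizationResult(f, cm.library_sizes.astype(float), cm.sample_ids[0])


def compute_cpm(
    cm: CountMatrix, norm: NormalizationResult | None = None, effective: bool = False
) -> pd.DataFrame:
    """Counts per million: CPM_gk = y_gk / (N_k · f_k if effective else N_k) × 1e6."""
    libs = cm.library_sizes.astype(float)
    if (libs <= 0).any():
        bad = list(libs.index[libs <= 0])
        raise ValidationError(f"zero library size for sample(s): {bad}")
    if effective:
        if norm is None:
            raise ValidationError("effective CPM requires a NormalizationResult")
        libs = libs * norm.factors.loc[libs.index]
    return cm.counts.div(libs, axis=1) * 1e6


def filter_low_expression(
    cm: CountMatrix, cpm_threshold: float = 1.5, min_samples: int | None = None
) -> CountMatrix:
    """Drop genes with raw CPM below `cpm_threshold` in too many samples.

    A gene is kept when its raw (pre-normalization) CPM reaches the threshold
    in at least `min_samples` samples; the default `min_samples` is the
    replicate-group size convention (2), keeping genes expressed in a single
    condition of a single genotype. Library sizes of the returned matrix are
    the pre-filter totals: filtering selects genes, it does not change how
    many reads were sequenced.
    """
    if cpm_threshold <= 0:
        raise ValidationError("cpm_threshold must be positive")
    if min_samples is None:
        min_samples = min(2, cm.n_samples)
    if not (1 <= min_samples <= cm.n_samples):
        raise ValidationError(
            f"min_samples must be in [1, {cm.n_samples}], got {min_samples}"
        )
    cpm = compute_cpm(cm)
    keep = (cpm >= cpm_threshold).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValidationError(
            "all genes fall below the CPM threshold; review cpm_threshold/min_samples"
        )
    return cm.subset_genes(list(cm.counts.index[keep]), keep_library_sizes=True)


def _choose_reference(counts: np.ndarray, libs: np.ndarray) -> int:
    """Sample whose 75th-percentile count fraction is closest to the mean."""
    with np.errstate(divide="ignore", invalid="ignore"):
        f75 = np.array(
            [np.quantile(counts[:, k] / libs[k], 0.75) for k in range(counts.shape[1])]
        )
    return int(np.argmin(np.abs(f75 - f75.mean())))


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
    weighted: bool,
) -> float:
    """TMM factor of one sample against the reference (log2 scale returned as 2^·)."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise ValidationError("no gene with positive counts in both sample and reference")
    o = obs[pos].astype(float)
    r = ref[pos].astype(float)
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)

    if np.max(np.abs(m)) < 1e-6:
        return 1.0

    n = m.size
    # double trim by rank, matching the published cutoffs
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    if weighted:
        log_f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    else:
        log_f = np.mean(m[keep])
    if not np.isfinite(log_f):
        return 1.0
    return float(2.0 ** log_f)


def tmm_factors(
    cm: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    weighted: bool = True,
    reference: str | None = None,
) -> NormalizationResult:
    """Compute TMM normalization factors, re-centred to geometric mean 1."""
    if cm.n_samples < 2:
        raise ValidationError("TMM requires at least 2 samples")
    counts = cm.counts.to_numpy(dtype=float)
    libs = cm.library_sizes.to_numpy(dtype=float)
    if reference is None:
        ref_idx = _choose_reference(counts, libs)
    else:
        ref_idx = cm.sample_ids.index(reference)
    ref_col = counts[:, ref_idx]
    n_ref = libs[ref_idx]

    f = np.empty(cm.n_samples)
    for k in range(cm.n_samples):
        if k == ref_idx:
            f[k] = 1.0
        else:
            f[k] = _tmm_pair(counts[:, k], ref_col, libs[k], n_ref, trim_m, trim_a, weighted)
    f = f / np.exp(np.mean(np.log(f)))
    return NormalizationResult(
        pd.Series(f, index=cm.counts.columns),
        cm.library_sizes.astype(float),
        cm.sample_ids[ref_idx],
    )
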