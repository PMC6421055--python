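"""GO over-representation analysis on top lists of regulated genes.

Top lists of the n most significant up- and downregulated genes (n = 50,
100, 300 and "all significant at p < 0.05" by default) are tested per GO
term for over-representation against the tested gene universe (the genes
that survived expression filtering). The default test is the upper-tail
hypergeometric; an optional Wallenius noncentral variant accepts per-gene
positive weights (e.g. length-bias weights) and reduces to the central test
when all weights are equal. BH adjustment is applied within each
(direction, top-size) stratum, over terms annotating at least
``min_term_size`` universe genes. The annotation map is taken as given — no
GO-DAG ancestor propagation.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_design import GOAnnotationMap, ValidationError
from .de import bh_fdr

DEFAULT_TOP_SIZES = (50, 100, 300)


def build_top_lists(
    ranked: pd.DataFrame,
    sizes: Sequence[int] = DEFAULT_TOP_SIZES,
    alpha: float = 0.05,
) -> dict[str, dict[str, list[str]]]:
    """Top-n gene lists per direction from a significance-ranked DE table.

    Returns ``{"up": {"50": [...], ..., "all": [...]}, "down": {...}}``. A
    gene is "up" when log2FC > 0 and "down" when < 0 (log2FC = 0 belongs to
    neither). Every list is drawn from the genes significant at `alpha`, in
    ranking order, so "top 300" is capped at the number of significant genes
    in that direction (with a warning when capped), and "all" is the full
    significant set.
    """
    if "p_value" not in ranked.columns or "log2fc" not in ranked.columns:
        raise ValidationError("ranked table requires p_value and log2fc columns")
    sig = ranked.loc[ranked["p_value"] < alpha]
    out: dict[str, dict[str, list[str]]] = {}
    for direction, mask in (("up", sig["log2fc"] > 0), ("down", sig["log2fc"] < 0)):
        genes = list(sig.loc[mask, "gene_id"])
        lists: dict[str, list[str]] = {}
        for size in sizes:
            if size > len(genes):
                warnings.warn(
                    f"{direction}: requested top {size}, only {len(genes)} "
                    f"significant genes; list capped",
                    stacklevel=2,
                )
            lists[str(size)] = genes[:size]
        lists["all"] = list(genes)
        out[direction] = lists
    return out


def _check_and_count(
    top: Sequence[str], universe: Sequence[str], annot: GOAnnotationMap,
    min_term_size: int,
):
    uni = list(dict.fromkeys(universe))
    uni_set = set(uni)
    offenders = sorted(set(top) - uni_set)
    if offenders:
        raise ValidationError(f"top genes outside the universe: {offenders}")
    top_set = set(top)
    term_genes = annot.term_to_genes(uni_set)
    rows = []
    for term, genes in sorted(term_genes.items()):
        big_k = len(genes)
        if big_k < min_term_size:
            continue
        rows.append((term, genes, big_k, len(genes & top_set)))
    return uni, top_set, rows


def hypergeom_enrich(
    top: Sequence[str],
    universe: Sequence[str],
    annot: GOAnnotationMap,
    min_term_size: int = 3,
    direction: str = "",
    top_size: str = "",
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per GO term.

    For a term annotating K of the N universe genes, with k of the n top
    genes annotated, p = P(X ≥ k), X ~ Hypergeom(N, K, n). BH FDR is
    computed across the tested terms.
    """
    uni, top_set, rows = _check_and_count(top, universe, annot, min_term_size)
    big_n, n = len(uni), len(top_set)
    records = []
    for term, _genes, big_k, k in rows:
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        records.append(
            {"term_id": term, "term_label": annot.label(term), "n_universe": big_n,
             "n_annotated": big_k, "n_top": n, "n_overlap": k,
             "p_value": min(1.0, p), "direction": direction, "top_size": top_size}
        )
    return _finalize(records)


def wallenius_enrich(
    top: Sequence[str],
    universe: Sequence[str],
    annot: GOAnnotationMap,
    weights: Mapping[str, float],
    min_term_size: int = 3,
    direction: str = "",
    top_size: str = "",
) -> pd.DataFrame:
    """Weighted over-representation via Wallenius' noncentral hypergeometric.

    Per term, the odds parameter is the mean weight of annotated universe
    genes over the mean weight of unannotated ones; equal weights reduce to
    the central hypergeometric test exactly.
    """
    uni, top_set, rows = _check_and_count(top, universe, annot, min_term_size)
    w = np.array([weights.get(g, np.nan) for g in uni], dtype=float)
    if np.isnan(w).any():
        missing = [g for g, wi in zip(uni, w) if np.isnan(wi)][:5]
        raise ValidationError(f"weights undefined for universe genes: {missing}")
    if (w <= 0).any():
        raise ValidationError("weights must be positive")
    uni_index = {g: i for i, g in enumerate(uni)}
    big_n, n = len(uni), len(top_set)
    records = []
    for term, genes, big_k, k in rows:
        inside = np.fromiter((uni_index[g] for g in genes), dtype=int)
        mask = np.zeros(big_n, dtype=bool)
        mask[inside] = True
        mean_in = w[mask].mean()
        mean_out = w[~mask].mean() if big_k < big_n else mean_in
        odds = mean_in / mean_out
        if np.isclose(odds, 1.0, rtol=0, atol=1e-12):
            p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        else:
            p = float(stats.nchypergeom_wallenius.sf(k - 1, big_n, big_k, n, odds))
        records.append(
            {"term_id": term, "term_label": annot.label(term), "n_universe": big_n,
             "n_annotated": big_k, "n_top": n, "n_overlap": k,
             "p_value": min(1.0, max(p, 0.0)), "direction": direction,
             "top_size": top_size}
        )
    return _finalize(records)


def _finalize(records: list[dict]) -> pd.DataFrame:
    columns = ["term_id", "term_label", "n_universe", "n_annotated", "n_top",
               "n_overlap", "p_value", "bh_fdr", "direction", "top_size"]
    if not records:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(records)
    df["bh_fdr"] = bh_fdr(df["p_value"].to_numpy())
    df = df.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    return df[columns]


def enrich_top_lists(
    ranked: pd.DataFrame,
    annot: GOAnnotationMap,
    universe: Sequence[str] | None = None,
    sizes: Sequence[int] = DEFAULT_TOP_SIZES,
    alpha: float = 0.05,
    method: str = "hypergeom",
    weights: Mapping[str, float] | None = None,
    min_term_size: int = 3,
) -> pd.DataFrame:
    """Run over-representation for every (direction, top-size) stratum.

    BH adjustment is per stratum; results are concatenated with `direction`
    and `top_size` columns identifying the stratum.
    """
    if universe is None:
        universe = list(ranked["gene_id"])
    lists = build_top_lists(ranked, sizes=sizes, alpha=alpha)
    frames = []
    for direction, by_size in lists.items():
        for size_label, genes in by_size.items():
            if not genes:
                continue
            if method == "hypergeom":
                res = hypergeom_enrich(genes, universe, annot, min_term_size,
                                       direction, size_label)
            elif method == "wallenius":
                if weights is None:
                    raise ValidationError("wallenius method requires weights")
                res = wallenius_enrich(genes, universe, annot, weights,
                                       min_term_size, direction, size_label)
            else:
                raise ValidationError(f"unknown enrichment method {method!r}")
            frames.append(res)
    if not frames:
        return _finalize([])
    return pd.concat(frames, ignore_index=True)
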