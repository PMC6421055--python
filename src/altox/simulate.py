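"""Negative-binomial count simulator with planted gene-response classes.

The generator emulates the downstream count matrix of a 4-genotype
(2 resistant, 2 sensitive) × 2-condition (control / aluminum stress) bulk
RNA-seq design with 2 biological replicates per cell — 16 samples. Counts are
drawn from a negative binomial with variance μ + φμ² (edgeR's dispersion
convention), per-gene baseline means log-normal on the count scale, and
per-sample library-size variation.

Genes are planted into response classes that operationalise the behaviours
the divergence analysis must discriminate: shared responses, group-specific
responses, opposite responses between tolerance groups, and responses that
are inconsistent *within* a group (opposite signs in the two genotypes of one
group — the case the consistency score must nullify). The returned truth
table records each gene's class and its planted per-genotype log2
fold change, so every downstream stage is testable without any download.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_design import CountMatrix, StudyDesign, GOAnnotationMap, ValidationError

logger = logging.getLogger(__name__)

GENE_CLASSES = (
    "null",
    "shared_up",
    "shared_down",
    "resistant_specific_up",
    "sensitive_specific_up",
    "divergent_opposite",
    "inconsistent_within_group",
)

DEFAULT_GENOTYPES = {
    "resistant": ("Hermes", "TMP1919"),
    "sensitive": ("Lira", "Orshanskiy"),
}

DEFAULT_CLASS_FRACTIONS = {
    "null": 0.85,
    "shared_up": 0.03,
    "shared_down": 0.03,
    "resistant_specific_up": 0.03,
    "sensitive_specific_up": 0.02,
    "divergent_opposite": 0.02,
    "inconsistent_within_group": 0.02,
}


@dataclass
class SimulationConfig:
    """Parameters of the count simulator.

    Defaults describe a small flax-like experiment: 5000 genes, 4 genotypes
    split 2/2 into tolerance groups, 2 replicates per (genotype, condition)
    cell, library sizes around 2 million reads, log-normal baseline means
    (median count ≈ 40, i.e. ≈ 20 CPM) and gamma-distributed NB dispersions
    with mean 0.1 — typical bulk-RNA-seq biological-replicate overdispersion.
    """

    n_genes: int = 5000
    genotypes: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_GENOTYPES)
    )
    replicates: int = 2
    baseline_meanlog: float = float(np.log(40.0))
    baseline_sdlog: float = 1.5
    dispersion_shape: float = 2.0
    dispersion_mean: float = 0.1
    library_size_range: tuple[float, float] = (0.8e0 * 2e6, 1.2e0 * 2e6)
    class_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    effect_size: float = 2.0
    #: genotype-level jitter (sd, log2 units) added to each planted non-null
    #: log2FC, emulating biological heterogeneity within a tolerance group
    within_group_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be positive")
        if self.replicates <= 0:
            raise ValidationError("replicates must be positive")
        unknown = set(self.class_fractions) - set(GENE_CLASSES)
        if unknown:
            raise ValidationError(f"unknown gene classes: {sorted(unknown)}")
        total = sum(self.class_fractions.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValidationError(f"class fractions must sum to 1, got {total}")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ValidationError("class fractions must be non-negative")
        if not np.isfinite(self.effect_size):
            raise ValidationError("effect size must be finite")
        for group in ("resistant", "sensitive"):
            if group not in self.genotypes or len(self.genotypes[group]) == 0:
                raise ValidationError(f"tolerance group {group!r} needs ≥1 genotype")


def _planted_logfc(cls: str, effect: float, genotypes: dict, rng: np.random.Generator,
                   within_sd: float) -> dict[str, float]:
    """Per-genotype planted log2FC for one gene of class `cls`."""
    res = list(genotypes["resistant"])
    sens = list(genotypes["sensitive"])
    lfc = {g: 0.0 for g in res + sens}
    if cls == "shared_up":
        for g in res + sens:
            lfc[g] = effect
    elif cls == "shared_down":
        for g in res + sens:
            lfc[g] = -effect
    elif cls == "resistant_specific_up":
        for g in res:
            lfc[g] = effect
    elif cls == "sensitive_specific_up":
        for g in sens:
            lfc[g] = effect
    elif cls == "divergent_opposite":
        for g in res:
            lfc[g] = effect / 2.0
        for g in sens:
            lfc[g] = -effect / 2.0
    elif cls == "inconsistent_within_group":
        # opposite signs within one group (chosen at random), other group flat
        group = res if rng.random() < 0.5 else sens
        signs = rng.permutation([1.0, -1.0] * (len(group) // 2 + 1))[: len(group)]
        for g, s in zip(group, signs):
            lfc[g] = s * effect / 2.0
    if within_sd > 0:
        for g in lfc:
            if lfc[g] != 0.0 or cls != "null":
                lfc[g] += rng.normal(0.0, within_sd)
    return lfc


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, StudyDesign, pd.DataFrame]:
    """Draw a count matrix, its design sheet and the planted-truth table.

    Counts follow NB(mean = baseline × 2^(planted log2FC if stress) ×
    library-size factor, dispersion φ) with variance μ + φμ². The truth table
    has one row per gene with its class label and planted per-genotype log2FC
    columns ``logfc_<genotype>``. Fixing the seed makes the three outputs
    byte-identical across runs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    res = list(config.genotypes["resistant"])
    sens = list(config.genotypes["sensitive"])
    all_genotypes = res + sens

    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]

    # class assignment: deterministic counts per class (largest remainder)
    fracs = {c: config.class_fractions.get(c, 0.0) for c in GENE_CLASSES}
    counts_per_class = {c: int(np.floor(f * config.n_genes)) for c, f in fracs.items()}
    short = config.n_genes - sum(counts_per_class.values())
    remainders = sorted(
        GENE_CLASSES, key=lambda c: fracs[c] * config.n_genes - counts_per_class[c],
        reverse=True,
    )
    for c in remainders[:short]:
        counts_per_class[c] += 1
    labels = np.concatenate(
        [np.repeat(c, n) for c, n in counts_per_class.items() if n > 0]
    )
    rng.shuffle(labels)

    baseline = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, config.n_genes)
    phi = rng.gamma(
        config.dispersion_shape,
        config.dispersion_mean / config.dispersion_shape,
        config.n_genes,
    )

    truth_rows = []
    logfc = np.zeros((config.n_genes, len(all_genotypes)))
    for i, (gid, cls) in enumerate(zip(gene_ids, labels)):
        lfc = _planted_logfc(cls, config.effect_size, config.genotypes, rng,
                             config.within_group_sd)
        if cls == "null":
            lfc = {g: 0.0 for g in all_genotypes}
        for j, g in enumerate(all_genotypes):
            logfc[i, j] = lfc[g]
        truth_rows.append({"gene_id": gid, "gene_class": cls,
                           "baseline_mean": baseline[i], "dispersion": phi[i],
                           **{f"logfc_{g}": lfc[g] for g in all_genotypes}})
    truth = pd.DataFrame(truth_rows)

    # design and library sizes
    design_rows = []
    sample_ids = []
    lib_lo, lib_hi = config.library_size_range
    nominal = 0.5 * (lib_lo + lib_hi)
    lib_sizes = {}
    for g in all_genotypes:
        tol = "resistant" if g in res else "sensitive"
        for cond in ("control", "stress"):
            for rep in range(1, config.replicates + 1):
                sid = f"{g}_{cond}_r{rep}"
                sample_ids.append(sid)
                design_rows.append(
                    {"sample_id": sid, "genotype": g, "tolerance": tol,
                     "condition": cond, "replicate": rep}
                )
                lib_sizes[sid] = rng.uniform(lib_lo, lib_hi)
    design = StudyDesign(pd.DataFrame(design_rows))

    geno_index = {g: j for j, g in enumerate(all_genotypes)}
    counts = np.zeros((config.n_genes, len(sample_ids)), dtype=np.int64)
    for k, row in enumerate(design_rows):
        factor = lib_sizes[row["sample_id"]] / nominal
        mu = baseline * factor
        if row["condition"] == "stress":
            mu = mu * np.exp2(logfc[:, geno_index[row["genotype"]]])
        counts[:, k] = _nb_draw(rng, mu, phi)

    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids))
    return cm, design, truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB with variance μ + φμ²; φ=0 entries fall back to Poisson."""
    mu = np.asarray(mu, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    poisson = phi <= 0
    if poisson.any():
        out[poisson] = rng.poisson(mu[poisson])
    nb = ~poisson
    if nb.any():
        r = 1.0 / phi[nb]
        p = r / (r + mu[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


def simulate_ct_table(
    truth: pd.DataFrame,
    selected_genes: list[str],
    design: StudyDesign,
    noise_sd: float = 0.3,
    seed: int = 0,
    reference_gene: str = "ETIF3E",
    technical_replicates: int = 3,
) -> pd.DataFrame:
    """Generate a qPCR Ct table whose −ΔΔCt equals the planted log2FC + noise.

    Each target gene gets a base Ct in the observed assay range; under stress
    the target's Ct shifts by −(planted log2FC) for that genotype, so that
    ΔΔCt = −log2FC exactly when ``noise_sd`` is 0. The reference gene is
    condition-invariant up to noise. Values are clamped to the empirical
    [23, 32] cycle window with a warning when clamping occurs.
    """
    missing = [g for g in selected_genes if g not in set(truth["gene_id"])]
    if missing:
        raise ValidationError(f"selected genes absent from truth table: {missing}")
    rng = np.random.default_rng(seed)
    truth_idx = truth.set_index("gene_id")
    rows = []
    # base Ct kept away from the clamp window edges so planted shifts of a
    # few cycles rarely clip
    base_ct = {g: rng.uniform(26.0, 29.0) for g in selected_genes}
    ref_ct = 26.0
    clamped = 0
    for _, srow in design.table.iterrows():
        sid, genotype, cond = srow["sample_id"], srow["genotype"], srow["condition"]
        for gene in [*selected_genes, reference_gene]:
            if gene == reference_gene:
                center = ref_ct
            else:
                center = base_ct[gene]
                if cond == "stress":
                    center = center - float(truth_idx.loc[gene, f"logfc_{genotype}"])
            for tech in range(1, technical_replicates + 1):
                ct = center + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                if ct < 23.0 or ct > 32.0:
                    clamped += 1
                    ct = min(max(ct, 23.0), 32.0)
                rows.append({"target_gene": gene, "sample_id": sid,
                             "technical_replicate": tech, "ct": ct})
    if clamped:
        warnings.warn(f"{clamped} Ct value(s) clamped to [23, 32]", stacklevel=2)
    return pd.DataFrame(rows)


def simulate_go_map(
    truth: pd.DataFrame,
    n_terms: int = 50,
    planted_class: str = "divergent_opposite",
    coverage: float = 0.8,
    term_size_range: tuple[int, int] = (10, 80),
    seed: int = 0,
) -> tuple[GOAnnotationMap, str]:
    """Random flat GO map with one term planted on a gene class.

    The planted term annotates `coverage` of the genes in `planted_class`
    (plus a few background genes); the remaining terms draw genes uniformly.
    Returns the map and the planted term id.
    """
    rng = np.random.default_rng(seed)
    genes = list(truth["gene_id"])
    class_genes = list(truth.loc[truth["gene_class"] == planted_class, "gene_id"])
    mapping: dict[str, set[str]] = {}
    labels: dict[str, str] = {}

    planted_term = "GO:9000000"
    n_in = max(1, int(round(coverage * len(class_genes))))
    chosen = list(rng.choice(class_genes, size=n_in, replace=False)) if class_genes else []
    background = list(rng.choice(genes, size=max(2, n_in // 10), replace=False))
    for g in chosen + background:
        mapping.setdefault(g, set()).add(planted_term)
    labels[planted_term] = f"synthetic term planted on {planted_class}"

    lo, hi = term_size_range
    for t in range(n_terms - 1):
        term = f"GO:{7000000 + t}"
        size = int(rng.integers(lo, hi + 1))
        for g in rng.choice(genes, size=min(size, len(genes)), replace=False):
            mapping.setdefault(g, set()).add(term)
        labels[term] = f"synthetic background term {t}"
    return GOAnnotationMap(mapping, labels), planted_term


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
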