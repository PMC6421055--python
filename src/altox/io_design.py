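"""Tabular I/O and experimental-design validation.

All on-disk tables are TSV (tab-separated, UTF-8, one header row). The
canonical in-memory containers are thin wrappers around pandas objects with
validation at construction time:

* :class:`CountMatrix` — gene × sample non-negative integer read counts.
* :class:`StudyDesign` — per-sample genotype / tolerance-group / condition /
  replicate annotation for the 2-group (resistant vs sensitive) × 2-condition
  (control vs aluminum stress) design.
* :class:`GOAnnotationMap` — flat gene → GO-term annotation.
* Plain DataFrames for the qPCR Ct table and the phenotype-means table,
  validated by :func:`read_ct_table` / :func:`read_phenotype_table`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TOLERANCE_LEVELS = ("resistant", "sensitive")
CONDITION_LEVELS = ("control", "stress")

#: Traits expected in a phenotype table (free-form strings are allowed; these
#: are the ones the field study reports).
DEFAULT_TRAITS = ("plant height cm", "fiber mass mg", "seed pod count")

DEFAULT_REFERENCE_GENE = "ETIF3E"


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Gene-by-sample integer read counts.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with sample ids as columns. Values must
        be non-negative integers (fractional input is rejected here; rounding
        happens at file ingest, see :func:`read_counts`).
    library_sizes
        Optional per-sample totals. When omitted they are the column sums.
        They may legitimately differ from the column sums after gene
        filtering, where the pre-filter totals are deliberately retained.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = sorted(set(c.index[c.index.duplicated()]))
            raise ValidationError(f"duplicate gene ids: {dups}")
        if c.columns.has_duplicates:
            dups = sorted(set(c.columns[c.columns.duplicated()]))
            raise ValidationError(f"duplicate sample ids: {dups}")
        values = c.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("count matrix body must be numeric")
        if (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at gene {c.index[g]!r}, sample {c.columns[s]!r}"
            )
        if not np.issubdtype(values.dtype, np.integer):
            if np.any(values != np.round(values)):
                g, s = np.argwhere(values != np.round(values))[0]
                raise ValidationError(
                    "non-integer count at gene "
                    f"{c.index[g]!r}, sample {c.columns[s]!r}; round at ingest"
                )
            self.counts = c.astype(np.int64)
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(np.int64)
        else:
            self.library_sizes = pd.Series(self.library_sizes, dtype=np.int64)
            missing = [s for s in self.counts.columns if s not in self.library_sizes.index]
            if missing:
                raise ValidationError(f"library sizes missing for samples: {missing}")
            self.library_sizes = self.library_sizes.loc[self.counts.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, genes: Iterable[str], keep_library_sizes: bool = True) -> "CountMatrix":
        """Return a new matrix restricted to `genes`.

        With ``keep_library_sizes`` (the default) the per-sample totals of the
        *unfiltered* matrix are carried over: gene filtering selects genes, it
        does not re-sequence the library.
        """
        sub = self.counts.loc[list(genes)]
        libs = self.library_sizes if keep_library_sizes else None
        return CountMatrix(sub, library_sizes=libs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts) and self.library_sizes.equals(
            other.library_sizes
        )


def read_counts(path) -> CountMatrix:
    """Read a counts TSV (first column gene ids, header row sample ids).

    Fractional values (e.g. RSEM expected counts) are rounded half-to-even
    with a logged warning; negative values and duplicate ids raise
    :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    body = df.to_numpy()
    if not np.issubdtype(body.dtype, np.number):
        raise ValidationError(f"{path}: count matrix body must be numeric")
    if np.any(body != np.round(body)):
        n_frac = int(np.sum(body != np.round(body)))
        logger.warning(
            "%s: %d fractional count(s) rounded half-to-even at ingest", path, n_frac
        )
        df = pd.DataFrame(
            np.rint(body), index=df.index, columns=df.columns
        )  # np.rint rounds half to even
    return CountMatrix(df)


def write_counts(cm: CountMatrix, path) -> None:
    """Write a counts TSV; read_counts(write_counts(x)) == x."""
    df = cm.counts.copy()
    df.index.name = df.index.name or "gene_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# StudyDesign
# ---------------------------------------------------------------------------


@dataclass
class ComparisonGrouping:
    """Named stress-arm / control-arm sample sets for one comparison unit."""

    name: str
    stress_samples: list[str]
    control_samples: list[str]

    def __post_init__(self) -> None:
        if not self.stress_samples or not self.control_samples:
            raise ValidationError(f"grouping {self.name!r}: both arms must be non-empty")
        if set(self.stress_samples) & set(self.control_samples):
            raise ValidationError(f"grouping {self.name!r}: arms overlap")


@dataclass
class StudyDesign:
    """Validated per-sample design table.

    The table holds one row per sample with columns ``sample_id``,
    ``genotype``, ``tolerance`` (resistant/sensitive), ``condition``
    (control/stress) and ``replicate``. Tokens are folded to lower case.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = ["sample_id", "genotype", "tolerance", "condition", "replicate"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"design table missing columns: {missing}")
        t = self.table.copy()
        for col in ("tolerance", "condition"):
            t[col] = t[col].astype(str).str.strip().str.lower()
        for col, levels in (("tolerance", TOLERANCE_LEVELS), ("condition", CONDITION_LEVELS)):
            bad = t.loc[~t[col].isin(levels)]
            if len(bad):
                row = bad.iloc[0]
                raise ValidationError(
                    f"unknown {col} value {row[col]!r} for sample {row['sample_id']!r}; "
                    f"expected one of {levels}"
                )
        if t["sample_id"].duplicated().any():
            dups = sorted(set(t.loc[t["sample_id"].duplicated(), "sample_id"]))
            raise ValidationError(f"duplicate sample ids in design: {dups}")
        t["replicate"] = t["replicate"].astype(int)
        if (t["replicate"] < 1).any():
            raise ValidationError("replicate indices must be positive integers")
        # genotype ↦ tolerance must be a function
        gt = t.groupby("genotype")["tolerance"].nunique()
        if (gt > 1).any():
            raise ValidationError(
                f"genotype(s) assigned to multiple tolerance groups: {list(gt[gt > 1].index)}"
            )
        for group in TOLERANCE_LEVELS:
            if not (t["tolerance"] == group).any():
                raise ValidationError(f"tolerance group {group!r} has no genotypes")
        cell = t.groupby(["genotype", "condition"]).size()
        for genotype in t["genotype"].unique():
            for condition in CONDITION_LEVELS:
                if (genotype, condition) not in cell.index:
                    raise ValidationError(
                        f"design cell ({genotype}, {condition}) has no replicates"
                    )
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def genotypes(self) -> list[str]:
        return list(dict.fromkeys(self.table["genotype"]))

    def tolerance_of(self, genotype: str) -> str:
        sub = self.table.loc[self.table["genotype"] == genotype, "tolerance"]
        if sub.empty:
            raise KeyError(genotype)
        return sub.iloc[0]

    def genotypes_in(self, tolerance: str) -> list[str]:
        sub = self.table.loc[self.table["tolerance"] == tolerance, "genotype"]
        return list(dict.fromkeys(sub))

    def samples(self, *, genotype: str | None = None, tolerance: str | None = None,
                condition: str | None = None) -> list[str]:
        t = self.table
        mask = pd.Series(True, index=t.index)
        if genotype is not None:
            mask &= t["genotype"] == genotype
        if tolerance is not None:
            mask &= t["tolerance"] == tolerance
        if condition is not None:
            mask &= t["condition"] == condition
        return list(t.loc[mask, "sample_id"])

    def grouping(self, name: str) -> ComparisonGrouping:
        """Resolve a comparison grouping by name.

        Recognised names: ``all`` (every genotype pooled), ``resistant`` and
        ``sensitive`` (tolerance-group pools), or any genotype name.
        """
        if name == "all":
            return ComparisonGrouping(
                "all", self.samples(condition="stress"), self.samples(condition="control")
            )
        if name in TOLERANCE_LEVELS:
            return ComparisonGrouping(
                name,
                self.samples(tolerance=name, condition="stress"),
                self.samples(tolerance=name, condition="control"),
            )
        if name in self.genotypes:
            return ComparisonGrouping(
                name,
                self.samples(genotype=name, condition="stress"),
                self.samples(genotype=name, condition="control"),
            )
        raise KeyError(f"unknown grouping {name!r}")

    def standard_groupings(self) -> list[ComparisonGrouping]:
        """The pooled-all, two tolerance-group pools and per-genotype groupings."""
        names = ["all", *TOLERANCE_LEVELS, *self.genotypes]
        return [self.grouping(n) for n in names]

    def validate_against(self, cm: CountMatrix) -> None:
        """Require set equality between design samples and matrix columns."""
        design_ids = set(self.sample_ids)
        matrix_ids = set(cm.sample_ids)
        if design_ids != matrix_ids:
            only_design = sorted(design_ids - matrix_ids)
            only_counts = sorted(matrix_ids - design_ids)
            raise ValidationError(
                "sample-id mismatch between design and counts: "
                f"design-only={only_design}, counts-only={only_counts}"
            )

    def summary(self) -> str:
        lines = ["genotype\ttolerance\tcondition\tn_replicates"]
        for (g, tol, cond), sub in self.table.groupby(["genotype", "tolerance", "condition"]):
            lines.append(f"{g}\t{tol}\t{cond}\t{len(sub)}")
        return "\n".join(lines)


def read_design(path) -> StudyDesign:
    """Read and validate a design sheet TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "genotype": str})
    return StudyDesign(df)


def write_design(design: StudyDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GO annotation map
# ---------------------------------------------------------------------------


@dataclass
class GOAnnotationMap:
    """Flat gene → set-of-GO-term annotation (no DAG propagation).

    Genes absent from the map are treated as unannotated, never as errors.
    """

    gene_to_terms: dict[str, set[str]]
    term_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, terms in self.gene_to_terms.items():
            for t in terms:
                if not isinstance(t, str) or not t:
                    raise ValidationError(f"empty GO term id for gene {gene!r}")

    def terms_of(self, gene: str) -> set[str]:
        return self.gene_to_terms.get(gene, set())

    def term_to_genes(self, universe: Iterable[str] | None = None) -> dict[str, set[str]]:
        """Invert the map, optionally restricted to a gene universe."""
        allowed = None if universe is None else set(universe)
        out: dict[str, set[str]] = {}
        for gene, terms in self.gene_to_terms.items():
            if allowed is not None and gene not in allowed:
                continue
            for t in terms:
                out.setdefault(t, set()).add(gene)
        return out

    def label(self, term: str) -> str:
        return self.term_labels.get(term, "")


def read_go_map(path) -> GOAnnotationMap:
    """Read a gene→GO TSV with columns gene_id, go_term[, term_label]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in df.columns or "go_term" not in df.columns:
        raise ValidationError("GO map requires columns gene_id, go_term")
    mapping: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    for row in df.itertuples(index=False):
        mapping.setdefault(row.gene_id, set()).add(row.go_term)
        if hasattr(row, "term_label") and isinstance(row.term_label, str):
            labels[row.go_term] = row.term_label
    return GOAnnotationMap(mapping, labels)


def write_go_map(annot: GOAnnotationMap, path) -> None:
    rows = []
    for gene in sorted(annot.gene_to_terms):
        for term in sorted(annot.gene_to_terms[gene]):
            rows.append((gene, term, annot.term_labels.get(term, "")))
    pd.DataFrame(rows, columns=["gene_id", "go_term", "term_label"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Ct table and phenotype table
# ---------------------------------------------------------------------------


def validate_ct_table(df: pd.DataFrame, reference_gene: str = DEFAULT_REFERENCE_GENE) -> pd.DataFrame:
    """Validate a long-format qPCR Ct table.

    Columns: target_gene, sample_id, technical_replicate, ct. The reference
    gene must be measured in every sample that carries any measurement, and
    all Ct values must be finite positive cycle numbers.
    """
    required = ["target_gene", "sample_id", "technical_replicate", "ct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"Ct table missing columns: {missing}")
    ct = pd.to_numeric(df["ct"], errors="coerce")
    if ct.isna().any() or not np.isfinite(ct).all() or (ct <= 0).any():
        raise ValidationError("Ct values must be finite positive cycle numbers")
    samples = set(df["sample_id"])
    ref_samples = set(df.loc[df["target_gene"] == reference_gene, "sample_id"])
    orphans = sorted(samples - ref_samples)
    if orphans:
        raise ValidationError(
            f"reference gene {reference_gene!r} not measured in samples: {orphans}"
        )
    out = df.copy()
    out["ct"] = ct.astype(float)
    return out


def read_ct_table(path, reference_gene: str = DEFAULT_REFERENCE_GENE) -> pd.DataFrame:
    return validate_ct_table(pd.read_csv(path, sep="\t"), reference_gene)


def validate_phenotype_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a phenotype-means table.

    Columns: cultivar, condition, trait, mean[, stderr]. Every
    (cultivar, trait) pair needs exactly one control and one stress row, and
    means must be positive.
    """
    required = ["cultivar", "condition", "trait", "mean"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"phenotype table missing columns: {missing}")
    t = df.copy()
    t["condition"] = t["condition"].astype(str).str.strip().str.lower()
    bad = t.loc[~t["condition"].isin(CONDITION_LEVELS)]
    if len(bad):
        raise ValidationError(f"unknown condition value {bad.iloc[0]['condition']!r}")
    t["mean"] = pd.to_numeric(t["mean"])
    if (t["mean"] <= 0).any():
        raise ValidationError("phenotype means must be positive")
    counts = t.groupby(["cultivar", "trait", "condition"]).size()
    if (counts != 1).any():
        key = counts[counts != 1].index[0]
        raise ValidationError(f"expected exactly one row for {key}")
    per_pair = t.groupby(["cultivar", "trait"])["condition"].nunique()
    if (per_pair != 2).any():
        key = per_pair[per_pair != 2].index[0]
        raise ValidationError(f"(cultivar, trait) {key} lacks a control/stress pair")
    return t


def read_phenotype_table(path) -> pd.DataFrame:
    return validate_phenotype_table(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# Generic result-table writer
# ---------------------------------------------------------------------------

#: Values below this magnitude are still printed positionally, not in
#: scientific notation (see write_table).
SCIENTIFIC_THRESHOLD = 1e-4


def write_table(records: pd.DataFrame, path, float_precision: int = 6) -> None:
    """Write a result table as TSV with a stable column order.

    Floats use '.' as the decimal separator; scientific notation is used only
    below :data:`SCIENTIFIC_THRESHOLD`. An empty table yields a header-only
    file.
    """

    def _fmt(x):
        if isinstance(x, (float, np.floating)):
            if x != 0 and abs(x) < SCIENTIFIC_THRESHOLD:
                return f"{x:.{float_precision}e}"
            return f"{x:.{float_precision}g}"
        return x

    out = records.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(_fmt)
    out.to_csv(path, sep="\t", index=False)
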