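"""Gene-catalog data model and summaries for an MSY assembly.

Covers the tabular end of the pipeline: catalog aggregation (gene/copy
counts by origin category, copy-number class and expression profile, with
per-Mb densities), the annotation acceptance filter (sequence similarity,
exon recovery, exon order and boundary conservation), cross-species
presence/absence matrices, and a cross-species expression fold-change
comparison on a raw count matrix.

The "significance" of expression differences is deliberately not modelled:
this module reports CPM fold changes with a threshold flag and leaves
formal differential testing to dedicated tools.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "GeneRecord",
    "AnnotationHit",
    "CountMatrix",
    "ComparativeMatrix",
    "CATEGORIES",
    "EXPRESSION_PROFILES",
    "load_catalog",
    "load_packaged_catalog",
    "summarize_catalog",
    "filter_annotation_hits",
    "comparative_matrix",
    "expression_compare",
]

CATEGORIES = (
    "ancestral X-Y",
    "autosomal transposed",
    "Y-born novel",
    "PAR transposed",
    "autosomal transposed to PAB",
)

EXPRESSION_PROFILES = ("broad", "testis-dominant", "limited", "none", "tentative")


@dataclass
class GeneRecord:
    """One catalog entry: a gene/transcript with origin and copy number."""

    gene: str
    category: str
    copy_number: int = 1
    expression: str = "broad"
    intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.gene}: unknown category {self.category!r}")
        if self.expression not in EXPRESSION_PROFILES:
            raise ValueError(f"{self.gene}: unknown expression {self.expression!r}")
        if self.copy_number < 1:
            raise ValueError(f"{self.gene}: copy_number must be >= 1")


def load_catalog(path) -> list[GeneRecord]:
    """Read a TSV catalog (gene, category, copies, expression[, coords])."""
    df = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for row in df.itertuples(index=False):
        intervals = []
        coords = getattr(row, "coords", "")
        if isinstance(coords, str) and coords:
            for part in coords.split(";"):
                a, b = part.split("-")
                intervals.append((int(a), int(b)))
        records.append(GeneRecord(gene=row.gene, category=row.category,
                                  copy_number=int(row.copies),
                                  expression=row.expression, intervals=intervals))
    return records


def load_packaged_catalog() -> list[GeneRecord]:
    """The packaged horse-MSY catalog fixture (partly synthetic).

    Marginal totals (genes and copies per category, single/multi split,
    expression profiles) transcribe the published summary table; gene names
    not printed in the running text are placeholders.  See the file header.
    """
    ref = importlib.resources.files("equimsy.data") / "table1_catalog_synthetic.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_catalog(path)


def _round1(x: float) -> float:
    """Round to one decimal, half away from zero (printed-density convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_catalog(catalog: list[GeneRecord], assembly_length: int) -> dict:
    """Aggregate a gene catalog into summary-table counts and densities.

    Returns a dict with total genes/copies, per-Mb densities (one decimal),
    counts per category split single-copy vs multi-copy (with copy sums),
    and expression-profile counts.
    """
    if not catalog:
        raise ValueError("empty catalog")
    if assembly_length <= 0:
        raise ValueError("assembly_length must be positive")
    total_genes = len(catalog)
    total_copies = sum(g.copy_number for g in catalog)
    mb = assembly_length / 1e6
    by_category = {}
    for cat in CATEGORIES:
        genes = [g for g in catalog if g.category == cat]
        single = [g for g in genes if g.copy_number == 1]
        multi = [g for g in genes if g.copy_number > 1]
        by_category[cat] = {
            "genes": len(genes),
            "single_copy": len(single),
            "multi_copy": len(multi),
            "copies": sum(g.copy_number for g in genes),
            "multi_copy_copies": sum(g.copy_number for g in multi),
            "expression": {
                prof: sum(1 for g in genes if g.expression == prof)
                for prof in EXPRESSION_PROFILES
            },
        }
    return {
        "total_genes": total_genes,
        "total_copies": total_copies,
        "single_copy_genes": sum(1 for g in catalog if g.copy_number == 1),
        "multi_copy_genes": sum(1 for g in catalog if g.copy_number > 1),
        "single_copy_copies": sum(1 for g in catalog if g.copy_number == 1),
        "multi_copy_copies": sum(g.copy_number for g in catalog if g.copy_number > 1),
        "gene_density_per_mb": _round1(total_genes / mb),
        "copy_density_per_mb": _round1(total_copies / mb),
        "by_category": by_category,
        "expression": {
            prof: sum(1 for g in catalog if g.expression == prof)
            for prof in EXPRESSION_PROFILES
        },
    }


@dataclass
class AnnotationHit:
    """A candidate gene-model alignment against the assembly."""

    model: str
    percent_identity: float
    exons_matched: int
    exons_total: int
    exon_order_preserved: bool
    boundaries_conserved: bool

    def __post_init__(self) -> None:
        if not 0 <= self.percent_identity <= 100:
            raise ValueError(f"{self.model}: identity out of [0, 100]")
        if self.exons_total <= 0:
            raise ValueError(f"{self.model}: exons_total must be positive")
        if self.exons_matched > self.exons_total:
            raise ValueError(f"{self.model}: matched > total exons")


def filter_annotation_hits(hits: list[AnnotationHit], min_identity: float = 80.0,
                           min_exon_fraction: float = 0.75,
                           ) -> tuple[list[AnnotationHit], list[tuple[AnnotationHit, list[str]]]]:
    """Partition hits into accepted and rejected-with-reasons.

    Accepted iff identity >= min_identity AND matched/total exons >=
    min_exon_fraction AND exon order preserved AND exon-intron boundaries
    conserved.  Thresholds are inclusive.
    """
    accepted, rejected = [], []
    for h in hits:
        reasons = []
        if h.percent_identity < min_identity:
            reasons.append("sequence similarity")
        if h.exons_matched / h.exons_total < min_exon_fraction:
            reasons.append("exon fraction")
        if not h.exon_order_preserved:
            reasons.append("exon order")
        if not h.boundaries_conserved:
            reasons.append("exon-intron boundaries")
        if reasons:
            rejected.append((h, reasons))
        else:
            accepted.append(h)
    return accepted, rejected


STATUSES = ("present", "pseudogene", "PAR", "absent")


@dataclass
class ComparativeMatrix:
    """Gene x species presence/absence/pseudogene/PAR status matrix."""

    table: pd.DataFrame  # rows: genes, columns: species, values from STATUSES
    union_size: int
    species_specific: list[str]
    universal: list[str]


def comparative_matrix(catalogs: dict[str, dict[str, str]]) -> ComparativeMatrix:
    """Combine per-species gene-status maps into one comparative matrix.

    ``catalogs`` maps species -> {gene -> status}; genes missing from a
    species are "absent".  Species-specific genes are non-absent in exactly
    one species; universal genes are non-absent and non-pseudogene in every
    species.
    """
    if len(catalogs) < 2:
        raise ValueError("need at least 2 species")
    species = sorted(catalogs)
    genes = sorted({g for cat in catalogs.values() for g in cat})
    data = {}
    for sp in species:
        col = []
        for g in genes:
            status = catalogs[sp].get(g, "absent")
            if status not in STATUSES:
                raise ValueError(f"unknown status {status!r} for {g} in {sp}")
            col.append(status)
        data[sp] = col
    table = pd.DataFrame(data, index=genes)
    present = table != "absent"
    specific = [g for g in genes if present.loc[g].sum() == 1]
    universal = [g for g in genes
                 if all(table.loc[g, sp] not in ("absent", "pseudogene") for sp in species)]
    return ComparativeMatrix(table=table, union_size=len(genes),
                             species_specific=specific, universal=universal)


@dataclass
class CountMatrix:
    """Raw gene x sample counts with a sample -> group map."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    groups: dict[str, str]
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.groups)
        if missing:
            raise ValueError(f"ungrouped samples: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        if (self.library_sizes <= 0).any():
            raise ValueError("zero library size")


def _cpm(cm: CountMatrix, pseudocount: float) -> pd.DataFrame:
    n_genes = cm.counts.shape[0]
    denom = cm.library_sizes + pseudocount * n_genes
    return (cm.counts + pseudocount).div(denom, axis=1) * 1e6


def expression_compare(cm: CountMatrix, group_a: str, group_b: str,
                       pseudocount: float = 0.5, fold_flag: float = 4.0,
                       low_cpm: float = 1.0) -> pd.DataFrame:
    """Per-gene CPM fold change between two sample groups.

    CPM = (count + pseudocount) / (library size + pseudocount x genes) x 1e6;
    fold = mean CPM(group_a) / mean CPM(group_b).  Genes with fold >=
    ``fold_flag`` (up in a) or <= 1/fold_flag (down in a relative to b) are
    flagged; genes below ``low_cpm`` in both groups are marked low-expression.
    """
    a_samples = [s for s, g in cm.groups.items() if g == group_a and s in cm.counts.columns]
    b_samples = [s for s, g in cm.groups.items() if g == group_b and s in cm.counts.columns]
    if not a_samples or not b_samples:
        raise ValueError(f"empty group: {group_a if not a_samples else group_b}")
    cpm = _cpm(cm, pseudocount)
    mean_a = cpm[a_samples].mean(axis=1)
    mean_b = cpm[b_samples].mean(axis=1)
    fold = mean_a / mean_b
    out = pd.DataFrame({
        "cpm_a": mean_a,
        "cpm_b": mean_b,
        "fold": fold,
        "direction": np.where(fold >= 1.0, "up", "down"),
        "flagged": (fold >= fold_flag) | (fold <= 1.0 / fold_flag),
        "low_expression": (mean_a < low_cpm) & (mean_b < low_cpm),
    })
    out.index.name = "gene"
    return out
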