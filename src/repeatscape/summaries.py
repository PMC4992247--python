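"""Summary statistics and tables of the repeat landscape.

Per-TE-model copy/coverage tables, SSR tables, coverage arithmetic with
inclusion-exclusion, genomic-context partitions of TE bases (exon / genic /
intergenic and element / 3-kbp flank / rest), per-chromosome copy densities,
and two sizing formulas used when calibrating an annotation campaign:

* k-mer (oligo) sizing for repeat-counting tools: ``l = log4(N) + 1``,
  rounded to the nearest integer (16 for a ~1 Gbp genome);
* C-value to bp: 1 pg of haploid DNA is 0.978e9 bp.

Printed tables round half-up to the precision of each column; the machine
output always keeps full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Mapping, Sequence, Tuple

import pandas as pd

from .annotation_algebra import (
    AnnotationSet,
    Feature,
    intersect,
    merge_intervals,
    subtract,
    union_coverage,
    long_join_copies,
)

PG_TO_BP = 0.978e9  # base pairs per picogram of haploid DNA


def round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# sizing formulas
# ---------------------------------------------------------------------------

def kmer_size(genome_length: int) -> int:
    """Oligo size for repeat-counting tools: round(log4(N) + 1)."""
    if genome_length < 1:
        raise ValueError("genome_length must be positive")
    return int(round_half_up(math.log(genome_length, 4) + 1, 0))


def cvalue_to_bp(pg: float) -> float:
    """Convert a C-value in picograms to base pairs (0.978e9 bp/pg)."""
    if pg < 0:
        raise ValueError("C-value cannot be negative")
    return pg * PG_TO_BP


# ---------------------------------------------------------------------------
# coverage arithmetic
# ---------------------------------------------------------------------------

def fold_change(a: float, b: float, ndigits: int = 2) -> float:
    """Ratio a/b, rounded half-up (the 'increase factor' of coverage
    comparisons)."""
    if b == 0:
        raise ZeroDivisionError("fold_change denominator is zero")
    return round_half_up(a / b, ndigits)


def coverage_union(
    components: Mapping[str, float],
    overlaps: Mapping[Tuple[str, ...], float] | None = None,
) -> float:
    """Inclusion-exclusion over named coverage components.

    ``overlaps`` maps tuples of component names to the coverage of their
    intersection; even-order terms are subtracted, odd-order terms added
    back.  With full annotation sets use
    :func:`repeatscape.annotation_algebra.venn_coverage` instead -- the two
    paths agree on every fixture.
    """
    total = sum(components.values())
    for names, value in (overlaps or {}).items():
        k = len(names)
        if k < 2:
            raise ValueError("overlap keys need at least two component names")
        total += value * (-1) ** (k - 1)
    return total


# ---------------------------------------------------------------------------
# per-model table
# ---------------------------------------------------------------------------

@dataclass
class ModelSummary:
    model: str
    te_type: str
    n_consensuses: int
    n_copies: int
    percent_of_copies: float
    percent_coverage: float


def model_table(
    copy_table: pd.DataFrame,
    genome_size: int,
    te_types: Mapping[str, str] | None = None,
    n_consensuses: Mapping[str, int] | None = None,
) -> List[ModelSummary]:
    """Per-model copy counts and coverages from a long-join copy table.

    percent_of_copies = 100 * n_copies / total copies;
    percent_coverage = 100 * summed copy bases / genome size.
    """
    if copy_table.empty:
        return []
    grouped = copy_table.groupby("model").agg(
        n_copies=("copy_id", "count"), bases=("copy_length", "sum")
    )
    total = grouped["n_copies"].sum()
    out = []
    for model, row in grouped.iterrows():
        out.append(
            ModelSummary(
                model=model,
                te_type=(te_types or {}).get(model, "undetermined"),
                n_consensuses=(n_consensuses or {}).get(model, 1),
                n_copies=int(row["n_copies"]),
                percent_of_copies=100.0 * row["n_copies"] / total,
                percent_coverage=100.0 * row["bases"] / genome_size,
            )
        )
    out.sort(key=lambda m: m.model)
    return out


def model_table_frame(summaries: Sequence[ModelSummary]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "model": m.model,
                "te_type": m.te_type,
                "n_consensuses": m.n_consensuses,
                "n_copies": m.n_copies,
                "percent_of_copies": round_half_up(m.percent_of_copies, 4),
                "percent_coverage": round_half_up(m.percent_coverage, 4),
            }
            for m in summaries
        ]
    )
    return df


def percent_of_copies(n_copies: int, total_copies: int) -> float:
    """Share of one model among all copies, in percent (full precision)."""
    return 100.0 * n_copies / total_copies


# ---------------------------------------------------------------------------
# SSR table
# ---------------------------------------------------------------------------

def ssr_table(arrays, genome_size: int) -> pd.DataFrame:
    """Per-SSR-class array counts, distinct-unit counts (exact dedup) and
    coverage percent."""
    from . import ssr_typing

    rows = []
    for cls in ssr_typing.CLASSES:
        sub = [a for a in arrays if a.ssr_class == cls]
        ivs_per_seq: Dict[str, list] = {}
        for a in sub:
            ivs_per_seq.setdefault(a.seqid, []).append((a.start - 1, a.end))
        bases = sum(
            e - s for ivs in ivs_per_seq.values() for s, e in merge_intervals(ivs)
        )
        rows.append(
            {
                "ssr_type": cls,
                "n_arrays": len(sub),
                "n_distinct_units": ssr_typing.dedupe_units(sub) if sub else 0,
                "percent_coverage": 100.0 * bases / genome_size,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genomic context partitions
# ---------------------------------------------------------------------------

@dataclass
class ContextPartition:
    """TE base counts partitioned by genomic context (two schemes)."""

    gene_scheme: Dict[str, int] = field(default_factory=dict)   # exon/genic/intergenic
    element_scheme: Dict[str, int] = field(default_factory=dict)  # inside/flank/rest
    total_bases: int = 0


def _flank_set(elements: AnnotationSet, flank: int) -> AnnotationSet:
    """3-kbp proximal+distal flanks, clipped at chromosome ends and at the
    element itself."""
    feats = []
    for f in elements:
        L = elements.genome[f.seqid]
        left_s = max(1, f.start - flank)
        if left_s < f.start:
            feats.append(Feature(f.seqid, "flank", "flank", left_s, f.start - 1))
        right_e = min(L, f.end + flank)
        if right_e > f.end:
            feats.append(Feature(f.seqid, "flank", "flank", f.end + 1, right_e))
    flanks = AnnotationSet(feats, elements.genome)
    return subtract(flanks, elements)


def context_partition(
    te_annotations: AnnotationSet,
    gene_annotations: AnnotationSet,
    context_elements: AnnotationSet,
    flank: int = 3000,
) -> ContextPartition:
    """Assign every annotated TE base to exactly one bin per scheme.

    Gene scheme, priority exon > genic > intergenic (genic = gene span minus
    exons); element scheme, priority inside element > 3-kbp flank > rest.
    Bins partition the TE bases exactly.
    """
    genome_size = te_annotations.genome_size()
    total = int(round(union_coverage(te_annotations) * genome_size))

    exons = AnnotationSet(
        [f for f in gene_annotations if f.feature_type == "exon"],
        gene_annotations.genome,
    )
    genes = AnnotationSet(
        [f for f in gene_annotations if f.feature_type == "gene"],
        gene_annotations.genome,
    )
    exonic = int(round(union_coverage(intersect(te_annotations, exons)) * genome_size))
    in_gene = int(round(union_coverage(intersect(te_annotations, genes)) * genome_size))
    genic = in_gene - exonic
    gene_scheme = {
        "exon": exonic,
        "genic": genic,
        "intergenic": total - in_gene,
    }

    inside = int(
        round(union_coverage(intersect(te_annotations, context_elements)) * genome_size)
    )
    flanks = _flank_set(context_elements, flank)
    in_flank = int(round(union_coverage(intersect(te_annotations, flanks)) * genome_size))
    element_scheme = {
        "inside": inside,
        "flank": in_flank,
        "rest": total - inside - in_flank,
    }
    return ContextPartition(gene_scheme, element_scheme, total)


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def density(
    aset: AnnotationSet,
    chrom_sizes: Mapping[str, int],
    max_nested_span: int = 50000,
) -> pd.DataFrame:
    """Copies per Mbp per chromosome; long-joined fragment pairs count once."""
    copies = long_join_copies(aset, max_nested_span=max_nested_span)
    rows = []
    for chrom, size in chrom_sizes.items():
        n = 0 if copies.empty else int((copies["seqid"] == chrom).sum())
        rows.append(
            {
                "seqid": chrom,
                "n_copies": n,
                "size_bp": size,
                "copies_per_mbp": n / (size / 1e6),
            }
        )
    return pd.DataFrame(rows)
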