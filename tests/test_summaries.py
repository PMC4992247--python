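"""Summary tables, sizing formulas, context partitions, densities."""

import numpy as np
import pandas as pd
import pytest

from conftest import bitmap, random_annotation_set
from repeatscape import annotation_algebra as alg
from repeatscape import summaries as sm
from repeatscape.annotation_algebra import AnnotationSet, Feature


def F(seqid, start, end, ftype="te", **attrs):
    return Feature(seqid=seqid, feature_type=ftype, start=start, end=end,
                   attributes={k: str(v) for k, v in attrs.items()})


# ---------------------------------------------------------------------------
# sizing formulas
# ---------------------------------------------------------------------------

def test_kmer_size_for_gbp_scale_genome():
    assert sm.kmer_size(1_047_000_000) == 16


def test_kmer_size_small_and_monotone():
    assert sm.kmer_size(4) == 2  # log4(4) + 1
    values = [sm.kmer_size(n) for n in np.logspace(2, 10, 60).astype(int)]
    assert values == sorted(values)


def test_cvalue_conversion():
    assert sm.cvalue_to_bp(1.25) / 1e9 == pytest.approx(1.2225)
    assert sm.round_half_up(sm.cvalue_to_bp(1.25) / 1e9, 3) == 1.223
    assert sm.cvalue_to_bp(0) == 0
    assert sm.cvalue_to_bp(2.5) == 2 * sm.cvalue_to_bp(1.25)


# ---------------------------------------------------------------------------
# coverage arithmetic
# ---------------------------------------------------------------------------

def test_fold_change():
    assert sm.fold_change(4.08, 1.73) == 2.36
    assert sm.fold_change(3.73, 1.54) == 2.42
    assert sm.fold_change(18.78, 11.47) == 1.64
    assert sm.fold_change(5.0, 5.0) == 1.0
    with pytest.raises(ZeroDivisionError):
        sm.fold_change(1.0, 0.0)


def test_coverage_union_inclusion_exclusion():
    assert sm.coverage_union(
        {"ssr": 4.08, "te_dm": 15.7}, {("ssr", "te_dm"): 1.0}
    ) == pytest.approx(18.78)
    # disjoint components: plain sum
    assert sm.coverage_union({"a": 1.0, "b": 2.0}) == pytest.approx(3.0)


def test_coverage_union_formula_matches_set_path(rng, toy_genome):
    """The inclusion-exclusion arithmetic agrees with the interval path."""
    for _ in range(10):
        a = random_annotation_set(rng, toy_genome, 80)
        b = random_annotation_set(rng, toy_genome, 80)
        formula = sm.coverage_union(
            {"a": alg.union_coverage(a), "b": alg.union_coverage(b)},
            {("a", "b"): alg.union_coverage(alg.intersect(a, b))},
        )
        assert formula == pytest.approx(alg.union_coverage(a, b), abs=1e-12)


# ---------------------------------------------------------------------------
# model table
# ---------------------------------------------------------------------------

def make_copy_table(rows):
    return pd.DataFrame(
        [
            {"copy_id": i + 1, "model": m, "seqid": "chr1",
             "n_fragments": 1, "copy_length": ln, "start": 1, "end": ln}
            for i, (m, ln) in enumerate(rows)
        ]
    )


def test_model_table_percentages():
    rows = [("CR1", 100)] * 3 + [("Kronos", 50)] * 1
    table = sm.model_table(make_copy_table(rows), genome_size=10000)
    by_model = {m.model: m for m in table}
    assert by_model["CR1"].percent_of_copies == pytest.approx(75.0)
    assert by_model["Kronos"].percent_of_copies == pytest.approx(25.0)
    assert by_model["CR1"].percent_coverage == pytest.approx(3.0)
    assert sum(m.percent_of_copies for m in table) == pytest.approx(100.0)


def test_single_model_is_100_percent():
    table = sm.model_table(make_copy_table([("Solo", 10)]), genome_size=100)
    assert table[0].percent_of_copies == 100.0


def test_percent_of_copies_full_precision():
    assert sm.round_half_up(sm.percent_of_copies(413857, 622616), 4) == 66.4707
    assert sm.round_half_up(sm.percent_of_copies(67691, 622616), 3) == 10.872


# ---------------------------------------------------------------------------
# context partition
# ---------------------------------------------------------------------------

def context_fixture(toy_genome):
    genes = AnnotationSet(
        [
            F("chr1", 1001, 3000, "gene"),
            F("chr1", 1001, 1400, "exon"),
            F("chr1", 2601, 3000, "exon"),
        ],
        toy_genome,
    )
    elements = AnnotationSet([F("chr1", 5001, 5400, "CpG_island")], toy_genome)
    return genes, elements


def test_te_wholly_in_exon(toy_genome):
    genes, elements = context_fixture(toy_genome)
    tes = AnnotationSet([F("chr1", 1100, 1199)], toy_genome)
    part = sm.context_partition(tes, genes, elements)
    assert part.gene_scheme == {"exon": 100, "genic": 0, "intergenic": 0}
    assert part.total_bases == 100


def test_te_straddling_gene_boundary_split(toy_genome):
    genes, elements = context_fixture(toy_genome)
    tes = AnnotationSet([F("chr1", 2901, 3100)], toy_genome)
    part = sm.context_partition(tes, genes, elements)
    assert part.gene_scheme == {"exon": 100, "genic": 0, "intergenic": 100}


def test_flank_scheme_bins(toy_genome):
    genes, elements = context_fixture(toy_genome)
    tes = AnnotationSet(
        [F("chr1", 5101, 5200),   # inside the element
         F("chr1", 5501, 5600),   # within the 3-kb flank
         F("chr2", 1, 100)],      # rest
        toy_genome,
    )
    part = sm.context_partition(tes, genes, elements)
    assert part.element_scheme == {"inside": 100, "flank": 100, "rest": 100}


def test_context_bins_partition_te_bases_exactly(rng, toy_genome):
    """Both schemes sum to the total annotated TE bases on random fixtures."""
    for _ in range(10):
        tes = random_annotation_set(rng, toy_genome, 60)
        genes_raw = random_annotation_set(rng, toy_genome, 10, max_len=2000)
        gene_feats = []
        for i, g in enumerate(genes_raw):
            gene_feats.append(F(g.seqid, g.start, g.end, "gene"))
            mid = (g.start + g.end) // 2
            gene_feats.append(F(g.seqid, g.start, mid, "exon"))
        genes = AnnotationSet(gene_feats, toy_genome)
        elements = random_annotation_set(rng, toy_genome, 8, max_len=600)
        part = sm.context_partition(tes, genes, elements)
        total = int(round(alg.union_coverage(tes) * sum(toy_genome.values())))
        assert sum(part.gene_scheme.values()) == total
        assert sum(part.element_scheme.values()) == total
        # exon bin agrees with the bitmap oracle
        te_bits = bitmap(tes)
        exon_bits = bitmap(AnnotationSet(
            [f for f in genes if f.feature_type == "exon"], toy_genome))
        exon_bases = sum(
            int((te_bits[s] & exon_bits[s]).sum()) for s in toy_genome
        )
        assert part.gene_scheme["exon"] == exon_bases


# ---------------------------------------------------------------------------
# densities and SSR table
# ---------------------------------------------------------------------------

def test_density_counts_long_joined_copies_once():
    genome = {"chr1": 10_000_000}
    host1 = F("chr1", 1000, 1499, model="Host")
    guest = F("chr1", 1500, 2499, model="Guest")
    host2 = F("chr1", 2500, 2999, model="Host")
    lone = F("chr1", 50000, 50999, model="Host")
    aset = AnnotationSet([host1, guest, host2, lone], genome)
    df = sm.density(aset, genome)
    assert int(df.iloc[0].n_copies) == 3  # joined host + guest + lone
    assert df.iloc[0].copies_per_mbp == pytest.approx(0.3)


def test_ssr_table_counts_and_coverage():
    from repeatscape import ssr_typing as st

    arrays = [
        st.TandemArray("chr1", 1, 100, 2, 50, "AC"),
        st.TandemArray("chr1", 201, 300, 2, 50, "AC"),
        st.TandemArray("chr1", 401, 500, 2, 50, "AG"),
    ]
    st.classify_all(arrays)
    df = sm.ssr_table(arrays, genome_size=10000)
    micro = df[df.ssr_type == st.MICROSATELLITE].iloc[0]
    assert micro.n_arrays == 3
    assert micro.n_distinct_units == 2
    assert micro.percent_coverage == pytest.approx(3.0)
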