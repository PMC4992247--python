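"""Interval algebra against per-base bitmap and brute-force oracles."""

import itertools
import subprocess

import numpy as np
import pytest

from conftest import (
    bitmap,
    bitmap_coverage,
    bitmap_intersect,
    bitmap_subtract,
    random_annotation_set,
    set_to_bitmap_equal,
)
from repeatscape import annotation_algebra as alg
from repeatscape.annotation_algebra import AnnotationSet, Feature


def F(seqid, start, end, **attrs):
    return Feature(seqid=seqid, feature_type="te", start=start, end=end,
                   attributes={k: str(v) for k, v in attrs.items()})


# ---------------------------------------------------------------------------
# set operations vs bitmap oracle
# ---------------------------------------------------------------------------

def test_set_operations_match_bitmap_oracle_on_random_fixtures(rng, toy_genome):
    for _ in range(30):
        a = random_annotation_set(rng, toy_genome, int(rng.integers(1, 200)))
        b = random_annotation_set(rng, toy_genome, int(rng.integers(1, 200)))
        assert alg.union_coverage(a) == pytest.approx(bitmap_coverage(a))
        assert set_to_bitmap_equal(alg.intersect(a, b), bitmap_intersect(a, b))
        assert set_to_bitmap_equal(alg.subtract(a, b), bitmap_subtract(a, b))


def test_self_operations(rng, toy_genome):
    a = random_annotation_set(rng, toy_genome, 50)
    assert len(alg.subtract(a, a)) == 0
    assert set_to_bitmap_equal(alg.intersect(a, a), bitmap(a))


def test_coverage_conservation(rng, toy_genome):
    """coverage(A) = coverage(A∩B) + coverage(A∖B)."""
    for _ in range(10):
        a = random_annotation_set(rng, toy_genome, 100)
        b = random_annotation_set(rng, toy_genome, 100)
        ca = alg.union_coverage(a)
        ci = alg.union_coverage(alg.intersect(a, b))
        cs = alg.union_coverage(alg.subtract(a, b))
        assert ca == pytest.approx(ci + cs, abs=1e-12)


def test_empty_set_coverage_and_unregistered_seqid(toy_genome):
    assert alg.union_coverage(AnnotationSet([], toy_genome)) == 0.0
    bad = AnnotationSet([F("chrX", 1, 10)], toy_genome)
    with pytest.raises(KeyError):
        alg.intersect(bad, AnnotationSet([], toy_genome))


def test_venn_regions_disjoint_and_sum_to_union(rng, toy_genome):
    for _ in range(10):
        named = {
            name: random_annotation_set(rng, toy_genome, 80)
            for name in ("A", "B", "C")
        }
        venn = alg.venn_coverage(named)
        union = alg.union_coverage(*named.values())
        assert sum(venn.values()) == pytest.approx(union, abs=1e-12)
        # each region checked against the bitmap oracle
        bits = {n: bitmap(s) for n, s in named.items()}
        total = sum(toy_genome.values())
        for members, cov in venn.items():
            expect = 0
            for seqid, L in toy_genome.items():
                mask = np.ones(L, dtype=bool)
                for n in named:
                    if n in members:
                        mask &= bits[n][seqid]
                    else:
                        mask &= ~bits[n][seqid]
                expect += int(mask.sum())
            assert cov == pytest.approx(expect / total, abs=1e-12)


def test_venn_two_disjoint_sets(toy_genome):
    a = AnnotationSet([F("chr1", 1, 100)], toy_genome)
    b = AnnotationSet([F("chr1", 201, 300)], toy_genome)
    venn = alg.venn_coverage({"a": a, "b": b})
    assert set(venn) == {frozenset({"a"}), frozenset({"b"})}
    self_venn = alg.venn_coverage({"x": a, "y": a})
    assert set(self_venn) == {frozenset({"x", "y"})}


def test_operations_order_independent(rng, toy_genome):
    a = random_annotation_set(rng, toy_genome, 120, attrs=True)
    shuffled = list(a)
    rng.shuffle(shuffled)
    b = AnnotationSet(shuffled, toy_genome)
    for op in (alg.resolve_stacks, alg.merge_juxtaposed,
               lambda s: alg.filter_min_length(s, 50)):
        ra, rb = op(a), op(b)
        assert sorted((f.seqid, f.start, f.end) for f in ra) == sorted(
            (f.seqid, f.start, f.end) for f in rb
        )


# ---------------------------------------------------------------------------
# stack resolution vs brute-force priority oracle
# ---------------------------------------------------------------------------

def brute_force_resolve(feats):
    """Independent enumeration: repeatedly keep the priority-best feature of
    the pool and discard everything (same model) overlapping it."""
    def priority(f):
        ident = float(f.attributes.get("identity", 0))
        cov = float(f.attributes.get("consensus_coverage", 0))
        return (-ident, -cov, -(f.end - f.start + 1), f.attributes.get("consensus", ""))

    pool = sorted(feats, key=priority)
    kept = []
    while pool:
        best = pool.pop(0)
        kept.append(best)
        pool = [
            f for f in pool
            if f.attributes.get("model") != best.attributes.get("model")
            or f.seqid != best.seqid
            or f.end < best.start or f.start > best.end
        ]
    return sorted((f.seqid, f.start, f.end) for f in kept)


def test_resolve_keeps_highest_identity(toy_genome):
    a = F("chr1", 100, 200, model="M", identity=85, consensus="x")
    b = F("chr1", 100, 200, model="M", identity=70, consensus="y")
    out = alg.resolve_stacks(AnnotationSet([a, b], toy_genome))
    assert len(out) == 1 and out.features[0].get("identity") == "85"


def test_resolve_single_feature_unchanged(toy_genome):
    a = F("chr1", 10, 50, model="M", identity=50)
    out = alg.resolve_stacks(AnnotationSet([a], toy_genome))
    assert [(f.start, f.end) for f in out] == [(10, 50)]


def test_resolve_different_models_keep_overlaps(toy_genome):
    a = F("chr1", 100, 200, model="M1", identity=90)
    b = F("chr1", 150, 250, model="M2", identity=50)
    out = alg.resolve_stacks(AnnotationSet([a, b], toy_genome))
    assert len(out) == 2


def test_resolve_matches_bruteforce_on_random_stacks(rng, toy_genome):
    for _ in range(60):
        n = int(rng.integers(1, 7))
        feats = []
        for _ in range(n):
            s = int(rng.integers(1, 400))
            e = s + int(rng.integers(10, 200))
            feats.append(
                F("chr1", s, e,
                  model=f"M{rng.integers(0, 2)}",
                  identity=f"{rng.uniform(0.4, 1.0):.4f}",
                  consensus_coverage=f"{rng.uniform(0.1, 1.0):.4f}",
                  consensus=f"c{rng.integers(0, 4)}")
            )
        out = alg.resolve_stacks(AnnotationSet(feats, toy_genome))
        assert sorted((f.seqid, f.start, f.end) for f in out) == brute_force_resolve(feats)


def test_resolve_output_has_no_same_model_overlaps(rng, toy_genome):
    a = random_annotation_set(rng, toy_genome, 150, attrs=True)
    out = alg.resolve_stacks(a)
    by_key = {}
    for f in out:
        by_key.setdefault((f.seqid, f.get("model")), []).append(f)
    for feats in by_key.values():
        feats.sort(key=lambda f: f.start)
        for f1, f2 in zip(feats, feats[1:]):
            assert f1.end < f2.start


def test_resolve_idempotent(rng, toy_genome):
    a = random_annotation_set(rng, toy_genome, 100, attrs=True)
    once = alg.resolve_stacks(a)
    twice = alg.resolve_stacks(once)
    assert [(f.seqid, f.start, f.end) for f in once] == [
        (f.seqid, f.start, f.end) for f in twice
    ]


# ---------------------------------------------------------------------------
# juxtaposition merging
# ---------------------------------------------------------------------------

def test_merge_bookended_same_model(toy_genome):
    a = F("chr1", 100, 199, model="M", consensus="c1")
    b = F("chr1", 200, 299, model="M", consensus="c2")
    out = alg.merge_juxtaposed(AnnotationSet([a, b], toy_genome))
    assert [(f.start, f.end) for f in out] == [(100, 299)]
    assert out.features[0].get("consensus") == "c1,c2"


def test_merge_never_joins_different_models(toy_genome):
    a = F("chr1", 100, 199, model="M1")
    b = F("chr1", 200, 299, model="M2")
    out = alg.merge_juxtaposed(AnnotationSet([a, b], toy_genome))
    assert len(out) == 2


def test_merge_respects_gap(toy_genome):
    a = F("chr1", 100, 199, model="M")
    b = F("chr1", 205, 299, model="M")
    assert len(alg.merge_juxtaposed(AnnotationSet([a, b], toy_genome), max_gap=0)) == 2
    assert len(alg.merge_juxtaposed(AnnotationSet([a, b], toy_genome), max_gap=5)) == 1


def test_chain_collapses_regardless_of_order(rng, toy_genome):
    chain = [F("chr1", 100 * i + 1, 100 * (i + 1), model="M", consensus=f"c{i}")
             for i in range(5)]
    for perm in itertools.permutations(chain):
        out = alg.merge_juxtaposed(AnnotationSet(list(perm), toy_genome))
        assert [(f.start, f.end) for f in out] == [(1, 500)]


def test_merge_idempotent(rng, toy_genome):
    a = random_annotation_set(rng, toy_genome, 150, attrs=True)
    once = alg.merge_juxtaposed(a)
    twice = alg.merge_juxtaposed(once)
    assert [(f.seqid, f.start, f.end) for f in once] == [
        (f.seqid, f.start, f.end) for f in twice
    ]


# ---------------------------------------------------------------------------
# long-join copy counting
# ---------------------------------------------------------------------------

def test_long_join_nested_scenario(toy_genome):
    host1 = F("chr1", 1000, 1499, model="Host")
    guest = F("chr1", 1500, 2499, model="Guest")
    host2 = F("chr1", 2500, 2999, model="Host")
    table = alg.long_join_copies(AnnotationSet([host1, guest, host2], toy_genome))
    host_rows = table[table.model == "Host"]
    assert len(host_rows) == 1
    assert int(host_rows.iloc[0].n_fragments) == 2
    assert int(host_rows.iloc[0].copy_length) == 1000
    assert len(table[table.model == "Guest"]) == 1


def test_long_join_without_guest_counts_two(toy_genome):
    host1 = F("chr1", 1000, 1499, model="Host")
    host2 = F("chr1", 2500, 2999, model="Host")
    table = alg.long_join_copies(AnnotationSet([host1, host2], toy_genome))
    assert len(table[table.model == "Host"]) == 2


def test_long_join_respects_span_limit(toy_genome):
    host1 = F("chr1", 100, 199, model="Host")
    guest = F("chr1", 200, 4999, model="Guest")
    host2 = F("chr1", 5000, 5099, model="Host")
    near = alg.long_join_copies(
        AnnotationSet([host1, guest, host2], toy_genome), max_nested_span=10000
    )
    far = alg.long_join_copies(
        AnnotationSet([host1, guest, host2], toy_genome), max_nested_span=1000
    )
    assert len(near[near.model == "Host"]) == 1
    assert len(far[far.model == "Host"]) == 2


# ---------------------------------------------------------------------------
# length filter
# ---------------------------------------------------------------------------

def test_min_length_boundary(toy_genome):
    short = F("chr1", 1, 19)
    exact = F("chr1", 100, 119)
    out = alg.filter_min_length(AnnotationSet([short, exact], toy_genome), 20)
    assert [(f.start, f.end) for f in out] == [(100, 119)]
    assert len(alg.filter_min_length(AnnotationSet([], toy_genome))) == 0


def test_min_length_removal_count_matches_bruteforce(rng, toy_genome):
    a = random_annotation_set(rng, toy_genome, 200, max_len=60)
    out = alg.filter_min_length(a, 30)
    assert len(a) - len(out) == sum(1 for f in a if f.length < 30)


# ---------------------------------------------------------------------------
# independent cross-check against bedtools
# ---------------------------------------------------------------------------

def test_intersect_subtract_agree_with_bedtools(tmp_path, rng, toy_genome):
    """Tiny-fixture cross-check of base-level semantics against bedtools."""
    from repeatscape import io as rio

    a = random_annotation_set(rng, toy_genome, 40, max_len=300)
    b = random_annotation_set(rng, toy_genome, 40, max_len=300)
    fa, fb = tmp_path / "a.bed", tmp_path / "b.bed"
    rio.write_bed(a, fa)
    rio.write_bed(b, fb)

    def bedtools(op):
        res = subprocess.run(
            ["bedtools", op, "-a", str(fa), "-b", str(fb)],
            capture_output=True, text=True, check=True,
        )
        ivs = {}
        for line in res.stdout.splitlines():
            c, s, e = line.split("\t")[:3]
            ivs.setdefault(c, []).append((int(s), int(e)))
        return {c: alg.merge_intervals(v) for c, v in ivs.items()}

    mine_i = {s: alg.merge_intervals([f.iv for f in feats])
              for s, feats in alg.intersect(a, b).by_seqid().items() if feats}
    mine_s = {s: alg.merge_intervals([f.iv for f in feats])
              for s, feats in alg.subtract(a, b).by_seqid().items() if feats}
    assert mine_i == bedtools("intersect")
    assert mine_s == bedtools("subtract")
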