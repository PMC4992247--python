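"""Dark-matter mining: probe selection, homology scan, subtraction."""

import numpy as np
import pytest

from conftest import bitmap
from repeatscape import dm_mining as dm
from repeatscape import synthetic_genome as sg
from repeatscape.annotation_algebra import AnnotationSet, Feature, union_coverage


def F(seqid, start, end, **attrs):
    return Feature(seqid=seqid, feature_type="te", start=start, end=end,
                   attributes={k: str(v) for k, v in attrs.items()})


@pytest.fixture(scope="module")
def consensus():
    return sg.random_sequence(np.random.default_rng(31), 700)


# ---------------------------------------------------------------------------
# probe selection
# ---------------------------------------------------------------------------

def test_probe_length_strictly_greater_and_identity_nonstrict():
    genome = {"chr1": "A" * 3000}
    feats = [
        F("chr1", 1, 500, model="M", identity=0.90),    # 500 bp: excluded
        F("chr1", 601, 1101, model="M", identity=0.90),  # 501 bp: included
        F("chr1", 1201, 1901, model="M", identity=0.79),  # identity too low
        F("chr1", 2001, 2701, model="M", identity=0.80),  # boundary: included
    ]
    aset = AnnotationSet(feats, {"chr1": 3000})
    probes = dm.select_probes(aset, genome)
    assert [(p.start, p.end) for p in probes] == [(601, 1101), (2001, 2701)]


def test_probe_without_identity_excluded():
    genome = {"chr1": "A" * 2000}
    aset = AnnotationSet([F("chr1", 1, 1000, model="M")], {"chr1": 2000})
    assert dm.select_probes(aset, genome) == []


def test_probe_selection_equals_bruteforce_filter(consensus):
    spec = sg.RepeatModelSpec("TeA", "LINE", consensus, 30, (0.0, 0.4),
                              truncation_prob=0.5)
    gt = sg.generate_genome([200000], [spec], seed=41)
    probes = dm.select_probes(gt.truth, gt.sequences)
    expected = [
        f for f in gt.truth
        if f.length > 500 and float(f.get("identity")) >= 0.80
    ]
    assert len(probes) == len(expected)
    assert {(p.start, p.end) for p in probes} == {(f.start, f.end) for f in expected}


# ---------------------------------------------------------------------------
# homology scan
# ---------------------------------------------------------------------------

def test_verbatim_probe_recovered_exactly(consensus):
    rng = np.random.default_rng(5)
    background = sg.random_sequence(rng, 5000)
    genome = {"chr1": background[:2000] + consensus + background[2000:]}
    probe = dm.ProbeCopy("M", "cons", consensus, 1.0)
    hits = dm.homology_scan([probe], genome)
    exact = [f for f in hits if f.start == 2001 and f.end == 2000 + len(consensus)]
    assert exact and exact[0].get("identity") == "1.0000"
    assert exact[0].strand == "+"


def test_reverse_complement_plant_found_on_minus_strand(consensus):
    rng = np.random.default_rng(6)
    background = sg.random_sequence(rng, 4000)
    rc = sg.reverse_complement(consensus)
    genome = {"chr1": background[:1500] + rc + background[1500:]}
    probe = dm.ProbeCopy("M", "cons", consensus, 1.0)
    hits = dm.homology_scan([probe], genome)
    exact = [f for f in hits if f.start == 1501 and f.end == 1500 + len(rc)]
    assert exact and exact[0].strand == "-"


def test_zero_hits_is_valid():
    genome = {"chr1": "AT" * 2000}
    probe = dm.ProbeCopy("M", "cons", "GC" * 100, 1.0)
    hits = dm.homology_scan([probe], genome, min_hit_identity=0.95, min_hit_len=100)
    assert len(hits) == 0


def test_divergent_plants_recovered_with_high_recall(consensus):
    """>=90% of planted bases recovered at 15% divergence, identity floor 0.6."""
    conserved = sg.RepeatModelSpec("TeA", "LINE", consensus, 5, (0.0, 0.01))
    diverged = sg.RepeatModelSpec("TeA_old", "LINE", consensus, 60, (0.15, 0.15))
    gt = sg.generate_genome([400000], [conserved, diverged], seed=51)
    probe_feats = AnnotationSet(
        [f for f in gt.truth if f.get("model") == "TeA"], gt.genome
    )
    probes = dm.select_probes(probe_feats, gt.sequences)
    assert probes
    hits = dm.homology_scan(probes, gt.sequences, min_hit_identity=0.6)
    hit_bits = bitmap(hits)
    planted = [f for f in gt.truth if f.get("model") == "TeA_old"]
    planted_bases = sum(f.length for f in planted)
    recovered = sum(
        int(hit_bits[f.seqid][f.start - 1 : f.end].sum()) for f in planted
    )
    assert recovered / planted_bases >= 0.90


def test_recall_monotone_in_identity_threshold(consensus):
    diverged = sg.RepeatModelSpec("TeA", "LINE", consensus, 20, (0.2, 0.2))
    gt = sg.generate_genome([150000], [diverged], seed=52)
    probe = dm.ProbeCopy("TeA", "cons", consensus, 1.0)
    planted = list(gt.truth)
    recovered = []
    for thr in (0.9, 0.7, 0.5):
        hits = dm.homology_scan([probe], gt.sequences, min_hit_identity=thr)
        bits = bitmap(hits)
        recovered.append(
            sum(int(bits[f.seqid][f.start - 1 : f.end].sum()) for f in planted)
        )
    assert recovered == sorted(recovered)


# ---------------------------------------------------------------------------
# subtraction and classification
# ---------------------------------------------------------------------------

def test_subtract_known_gives_zero_base_overlap(rng, toy_genome):
    from conftest import random_annotation_set

    hits = random_annotation_set(rng, toy_genome, 80)
    known = random_annotation_set(rng, toy_genome, 80)
    out = dm.subtract_known(hits, known)
    out_bits = bitmap(out)
    known_bits = bitmap(known)
    for s in toy_genome:
        assert not (out_bits[s] & known_bits[s]).any()


def test_subtract_fully_contained_hits_vanish(toy_genome):
    hits = AnnotationSet([F("chr1", 100, 200, model="M")], toy_genome)
    known = AnnotationSet([F("chr1", 50, 300)], toy_genome)
    assert len(dm.subtract_known(hits, known)) == 0
    disjoint = AnnotationSet([F("chr1", 400, 500, model="M")], toy_genome)
    out = dm.subtract_known(disjoint, known)
    assert [(f.start, f.end) for f in out] == [(400, 500)]


def test_coverage_additivity_after_subtraction(rng, toy_genome):
    from conftest import random_annotation_set
    from repeatscape.annotation_algebra import AnnotationSet as AS

    hits = random_annotation_set(rng, toy_genome, 60)
    known = random_annotation_set(rng, toy_genome, 60)
    dm_set = dm.subtract_known(hits, known)
    both = AS(list(known) + list(dm_set), toy_genome)
    assert union_coverage(both) == pytest.approx(
        union_coverage(known) + union_coverage(dm_set), abs=1e-12
    )


def test_classify_dm_adjacent_vs_distant(toy_genome):
    existing = AnnotationSet([F("chr1", 1000, 1999, model="M")], toy_genome)
    abutting = F("chr1", 2000, 2100, model="M")
    far = F("chr1", 9000, 9100, model="M")
    other_model = F("chr1", 2000, 2100, model="X")
    out = dm.classify_dm(
        AnnotationSet([abutting, far, other_model], toy_genome), existing,
        adjacency_gap=100,
    )
    status = {(f.start, f.get("model")): f.get("dm_status") for f in out}
    assert status[(2000, "M")] == "extended"
    assert status[(9000, "M")] == "new"
    assert status[(2000, "X")] == "new"
    assert all(f.get("dm_status") in ("new", "extended") for f in out)


def test_classify_dm_matches_bruteforce_nearest_neighbour(rng, toy_genome):
    from conftest import random_annotation_set

    existing = random_annotation_set(rng, toy_genome, 50, attrs=True)
    dm_set = random_annotation_set(rng, toy_genome, 50, attrs=True)
    gap = 200
    out = dm.classify_dm(dm_set, existing, adjacency_gap=gap)
    for f in out:
        dists = [
            max(n.start - f.end - 1, f.start - n.end - 1)
            for n in existing
            if n.seqid == f.seqid and n.get("model") == f.get("model")
        ]
        expected = "extended" if dists and min(dists) <= gap else "new"
        assert f.get("dm_status") == expected
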