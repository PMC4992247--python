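"""Shared fixtures and independent oracles for the test suite.

The bitmap oracle represents a genome as one boolean array per chromosome
and implements every set operation by per-base logic; it is deliberately
naive and independent of the interval implementations it checks.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
import pytest

from repeatscape.annotation_algebra import AnnotationSet, Feature


# ---------------------------------------------------------------------------
# bitmap oracle
# ---------------------------------------------------------------------------

def bitmap(aset: AnnotationSet) -> Dict[str, np.ndarray]:
    """Per-base boolean occupancy per chromosome."""
    out = {s: np.zeros(L, dtype=bool) for s, L in aset.genome.items()}
    for f in aset:
        out[f.seqid][f.start - 1 : f.end] = True
    return out


def bitmap_coverage(aset: AnnotationSet) -> float:
    bits = bitmap(aset)
    total = sum(L for L in aset.genome.values())
    return sum(int(b.sum()) for b in bits.values()) / total


def bitmap_intersect(a: AnnotationSet, b: AnnotationSet) -> Dict[str, np.ndarray]:
    ba, bb = bitmap(a), bitmap(b)
    return {s: ba[s] & bb[s] for s in ba}


def bitmap_subtract(a: AnnotationSet, b: AnnotationSet) -> Dict[str, np.ndarray]:
    ba, bb = bitmap(a), bitmap(b)
    return {s: ba[s] & ~bb[s] for s in ba}


def set_to_bitmap_equal(aset: AnnotationSet, bits: Dict[str, np.ndarray]) -> bool:
    """True when the features of ``aset`` cover exactly the set bits."""
    mine = bitmap(aset)
    return all(np.array_equal(mine[s], bits[s]) for s in bits)


def random_annotation_set(
    rng: np.random.Generator,
    genome: Dict[str, int],
    n_features: int,
    max_len: int = 500,
    attrs: bool = False,
) -> AnnotationSet:
    names = list(genome)
    feats: List[Feature] = []
    for i in range(n_features):
        seqid = names[rng.integers(0, len(names))]
        L = genome[seqid]
        length = int(rng.integers(1, min(max_len, L) + 1))
        start = int(rng.integers(0, L - length + 1))
        attributes = {}
        if attrs:
            attributes = {
                "model": f"M{rng.integers(0, 3)}",
                "identity": f"{rng.uniform(0.5, 1.0):.4f}",
                "consensus_coverage": f"{rng.uniform(0.1, 1.0):.4f}",
                "consensus": f"cons{rng.integers(0, 5)}",
            }
        feats.append(
            Feature(seqid=seqid, feature_type="region", start=start + 1,
                    end=start + length, attributes=attributes)
        )
    return AnnotationSet(feats, genome)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


@pytest.fixture
def toy_genome() -> Dict[str, int]:
    return {"chr1": 10000, "chr2": 6000}
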