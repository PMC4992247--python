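"""Mine "dark matter": divergent repeat segments missed by consensus-based
annotation.

Well-conserved annotated TE copies (longer than 500 bp, at least 80 %
identity to their consensus) are extracted as probes and used to re-scan the
genome for older, more fragmented copies of the same models.  Hits are
reported by a seed-and-extend homology scanner: exact k-mer seeding (default
k = 11) on both strands, ungapped extension with +1/-1 scoring and an X-drop
of 20, accepting hits of at least ``min_hit_len`` bases (default 20, the
minimum copy size used throughout) and ``min_hit_identity`` (default 0.60).
Everything already annotated is then subtracted at base level, and the
remaining dark-matter segments are classified as *extended* (adjacent to an
existing annotation of the same TE model) or *new*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Tuple

from .annotation_algebra import (
    AnnotationSet,
    Feature,
    merge_intervals,
    subtract as _subtract,
)
from .synthetic_genome import reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_MIN_PROBE_LEN = 500
DEFAULT_MIN_PROBE_IDENTITY = 0.80
DEFAULT_SEED_K = 11
DEFAULT_MIN_HIT_IDENTITY = 0.60
DEFAULT_MIN_HIT_LEN = 20
XDROP = 20


@dataclass
class ProbeCopy:
    """A genomic TE copy used as a dark-matter probe."""

    model: str
    consensus: str
    sequence: str
    identity_to_consensus: float
    seqid: str = "."
    start: int = 0  # 1-based origin of the extracted copy
    end: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError("probe sequence must be non-empty")
        if not 0 <= self.identity_to_consensus <= 1:
            raise ValueError("identity must be in [0, 1]")

    @property
    def length(self) -> int:
        return len(self.sequence)


def select_probes(
    annotations: AnnotationSet,
    genome_sequences: Mapping[str, str],
    min_len: int = DEFAULT_MIN_PROBE_LEN,
    min_identity: float = DEFAULT_MIN_PROBE_IDENTITY,
) -> List[ProbeCopy]:
    """Extract the well-conserved copies to use as probes.

    Selection is strict on length (``> min_len``) and non-strict on identity
    (``>= min_identity``).  Features without an identity attribute are
    excluded and logged.
    """
    probes: List[ProbeCopy] = []
    for f in annotations:
        ident = f.get("identity")
        if ident is None:
            logger.warning(
                "feature %s:%d-%d has no identity attribute; excluded from probes",
                f.seqid, f.start, f.end,
            )
            continue
        if f.length > min_len and float(ident) >= min_identity:
            seq = genome_sequences[f.seqid][f.start - 1 : f.end]
            probes.append(
                ProbeCopy(
                    model=f.get("model") or "",
                    consensus=f.get("consensus") or "",
                    sequence=seq,
                    identity_to_consensus=float(ident),
                    seqid=f.seqid,
                    start=f.start,
                    end=f.end,
                )
            )
    return probes


# ---------------------------------------------------------------------------
# seed-and-extend scan
# ---------------------------------------------------------------------------

def _kmer_index(seq: str, k: int) -> Dict[str, List[int]]:
    index: Dict[str, List[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _extend(probe: str, target: str, p: int, g: int, k: int) -> Tuple[int, int, int, int]:
    """Ungapped X-drop extension of an exact k-mer seed.

    Returns (probe_start, probe_end, genome_start, genome_end) half-open in
    both sequences, trimmed to the maximal-score extent.
    """
    # right extension
    score = k
    best = score
    pi, gi = p + k, g + k
    best_right = (pi, gi)
    while pi < len(probe) and gi < len(target):
        score += 1 if probe[pi] == target[gi] else -1
        pi += 1
        gi += 1
        if score > best:
            best = score
            best_right = (pi, gi)
        elif best - score > XDROP:
            break
    # left extension
    score = best
    pi, gi = p, g
    best_left = (pi, gi)
    while pi > 0 and gi > 0:
        pi -= 1
        gi -= 1
        score += 1 if probe[pi] == target[gi] else -1
        if score > best:
            best = score
            best_left = (pi, gi)
        elif best - score > XDROP:
            break
    return best_left[0], best_right[0], best_left[1], best_right[1]


def homology_scan(
    probes: List[ProbeCopy],
    genome_sequences: Mapping[str, str],
    seed_k: int = DEFAULT_SEED_K,
    min_hit_identity: float = DEFAULT_MIN_HIT_IDENTITY,
    min_hit_len: int = DEFAULT_MIN_HIT_LEN,
) -> AnnotationSet:
    """Scan the genome with every probe on both strands.

    Hits passing the identity and length thresholds are collected per TE
    model and collapsed (union) into maximal segments; each hit feature
    records the model, the best probe, the hit identity, and the strand.
    Zero hits is a valid outcome.
    """
    genome = {name: len(seq) for name, seq in genome_sequences.items()}
    hits_per_model: Dict[Tuple[str, str], List[Tuple[int, int, float, str, str]]] = {}
    for seqid, target in genome_sequences.items():
        index = _kmer_index(target, seed_k)
        for probe in probes:
            for strand, pseq in (("+", probe.sequence), ("-", reverse_complement(probe.sequence))):
                seen_diag: Dict[int, int] = {}  # diagonal -> genome end already covered
                for p in range(0, len(pseq) - seed_k + 1):
                    kmer = pseq[p : p + seed_k]
                    if "N" in kmer:
                        continue
                    for g in index.get(kmer, ()):  # exact seeds
                        d = g - p
                        if seen_diag.get(d, -1) >= g:
                            continue
                        ps, pe, gs, ge = _extend(pseq, target, p, g, seed_k)
                        seen_diag[d] = ge
                        length = ge - gs
                        if length < min_hit_len:
                            continue
                        matches = sum(
                            1 for a, b in zip(pseq[ps:pe], target[gs:ge]) if a == b
                        )
                        ident = matches / length
                        if ident >= min_hit_identity:
                            hits_per_model.setdefault((seqid, probe.model), []).append(
                                (gs, ge, ident, strand, probe.consensus)
                            )
    feats: List[Feature] = []
    hit_id = 0
    for (seqid, model), hits in sorted(hits_per_model.items()):
        ivs = merge_intervals([(s, e) for s, e, *_ in hits])
        for s, e in ivs:
            inside = [h for h in hits if h[0] < e and h[1] > s]
            best = max(inside, key=lambda h: h[2])
            hit_id += 1
            feats.append(
                Feature(
                    seqid=seqid,
                    source="dm_scan",
                    feature_type="repeat_region",
                    start=s + 1,
                    end=e,
                    strand=best[3],
                    attributes={
                        "ID": f"dm{hit_id}",
                        "model": model,
                        "probe": best[4],
                        "identity": f"{best[2]:.4f}",
                    },
                )
            )
    feats.sort(key=lambda f: (f.seqid, f.start, f.end))
    return AnnotationSet(feats, genome)


def subtract_known(hits: AnnotationSet, known: AnnotationSet) -> AnnotationSet:
    """Remove every base already annotated; hits may be split across the
    subtracted spans.  The result has zero base overlap with ``known``."""
    return _subtract(hits, known)


def classify_dm(
    dm: AnnotationSet, existing: AnnotationSet, adjacency_gap: int = 0
) -> AnnotationSet:
    """Label each dark-matter segment ``extended`` or ``new``.

    A segment within ``adjacency_gap`` bases of an existing annotation of
    the SAME TE model extends it; anything else is new.  The labels
    partition the set (attribute ``dm_status``).
    """
    by_model: Dict[Tuple[str, str], List[Feature]] = {}
    for f in existing:
        by_model.setdefault((f.seqid, f.get("model") or ""), []).append(f)
    feats: List[Feature] = []
    for f in dm:
        neighbours = by_model.get((f.seqid, f.get("model") or ""), [])
        extended = any(
            max(n.start - f.end - 1, f.start - n.end - 1) <= adjacency_gap
            for n in neighbours
        )
        attrs = dict(f.attributes)
        attrs["dm_status"] = "extended" if extended else "new"
        feats.append(
            Feature(f.seqid, f.source, f.feature_type, f.start, f.end,
                    f.score, f.strand, attrs)
        )
    return AnnotationSet(feats, dm.genome)
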