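"""Strip assembly-gap N-stretches and restore coordinates afterwards.

Some repeat detectors mishandle runs of unresolved bases ('N'): one widely
used oligo-counting program reads them as stretches of 'A' and emits a flood
of false A-rich annotations.  The fix is to remove the N-runs before running
the tool, and to lift the resulting annotations back onto original
coordinates afterwards.  :func:`build_index` performs the strip and records
an :class:`NIndex`; :func:`restore_interval` maps stripped-coordinate
intervals back, splitting any interval that spans a removed gap (the gap
bases were never scored by the wrapped tool, so an annotation is never
extended across one).

All coordinates here are 0-based half-open; GFF/BED conversion happens in
:mod:`repeatscape.io`.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

from .annotation_algebra import AnnotationSet, Feature, Interval

_N_RUN = re.compile(r"[nN]+")


@dataclass
class NIndex:
    """Ledger of the N-runs removed from one sequence.

    ``runs`` are maximal, sorted, non-overlapping intervals in original
    coordinates; ``stripped_length == original_length - sum(run lengths)``.
    """

    runs: List[Interval] = field(default_factory=list)
    original_length: int = 0

    def __post_init__(self) -> None:
        for (s1, e1), (s2, e2) in zip(self.runs, self.runs[1:]):
            if s2 <= e1:
                raise ValueError("N-runs must be sorted and disjoint")
        # segment bookkeeping: non-N segments in original coordinates with
        # their cumulative start in stripped coordinates
        self._segments: List[Tuple[int, int, int]] = []  # (strip_start, orig_start, length)
        pos = 0
        stripped = 0
        for s, e in self.runs:
            if s > pos:
                self._segments.append((stripped, pos, s - pos))
                stripped += s - pos
            pos = e
        if self.original_length > pos:
            self._segments.append((stripped, pos, self.original_length - pos))
        self._strip_starts = [seg[0] for seg in self._segments]

    @property
    def stripped_length(self) -> int:
        return self.original_length - sum(e - s for s, e in self.runs)

    def restore_position(self, p: int) -> int:
        """Original coordinate of stripped position ``p``."""
        if not 0 <= p < self.stripped_length:
            raise IndexError(f"stripped position {p} out of range")
        i = bisect_right(self._strip_starts, p) - 1
        strip_start, orig_start, _ = self._segments[i]
        return orig_start + (p - strip_start)


def build_index(sequence: str) -> Tuple[str, NIndex]:
    """Remove all N-runs from ``sequence`` and return the stripped sequence
    plus the :class:`NIndex` needed to restore coordinates.

    Case-insensitive on N; the case of the remaining bases is preserved
    (soft-masking survives the round trip).  An empty sequence yields an
    empty index.
    """
    runs = [(m.start(), m.end()) for m in _N_RUN.finditer(sequence)]
    stripped = _N_RUN.sub("", sequence)
    return stripped, NIndex(runs=runs, original_length=len(sequence))


def restore_interval(index: NIndex, interval: Interval) -> List[Interval]:
    """Map a stripped-coordinate half-open interval back to original
    coordinates.

    Returns one or more intervals: an input spanning a removed N-run is split
    into the corresponding original-coordinate pieces (callers report the
    pieces as parts sharing one identifier).
    """
    s, e = interval
    if not (0 <= s < e <= index.stripped_length):
        raise IndexError(f"stripped interval {interval} out of range")
    out: List[Interval] = []
    for strip_start, orig_start, length in index._segments:
        seg_end = strip_start + length
        lo = max(s, strip_start)
        hi = min(e, seg_end)
        if lo < hi:
            out.append((orig_start + (lo - strip_start), orig_start + (hi - strip_start)))
    return out


# ---------------------------------------------------------------------------
# whole-genome helpers
# ---------------------------------------------------------------------------

def strip_genome(sequences: Dict[str, str]) -> Tuple[Dict[str, str], Dict[str, NIndex]]:
    stripped, indices = {}, {}
    for name, seq in sequences.items():
        stripped[name], indices[name] = build_index(seq)
    return stripped, indices


def restore_annotations(
    aset: AnnotationSet, indices: Dict[str, NIndex]
) -> AnnotationSet:
    """Lift a stripped-coordinate AnnotationSet back to original coordinates.

    Split features carry ``part`` / ``part_of`` attributes sharing one
    identifier so downstream copy counting can recognise them.
    """
    feats: List[Feature] = []
    genome = {name: idx.original_length for name, idx in indices.items()}
    for k, f in enumerate(aset):
        idx = indices[f.seqid]
        pieces = restore_interval(idx, f.iv)
        ident = f.get("ID") or f"restored{k + 1}"
        for j, (s, e) in enumerate(pieces):
            attrs = dict(f.attributes)
            if len(pieces) > 1:
                attrs["part"] = str(j + 1)
                attrs["part_of"] = ident
                attrs["split_at_gap"] = "true"
            feats.append(
                Feature(
                    seqid=f.seqid,
                    source=f.source,
                    feature_type=f.feature_type,
                    start=s + 1,
                    end=e,
                    score=f.score,
                    strand=f.strand,
                    attributes=attrs,
                )
            )
    feats.sort(key=lambda f: (f.seqid, f.start, f.end))
    return AnnotationSet(feats, genome)


def nindex_to_bed_rows(indices: Dict[str, NIndex]):
    """N-runs as (seqid, start, end) rows, 0-based half-open (BED)."""
    for name, idx in indices.items():
        for s, e in idx.runs:
            yield name, s, e


def nindex_from_runs(runs_by_seqid: Dict[str, List[Interval]], lengths: Dict[str, int]) -> Dict[str, NIndex]:
    return {
        name: NIndex(runs=sorted(runs_by_seqid.get(name, [])), original_length=lengths[name])
        for name in lengths
    }
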