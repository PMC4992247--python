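"""Attribute-aware annotation handling and interval algebra.

Repeat-annotation pipelines emit GFF files in which one transposable-element
(TE) copy is frequently represented by several overlapping or juxtaposed
features, each produced by a different consensus of the same TE model.  This
module provides the defragmentation steps used to turn such raw output into a
copy inventory:

* stack resolution  -- keep one representative among mutually overlapping
  same-model features,
* juxtaposition merging -- fuse same-model features separated by at most a
  configurable gap,
* long-join copy counting -- count two same-model fragments flanking a nested
  insertion of a different model as a single copy,
* minimum-length filtering,

plus bedtools-equivalent base-level set operations (intersect, subtract,
union coverage, Venn partition of named sets) with coverage accounting
against a registered genome size.

Coordinates on :class:`Feature` follow GFF semantics (1-based, inclusive);
all internal arithmetic converts to 0-based half-open intervals at the
function boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Mapping, Sequence, Tuple

import pandas as pd

logger = logging.getLogger(__name__)

Interval = Tuple[int, int]  # 0-based half-open


@dataclass
class Feature:
    """A single GFF-style annotation (1-based inclusive coordinates)."""

    seqid: str
    source: str = "."
    feature_type: str = "feature"
    start: int = 1
    end: int = 1
    score: str = "."
    strand: str = "."
    attributes: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"feature end < start ({self.seqid}:{self.start}-{self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def iv(self) -> Interval:
        """0-based half-open interval."""
        return (self.start - 1, self.end)

    def get(self, key: str, default: str | None = None) -> str | None:
        return self.attributes.get(key, default)


class AnnotationSet:
    """An ordered collection of features over a registered genome.

    The genome registry maps seqid -> sequence length and is the coverage
    denominator; operating on a feature whose seqid is not registered is an
    error for the set operations.
    """

    def __init__(
        self,
        features: Iterable[Feature] = (),
        genome: Mapping[str, int] | None = None,
    ) -> None:
        self.features: List[Feature] = list(features)
        self.genome: Dict[str, int] = dict(genome or {})

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def sorted(self) -> "AnnotationSet":
        feats = sorted(self.features, key=lambda f: (f.seqid, f.start, f.end))
        return AnnotationSet(feats, self.genome)

    def genome_size(self) -> int:
        return sum(self.genome.values())

    def check_registry(self) -> None:
        for f in self.features:
            if f.seqid not in self.genome:
                raise KeyError(f"seqid {f.seqid!r} not in genome registry")

    def by_seqid(self) -> Dict[str, List[Feature]]:
        out: Dict[str, List[Feature]] = {s: [] for s in self.genome}
        for f in self.features:
            out.setdefault(f.seqid, []).append(f)
        for feats in out.values():
            feats.sort(key=lambda f: (f.start, f.end))
        return out

    def total_bases(self) -> int:
        """Summed feature lengths (double-counts overlaps)."""
        return sum(f.length for f in self.features)


# ---------------------------------------------------------------------------
# plain interval helpers (0-based half-open)
# ---------------------------------------------------------------------------

def merge_intervals(ivs: Iterable[Interval]) -> List[Interval]:
    """Collapse intervals into a sorted, disjoint union."""
    ivs = sorted(ivs)
    out: List[Interval] = []
    for s, e in ivs:
        if e <= s:
            continue
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def intersect_intervals(a: Sequence[Interval], b: Sequence[Interval]) -> List[Interval]:
    """Intersection of two disjoint sorted interval lists."""
    out: List[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract_intervals(a: Sequence[Interval], b: Sequence[Interval]) -> List[Interval]:
    """a minus b, both disjoint and sorted."""
    out: List[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def _union_by_seqid(aset: AnnotationSet) -> Dict[str, List[Interval]]:
    per: Dict[str, List[Interval]] = {}
    for f in aset:
        per.setdefault(f.seqid, []).append(f.iv)
    return {s: merge_intervals(v) for s, v in per.items()}


# ---------------------------------------------------------------------------
# defragmentation
# ---------------------------------------------------------------------------

MODEL_KEY = "model"
IDENTITY_KEY = "identity"
CONS_COV_KEY = "consensus_coverage"
CONSENSUS_KEY = "consensus"


def _identity(f: Feature) -> float:
    v = f.get(IDENTITY_KEY)
    if v is None:
        logger.warning(
            "feature %s:%d-%d lacks %r attribute; treated as identity 0",
            f.seqid, f.start, f.end, IDENTITY_KEY,
        )
        return 0.0
    return float(v)


def _cons_cov(f: Feature) -> float:
    v = f.get(CONS_COV_KEY)
    return float(v) if v is not None else 0.0


def _stack_priority(f: Feature) -> tuple:
    # higher identity, then higher consensus coverage, then longer, then
    # lexicographically smaller consensus name wins
    return (-_identity(f), -_cons_cov(f), -f.length, f.get(CONSENSUS_KEY) or "")


def resolve_stacks(aset: AnnotationSet) -> AnnotationSet:
    """Keep one representative among mutually overlapping same-model features.

    Greedy by priority: the best feature of a stack survives and every
    same-model feature overlapping it is dropped; the procedure repeats on
    the remainder, so the output has no same-model overlaps.  Priority is
    (1) highest percent identity to the annotating consensus, (2) highest
    fraction of the consensus covered, then longer interval, then consensus
    name.  Features of different models are never compared.
    """
    kept: List[Feature] = []
    groups: Dict[Tuple[str, str], List[Feature]] = {}
    for f in aset:
        groups.setdefault((f.seqid, f.get(MODEL_KEY) or ""), []).append(f)
    for feats in groups.values():
        pool = sorted(feats, key=_stack_priority)
        chosen: List[Feature] = []
        for f in pool:
            if all(f.end < c.start or f.start > c.end for c in chosen):
                chosen.append(f)
        kept.extend(chosen)
    kept.sort(key=lambda f: (f.seqid, f.start, f.end))
    return AnnotationSet(kept, aset.genome)


def merge_juxtaposed(aset: AnnotationSet, max_gap: int = 0) -> AnnotationSet:
    """Fuse same-model features separated by at most ``max_gap`` bases.

    ``max_gap=0`` fuses only bookended/overlapping features (e.g. [100,199]
    and [200,299] -> [100,299]).  The fused feature records the constituent
    consensus names in its ``consensus`` attribute.
    """
    out: List[Feature] = []
    groups: Dict[Tuple[str, str], List[Feature]] = {}
    for f in aset:
        groups.setdefault((f.seqid, f.get(MODEL_KEY) or ""), []).append(f)
    for feats in groups.values():
        feats.sort(key=lambda f: (f.start, f.end))
        cur = feats[0]
        members = [cur]
        for f in feats[1:]:
            gap = f.start - cur.end - 1
            if gap <= max_gap:
                members.append(f)
                if f.end > cur.end:
                    cur = replace(cur, end=f.end)
            else:
                out.append(_fuse(members, cur.end))
                cur = f
                members = [f]
        out.append(_fuse(members, cur.end))
    out.sort(key=lambda f: (f.seqid, f.start, f.end))
    return AnnotationSet(out, aset.genome)


def _fuse(members: List[Feature], end: int) -> Feature:
    if len(members) == 1:
        return members[0]
    first = members[0]
    attrs = dict(first.attributes)
    names = []
    for m in members:
        c = m.get(CONSENSUS_KEY)
        if c and c not in names:
            names.append(c)
    if names:
        attrs[CONSENSUS_KEY] = ",".join(names)
    idents = [_identity(m) for m in members if m.get(IDENTITY_KEY) is not None]
    if idents:
        # length-weighted identity of the fused span
        w = sum(m.length for m in members)
        attrs[IDENTITY_KEY] = f"{sum(_identity(m) * m.length for m in members) / w:.4f}"
    return replace(first, end=end, attributes=attrs)


def long_join_copies(aset: AnnotationSet, max_nested_span: int = 50000) -> pd.DataFrame:
    """Count TE copies, joining same-model fragments that flank a nested TE.

    Two consecutive same-model fragments are counted as ONE copy (the
    intervals stay split) when their gap is at most ``max_nested_span`` and
    is essentially filled (>= 95 % of its bases) by features of a different
    model -- the signature of a host copy split by a nested insertion, as
    opposed to two independent copies that merely have some other repeat
    somewhere between them.  Returns a table with one row per copy: model,
    seqid, fragment count, total copy length, and fragment coordinates.
    """
    per_seqid = aset.by_seqid()
    rows = []
    copy_id = 0
    for seqid, feats in per_seqid.items():
        by_model: Dict[str, List[Feature]] = {}
        for f in feats:
            by_model.setdefault(f.get(MODEL_KEY) or "", []).append(f)
        for model, frags in by_model.items():
            frags.sort(key=lambda f: (f.start, f.end))
            i = 0
            while i < len(frags):
                members = [frags[i]]
                j = i
                while j + 1 < len(frags):
                    a, b = frags[j], frags[j + 1]
                    gap_len = b.start - a.end - 1
                    if gap_len <= 0 or gap_len > max_nested_span:
                        break
                    gap_iv = (a.end, b.start - 1)  # 0-based half-open
                    guest_ivs = merge_intervals(
                        [
                            (max(g.iv[0], gap_iv[0]), min(g.iv[1], gap_iv[1]))
                            for g in feats
                            if g.get(MODEL_KEY) != model
                            and g.iv[0] < gap_iv[1] and g.iv[1] > gap_iv[0]
                        ]
                    )
                    filled = sum(e - s for s, e in guest_ivs)
                    if filled < 0.95 * gap_len:
                        break
                    members.append(b)
                    j += 1
                copy_id += 1
                rows.append(
                    {
                        "copy_id": copy_id,
                        "model": model,
                        "seqid": seqid,
                        "n_fragments": len(members),
                        "copy_length": sum(m.length for m in members),
                        "start": members[0].start,
                        "end": members[-1].end,
                    }
                )
                i = j + 1
    return pd.DataFrame(
        rows,
        columns=[
            "copy_id", "model", "seqid", "n_fragments",
            "copy_length", "start", "end",
        ],
    )


def filter_min_length(aset: AnnotationSet, min_len: int = 20) -> AnnotationSet:
    """Drop features shorter than ``min_len`` bases (default 20 bp)."""
    kept = [f for f in aset if f.length >= min_len]
    n_removed = len(aset) - len(kept)
    if n_removed:
        logger.info("filter_min_length(%d): removed %d features", min_len, n_removed)
    return AnnotationSet(kept, aset.genome)


# ---------------------------------------------------------------------------
# set operations
# ---------------------------------------------------------------------------

def _ivs_to_features(per: Mapping[str, List[Interval]], ftype: str) -> List[Feature]:
    feats = []
    for seqid in sorted(per):
        for s, e in per[seqid]:
            feats.append(Feature(seqid=seqid, feature_type=ftype, start=s + 1, end=e))
    return feats


def intersect(a: AnnotationSet, b: AnnotationSet) -> AnnotationSet:
    """Base-level intersection (collapsed intervals)."""
    a.check_registry()
    b.check_registry()
    ua, ub = _union_by_seqid(a), _union_by_seqid(b)
    per = {
        s: intersect_intervals(ua[s], ub[s])
        for s in ua if s in ub
    }
    per = {s: v for s, v in per.items() if v}
    return AnnotationSet(_ivs_to_features(per, "intersection"), a.genome)


def subtract(a: AnnotationSet, b: AnnotationSet) -> AnnotationSet:
    """Base-level subtraction a - b; features split across removed spans."""
    a.check_registry()
    b.check_registry()
    ub = _union_by_seqid(b)
    feats: List[Feature] = []
    for f in a:
        pieces = subtract_intervals([f.iv], ub.get(f.seqid, []))
        for k, (s, e) in enumerate(pieces):
            attrs = dict(f.attributes)
            if len(pieces) > 1:
                attrs["part"] = str(k + 1)
            feats.append(replace(f, start=s + 1, end=e, attributes=attrs))
    feats.sort(key=lambda f: (f.seqid, f.start, f.end))
    return AnnotationSet(feats, a.genome)


def union_coverage(*sets: AnnotationSet) -> float:
    """Fraction of the registered genome covered by the union of the sets."""
    if not sets:
        return 0.0
    genome = sets[0].genome
    size = sum(genome.values())
    if size == 0:
        raise ValueError("empty genome registry")
    per: Dict[str, List[Interval]] = {}
    for aset in sets:
        aset.check_registry()
        for f in aset:
            per.setdefault(f.seqid, []).append(f.iv)
    covered = sum(
        e - s for ivs in per.values() for s, e in merge_intervals(ivs)
    )
    return covered / size


def coverage(aset: AnnotationSet) -> float:
    """Fraction of the registered genome covered by this set."""
    return union_coverage(aset)


def venn_coverage(named_sets: Mapping[str, AnnotationSet]) -> Dict[frozenset, float]:
    """Coverage of every disjoint membership region among named sets.

    Returns a map from the frozenset of member names to the fraction of the
    genome covered exclusively by that combination; the values sum to the
    union coverage.
    """
    names = list(named_sets)
    if not names:
        return {}
    genome = named_sets[names[0]].genome
    size = sum(genome.values())
    unions = {n: _union_by_seqid(named_sets[n]) for n in names}
    seqids = set()
    for u in unions.values():
        seqids.update(u)
    out: Dict[frozenset, int] = {}
    for seqid in seqids:
        # boundary sweep over elementary segments
        bounds = set()
        for n in names:
            for s, e in unions[n].get(seqid, []):
                bounds.add(s)
                bounds.add(e)
        bounds = sorted(bounds)
        ptrs = {n: 0 for n in names}
        for s, e in zip(bounds, bounds[1:]):
            members = []
            for n in names:
                ivs = unions[n].get(seqid, [])
                i = ptrs[n]
                while i < len(ivs) and ivs[i][1] <= s:
                    i += 1
                ptrs[n] = i
                if i < len(ivs) and ivs[i][0] <= s:
                    members.append(n)
            if members:
                key = frozenset(members)
                out[key] = out.get(key, 0) + (e - s)
    return {k: v / size for k, v in out.items()}
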