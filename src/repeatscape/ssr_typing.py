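"""Classify tandem-repeat detections into SSR types.

Tandem Repeat Finder (TRF, run with parameters Match,Mismatch,Delta,PM,PI,
Minscore,MaxPeriod = 2,5,7,80,10,25,2000) reports every tandem array it can
score.  This module parses its ``.dat`` output and applies the SSR taxonomy
used throughout the analysis:

==============  ==================  =========================================
unit length      class               retention rule
==============  ==================  =========================================
1 bp             simple repeat       kept when >= 50 units; sub-typed polyA
                                     (unit A/T) or polyC (unit C/G)
2-10 bp          microsatellite      kept when >= 50 units
11-60 bp         minisatellite       kept when >= 50 units
>60 bp           large tandem repeat 2-50 units
>60 bp           satellite DNA       > 50 units
==============  ==================  =========================================

TRF copy numbers are fractional (e.g. "50.3") and are compared directly to
the thresholds (>= 50.0 retains a small-unit array; strictly > 50.0 promotes
a large-unit array to satellite).

:func:`find_exact_tandems` is an independent brute-force detector for
*perfect* arrays: it serves as the test oracle standing in for TRF on
synthetic genomes with planted arrays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, TextIO

from .annotation_algebra import AnnotationSet, Feature

logger = logging.getLogger(__name__)

SIMPLE_POLYA = "simple_polyA"
SIMPLE_POLYC = "simple_polyC"
MICROSATELLITE = "microsatellite"
MINISATELLITE = "minisatellite"
LARGE_TANDEM_REPEAT = "large_tandem_repeat"
SATELLITE = "satellite"
REJECTED = "rejected"

CLASSES = (
    SIMPLE_POLYA,
    SIMPLE_POLYC,
    MICROSATELLITE,
    MINISATELLITE,
    LARGE_TANDEM_REPEAT,
    SATELLITE,
)

MAX_PERIOD = 2000  # TRF MaxPeriod used throughout
TRF_PARAMETERS = (2, 5, 7, 80, 10, 25, MAX_PERIOD)


@dataclass
class TandemArray:
    """One TRF detection (coordinates as printed: 1-based inclusive)."""

    seqid: str
    start: int
    end: int
    unit_length: int
    copy_number: float
    consensus_unit: str
    percent_matches: float = 100.0
    percent_indels: float = 0.0
    alignment_score: float = 0.0
    ssr_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end < start")
        if self.unit_length < 1 or self.unit_length > MAX_PERIOD:
            raise ValueError(f"unit_length {self.unit_length} outside [1, {MAX_PERIOD}]")
        if self.copy_number <= 1:
            raise ValueError("copy_number must exceed 1")

    @property
    def array_length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# TRF .dat parsing
# ---------------------------------------------------------------------------

def parse_trf_dat(stream: Iterable[str] | TextIO) -> List[TandemArray]:
    """Parse the TRF ``-d`` data-file dialect.

    ``Sequence:`` header lines set the seqid for the detection records that
    follow; ``Parameters:`` and other header lines are skipped with a log
    entry.  A detection record has 15 whitespace-separated fields
    (start end period copies consensus_size pct_match pct_indel score
    A C G T entropy consensus_unit array_sequence); a record with the wrong
    field count is an error naming the line.
    """
    arrays: List[TandemArray] = []
    seqid: Optional[str] = None
    for lineno, line in enumerate(stream, 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("Sequence:"):
            seqid = line.split(None, 1)[1].split()[0]
            continue
        first = line.split(None, 1)[0]
        if not first[0].isdigit():
            logger.info("skipping header line %d: %s", lineno, line[:60])
            continue
        fields = line.split()
        if len(fields) != 15:
            raise ValueError(
                f"line {lineno}: expected 15 fields in TRF record, got {len(fields)}"
            )
        if seqid is None:
            raise ValueError(f"line {lineno}: record before any 'Sequence:' header")
        arrays.append(
            TandemArray(
                seqid=seqid,
                start=int(fields[0]),
                end=int(fields[1]),
                unit_length=int(fields[2]),
                copy_number=float(fields[3]),
                consensus_unit=fields[13],
                percent_matches=float(fields[5]),
                percent_indels=float(fields[6]),
                alignment_score=float(fields[7]),
            )
        )
    return arrays


def format_trf_dat(arrays: Iterable[TandemArray]) -> str:
    """Render arrays in the TRF ``.dat`` dialect (for fixtures/round trips)."""
    lines: List[str] = []
    current = None
    for a in arrays:
        if a.seqid != current:
            lines.append(f"Sequence: {a.seqid}")
            current = a.seqid
        unit = a.consensus_unit
        seq = (unit * (int(a.copy_number) + 2))[: a.array_length]
        lines.append(
            f"{a.start} {a.end} {a.unit_length} {a.copy_number:.1f} {a.unit_length} "
            f"{a.percent_matches:.0f} {a.percent_indels:.0f} {a.alignment_score:.0f} "
            f"25 25 25 25 2.00 {unit} {seq}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify(
    array: TandemArray,
    *,
    min_units_small: float = 50,
    unit_boundary_small: int = 10,
    unit_boundary_mini: int = 60,
    satellite_min_units: float = 50,
) -> str:
    """Assign the SSR class (or ``rejected``) of one tandem array.

    Unit length 1 bp -> simple repeat (polyA for unit A/T, polyC for C/G);
    2-10 bp -> microsatellite; 11-60 bp -> minisatellite; these three are
    retained only when the copy number reaches ``min_units_small`` (default
    50 units).  Units over 60 bp with 2 to 50 copies are large tandem
    repeats and with more than 50 copies satellite DNAs.
    """
    u = array.unit_length
    n = array.copy_number
    if u <= unit_boundary_mini:
        if n < min_units_small:
            cls = REJECTED
        elif u == 1:
            base = array.consensus_unit.upper()
            cls = SIMPLE_POLYA if base in ("A", "T") else SIMPLE_POLYC
        elif u <= unit_boundary_small:
            cls = MICROSATELLITE
        else:
            cls = MINISATELLITE
    else:
        cls = SATELLITE if n > satellite_min_units else LARGE_TANDEM_REPEAT
    array.ssr_class = cls
    return cls


def classify_all(arrays: Iterable[TandemArray], **kwargs) -> List[TandemArray]:
    for a in arrays:
        classify(a, **kwargs)
    return list(arrays)


# ---------------------------------------------------------------------------
# GFF output (six-attribute schema)
# ---------------------------------------------------------------------------

def to_gff(arrays: Iterable[TandemArray], genome: Dict[str, int] | None = None) -> AnnotationSet:
    """Retained arrays as GFF features.

    The ninth column carries exactly: ID, SSR type, repeat-unit size,
    repeat-unit sequence, tandem-array size, and the number of unit copies.
    Rejected or unclassified arrays are excluded.
    """
    feats: List[Feature] = []
    i = 0
    for a in arrays:
        if a.ssr_class in (None, REJECTED):
            continue
        i += 1
        feats.append(
            Feature(
                seqid=a.seqid,
                source="repeatscape",
                feature_type="tandem_repeat",
                start=a.start,
                end=a.end,
                score=".",
                strand=".",
                attributes={
                    "ID": f"SSR{i}",
                    "ssr_type": a.ssr_class,
                    "unit_size": str(a.unit_length),
                    "unit": a.consensus_unit,
                    "array_size": str(a.array_length),
                    "copy_number": f"{a.copy_number:g}",
                },
            )
        )
    return AnnotationSet(feats, genome or {})


def from_gff(aset: AnnotationSet) -> List[TandemArray]:
    """Inverse of :func:`to_gff` (round-trip support)."""
    out = []
    for f in aset:
        a = TandemArray(
            seqid=f.seqid,
            start=f.start,
            end=f.end,
            unit_length=int(f.attributes["unit_size"]),
            copy_number=float(f.attributes["copy_number"]),
            consensus_unit=f.attributes["unit"],
        )
        a.ssr_class = f.attributes["ssr_type"]
        out.append(a)
    return out


def dedupe_units(arrays: Iterable[TandemArray]) -> int:
    """Number of distinct repeated units among arrays (exact, 100% identity)."""
    return len({a.consensus_unit.upper() for a in arrays})


# ---------------------------------------------------------------------------
# brute-force oracle for perfect tandems
# ---------------------------------------------------------------------------

def _primitive(unit: str) -> bool:
    u = len(unit)
    for p in range(1, u):
        if u % p == 0 and unit == unit[:p] * (u // p):
            return False
    return True


def find_exact_tandems(
    sequence: str, max_unit: int = 60, min_copies: float = 2.0
) -> List[TandemArray]:
    """Report every maximal perfect tandem run (independent brute force).

    Runs are leftmost-anchored with the smallest primitive unit; copy
    numbers may be fractional when a final unit is partial.  N bases never
    participate in a run.  Quadratic and meant for test-scale sequences.
    """
    seq = sequence.upper()
    L = len(seq)
    out: List[TandemArray] = []
    for u in range(1, max_unit + 1):
        i = 0
        while i + 2 * u <= L:
            unit = seq[i : i + u]
            if "N" in unit or not _primitive(unit):
                i += 1
                continue
            # leftmost anchoring: the run must not extend left
            if i > 0 and seq[i - 1] == seq[i - 1 + u] and seq[i - 1] != "N":
                i += 1
                continue
            j = i + u
            while j < L and seq[j] == seq[j - u] and seq[j] != "N":
                j += 1
            run = j - i
            copies = run / u
            if copies >= min_copies and copies >= 2:
                # suppress runs whose repeating pattern is a cyclic shift of
                # a shorter unit already reported over the same span
                if not any(
                    o.start - 1 <= i and o.end >= j and u % o.unit_length == 0
                    for o in out
                ):
                    out.append(
                        TandemArray(
                            seqid="seq",
                            start=i + 1,
                            end=j,
                            unit_length=u,
                            copy_number=round(copies, 2),
                            consensus_unit=unit,
                        )
                    )
                i = j - u + 1
            else:
                i += 1
    out.sort(key=lambda a: (a.start, a.unit_length))
    return out
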