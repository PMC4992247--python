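"""Permutation tests for chromosomal enrichment and TE hotspots.

Two empirical-null frameworks:

* **Chromosome enrichment** -- is an element class (TEs, genes, S/MARs, CpG
  islands) over- or under-represented on each chromosome?  The sampling
  space is the *reduced genome*: each chromosome's length minus the bases
  the element class already covers there.  Each permutation redistributes
  the genome-wide total of elements across chromosomes with probability
  proportional to reduced size (count mode: a multinomial draw) or
  re-assigns the observed element lengths (coverage mode).  With the
  default 100000 permutations the 1st/99th empirical percentiles bound the
  central 98 % of the null; an observation strictly outside them is called
  ``over`` or ``under``.

* **Hotspot scan** -- 50-kbp windows tile each chromosome; each of the
  (default 1000) permutations re-places the chromosome's TE copies, lengths
  preserved, uniformly over non-N positions without overlap (rejection
  sampling).  Per-window copy counts are pooled per chromosome into one
  null distribution; a window whose observed count strictly exceeds the
  empirical 99th percentile is a hotspot.  Windows that are more than half
  N are excluded from both the observed and the null tallies.

All randomness flows through one seeded ``numpy`` generator and the seed is
recorded in every result row.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation_algebra import AnnotationSet, merge_intervals
from .nmask import NIndex

logger = logging.getLogger(__name__)

CALL_OVER = "over"
CALL_UNDER = "under"
CALL_HOTSPOT = "hotspot"
CALL_NONE = "none"


@dataclass
class PermutationResult:
    """Observed value vs an empirical null for one chromosome or window."""

    unit: str
    observed: float
    low_threshold: float
    high_threshold: float
    call: str
    n_perm: int
    seed: int
    quantiles: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.low_threshold > self.high_threshold:
            raise ValueError("low_threshold > high_threshold")


def results_to_frame(results: Sequence[PermutationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "unit": r.unit,
                "observed": r.observed,
                "low_threshold": r.low_threshold,
                "high_threshold": r.high_threshold,
                "call": r.call,
                "n_perm": r.n_perm,
                "seed": r.seed,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# reduced genome
# ---------------------------------------------------------------------------

def reduced_genome(
    chrom_sizes: Mapping[str, int], element_annotations: AnnotationSet
) -> Dict[str, int]:
    """Chromosome sizes minus the bases covered by the element class."""
    covered: Dict[str, int] = {c: 0 for c in chrom_sizes}
    per: Dict[str, list] = {}
    for f in element_annotations:
        per.setdefault(f.seqid, []).append(f.iv)
    for seqid, ivs in per.items():
        if seqid not in covered:
            raise KeyError(f"seqid {seqid!r} not in chromosome sizes")
        covered[seqid] = sum(e - s for s, e in merge_intervals(ivs))
    out = {c: chrom_sizes[c] - covered[c] for c in chrom_sizes}
    if any(v < 0 for v in out.values()):
        raise ValueError("element coverage exceeds chromosome size")
    return out


# ---------------------------------------------------------------------------
# chromosome enrichment
# ---------------------------------------------------------------------------

def chromosome_enrichment(
    element_counts: Mapping[str, int],
    reduced_sizes: Mapping[str, int],
    n_perm: int = 100000,
    alpha: float = 0.01,
    seed: int = 0,
    mode: str = "count",
    element_lengths: Mapping[str, Sequence[int]] | None = None,
) -> List[PermutationResult]:
    """Empirical over/under-representation call per chromosome.

    ``element_counts`` maps chromosome -> observed number of copies (count
    mode) while ``element_lengths`` additionally supplies the per-chromosome
    copy lengths for coverage mode (observed statistic: summed length).
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100: empirical thresholds are meaningless")
    if mode not in ("count", "coverage"):
        raise ValueError("mode must be 'count' or 'coverage'")
    chroms = list(reduced_sizes)
    total = int(sum(element_counts.get(c, 0) for c in chroms))
    if total < 1:
        raise ValueError("need at least one element")
    rng = np.random.default_rng(seed)
    sizes = np.array([reduced_sizes[c] for c in chroms], dtype=float)
    p = sizes / sizes.sum()

    if mode == "count":
        null = rng.multinomial(total, p, size=n_perm)  # (n_perm, K)
        observed = np.array([element_counts.get(c, 0) for c in chroms], dtype=float)
    else:
        if element_lengths is None:
            raise ValueError("coverage mode requires element_lengths")
        lengths = np.concatenate(
            [np.asarray(element_lengths.get(c, []), dtype=float) for c in chroms]
        )
        if len(lengths) != total:
            raise ValueError("element_lengths inconsistent with element_counts")
        K = len(chroms)
        null = np.zeros((n_perm, K))
        chunk = max(1, int(2e7 // max(total, 1)))
        for lo in range(0, n_perm, chunk):
            hi = min(lo + chunk, n_perm)
            assign = rng.choice(K, size=(hi - lo, total), p=p)
            for k in range(K):
                null[lo:hi, k] = ((assign == k) * lengths).sum(axis=1)
        observed = np.array(
            [float(np.sum(element_lengths.get(c, []))) for c in chroms]
        )

    lo_q = np.quantile(null, alpha, axis=0)
    hi_q = np.quantile(null, 1 - alpha, axis=0)
    results = []
    for i, c in enumerate(chroms):
        if observed[i] > hi_q[i]:
            call = CALL_OVER
        elif observed[i] < lo_q[i]:
            call = CALL_UNDER
        else:
            call = CALL_NONE
        results.append(
            PermutationResult(
                unit=c,
                observed=float(observed[i]),
                low_threshold=float(lo_q[i]),
                high_threshold=float(hi_q[i]),
                call=call,
                n_perm=n_perm,
                seed=seed,
            )
        )
    return results


# ---------------------------------------------------------------------------
# hotspot scan
# ---------------------------------------------------------------------------

def _place_copies_nonoverlap(
    rng: np.random.Generator,
    chrom_len: int,
    lengths: Sequence[int],
    n_runs: Sequence[Tuple[int, int]],
    max_attempts: int = 1_000_000,
) -> List[int]:
    """Place copies uniformly over non-N positions without overlap.

    Rejection sampling with a hard attempt cap; failure raises with a hint
    that coverage is too high for non-overlapping placement.
    """
    placed_starts: List[int] = []
    placed_ends: List[int] = []
    forbidden = sorted(n_runs)
    attempts = 0
    out: List[int] = []
    for length in sorted(lengths, reverse=True):
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    "rejection sampling exceeded the attempt cap; element "
                    "coverage is likely too high for non-overlap placement"
                )
            start = int(rng.integers(0, chrom_len - length + 1))
            end = start + length
            if _overlaps_sorted(forbidden, start, end):
                continue
            i = bisect_left(placed_starts, start)
            if i > 0 and placed_ends[i - 1] > start:
                continue
            if i < len(placed_starts) and placed_starts[i] < end:
                continue
            placed_starts.insert(i, start)
            placed_ends.insert(i, end)
            out.append(start)
            break
    return out


def _overlaps_sorted(ivs: Sequence[Tuple[int, int]], start: int, end: int) -> bool:
    i = bisect_left(ivs, (end, end))
    if i > 0 and ivs[i - 1][1] > start:
        return True
    return False


def _window_layout(
    chrom_len: int, window: int, n_index: Optional[NIndex]
) -> Tuple[List[Tuple[int, int]], List[bool]]:
    """Non-overlapping tiles from position 0; a window over 50% N is
    excluded."""
    windows = []
    for s in range(0, chrom_len, window):
        windows.append((s, min(s + window, chrom_len)))
    included = []
    for s, e in windows:
        n_bases = 0
        if n_index is not None:
            for rs, re in n_index.runs:
                n_bases += max(0, min(re, e) - max(rs, s))
        included.append(n_bases <= (e - s) / 2)
    return windows, included


def hotspot_scan(
    te_annotations: AnnotationSet,
    chrom_sizes: Mapping[str, int],
    n_indices: Mapping[str, NIndex] | None = None,
    window: int = 50000,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
) -> List[PermutationResult]:
    """Flag windows whose TE copy count exceeds the chromosome's empirical
    99th percentile of permuted placements.

    A copy is assigned to the window containing its start position.  Each
    permutation preserves the observed copy lengths of the chromosome, so
    the total placed bases are conserved.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100: empirical thresholds are meaningless")
    rng = np.random.default_rng(seed)
    per_chrom = te_annotations.by_seqid()
    results: List[PermutationResult] = []
    for chrom in chrom_sizes:
        L = chrom_sizes[chrom]
        n_index = (n_indices or {}).get(chrom)
        n_runs = n_index.runs if n_index else []
        if L < window:
            logger.info("%s shorter than window: single truncated window", chrom)
        windows, included = _window_layout(L, window, n_index)
        feats = per_chrom.get(chrom, [])
        lengths = [f.length for f in feats]
        if not feats:
            for (s, e), inc in zip(windows, included):
                if inc:
                    results.append(
                        PermutationResult(
                            unit=f"{chrom}:{s + 1}-{e}",
                            observed=0,
                            low_threshold=0,
                            high_threshold=0,
                            call=CALL_NONE,
                            n_perm=n_perm,
                            seed=seed,
                        )
                    )
            continue
        starts0 = [f.start - 1 for f in feats]
        observed = _window_counts(starts0, windows, included, window)
        pooled: List[int] = []
        for _ in range(n_perm):
            placed = _place_copies_nonoverlap(rng, L, lengths, n_runs)
            pooled.extend(_window_counts(placed, windows, included, window))
        threshold = float(np.quantile(np.asarray(pooled), 1 - alpha))
        for (s, e), inc, obs in zip(windows, included, observed_iter(observed, included)):
            if not inc:
                continue
            call = CALL_HOTSPOT if obs > threshold else CALL_NONE
            results.append(
                PermutationResult(
                    unit=f"{chrom}:{s + 1}-{e}",
                    observed=obs,
                    low_threshold=0.0,
                    high_threshold=threshold,
                    call=call,
                    n_perm=n_perm,
                    seed=seed,
                )
            )
    return results


def _window_counts(
    starts: Sequence[int],
    windows: Sequence[Tuple[int, int]],
    included: Sequence[bool],
    window: int,
) -> List[int]:
    counts = [0] * len(windows)
    for s in starts:
        w = s // window
        if w < len(windows):
            counts[w] += 1
    return [c for c, inc in zip(counts, included) if inc]


def observed_iter(observed: Sequence[int], included: Sequence[bool]):
    it = iter(observed)
    for inc in included:
        yield next(it) if inc else 0
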