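"""Simulate multi-chromosome genomes with planted, ground-truthed repeats.

Every downstream stage of the pipeline (SSR typing, TE defragmentation,
dark-matter mining, N-gap remapping, permutation tests) is exercised on
genomes produced here, so each planted element carries an exact truth record:
its coordinates, class or TE model, realised divergence, truncation flags and
copy identifier.

The generator emulates the structure of a repeat-rich assembly:

* i.i.d. uniform background nucleotides (configurable GC),
* TE copies derived from consensus models with controlled divergence,
  5'/3' truncation, and optional single-level nesting (a guest copy inserted
  inside a host copy, splitting the host into two truth features that share
  a copy identifier -- the "long-join" situation),
* tandem arrays for every SSR class,
* N-stretch assembly gaps planted outside repeats,
* gene / CpG-island / S-MAR-like context features on a separate truth track.

Substitution-only mutation: planted copies keep the consensus length (minus
truncation), so identity can be recomputed by direct per-base comparison.
Indel evolution and CpG-biased mutation are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotation_algebra import AnnotationSet, Feature, Interval
from . import ssr_typing

BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

TE_TYPES = ("LINE", "LTR", "TIR", "undetermined")


class PackingError(RuntimeError):
    """Requested repeats exceed chromosome capacity."""


@dataclass
class RepeatModelSpec:
    """A TE model to plant: a consensus plus copy-generation parameters."""

    name: str
    te_type: str
    consensus: str
    copy_count: int
    divergence_range: Tuple[float, float] = (0.0, 0.2)
    truncation_prob: float = 0.0
    nesting_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.te_type not in TE_TYPES:
            raise ValueError(f"te_type must be one of {TE_TYPES}")
        if not (50 <= len(self.consensus) <= 10000):
            raise ValueError("consensus length must be in [50, 10000]")
        if set(self.consensus.upper()) - set("ACGT"):
            raise ValueError("consensus must contain only A/C/G/T")
        lo, hi = self.divergence_range
        if not (0 <= lo <= hi <= 0.5):
            raise ValueError("divergence_range must satisfy 0 <= lo <= hi <= 0.5")
        if self.copy_count < 0:
            raise ValueError("copy_count must be >= 0")


@dataclass
class SsrPlantSpec:
    """Tandem arrays of one SSR class to plant."""

    ssr_class: str
    unit_length: int
    copy_number: float
    count: int = 1

    _RANGES = {
        ssr_typing.SIMPLE_POLYA: (1, 1),
        ssr_typing.SIMPLE_POLYC: (1, 1),
        ssr_typing.MICROSATELLITE: (2, 10),
        ssr_typing.MINISATELLITE: (11, 60),
        ssr_typing.LARGE_TANDEM_REPEAT: (61, ssr_typing.MAX_PERIOD),
        ssr_typing.SATELLITE: (61, ssr_typing.MAX_PERIOD),
    }

    def __post_init__(self) -> None:
        lo, hi = self._RANGES[self.ssr_class]
        if not (lo <= self.unit_length <= hi):
            raise ValueError(
                f"unit_length {self.unit_length} outside [{lo},{hi}] for {self.ssr_class}"
            )
        if self.copy_number <= 1:
            raise ValueError("copy_number must exceed 1")


@dataclass
class GenomeTruth:
    """A simulated genome plus exact truth annotations."""

    sequences: Dict[str, str]
    truth: AnnotationSet
    context: AnnotationSet
    n_runs: Dict[str, List[Interval]]
    seed: int

    @property
    def genome(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def mutate_copy(
    consensus: str,
    divergence: float,
    truncate_5p: int = 0,
    truncate_3p: int = 0,
    seed: int | np.random.Generator = 0,
) -> str:
    """Derive a decayed copy from a consensus.

    Truncations are applied first; each remaining base is then substituted
    with probability ``divergence`` by one of the three other bases, so the
    expected substituted fraction equals ``divergence`` and the returned
    length equals ``len(consensus) - truncate_5p - truncate_3p``.
    """
    if not 0 <= divergence <= 1:
        raise ValueError("divergence must be in [0, 1]")
    if truncate_5p + truncate_3p >= len(consensus):
        raise ValueError("truncations must sum to less than the consensus length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    core = consensus[truncate_5p : len(consensus) - truncate_3p]
    if divergence == 0:
        return core
    arr = np.array(list(core))
    hit = rng.random(len(arr)) < divergence
    if hit.any():
        # substitute by a uniformly chosen *different* base
        idx = {b: i for i, b in enumerate("ACGT")}
        cur = np.array([idx[b] for b in arr[hit]])
        shift = rng.integers(1, 4, size=hit.sum())
        arr[hit] = BASES[(cur + shift) % 4]
    return "".join(arr)


def identity_to(consensus: str, copy: str, offset: int = 0) -> float:
    """Fraction of positions of ``copy`` matching the consensus (aligned
    without gaps at ``offset``)."""
    ref = consensus[offset : offset + len(copy)]
    matches = sum(a == b for a, b in zip(ref, copy))
    return matches / len(copy)


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

def _place(
    rng: np.random.Generator,
    occupied: List[Interval],
    chrom_len: int,
    length: int,
    chrom_name: str,
    max_tries: int = 2000,
) -> int:
    """Uniform non-overlapping placement by rejection; explicit failure names
    the chromosome."""
    if length > chrom_len:
        raise PackingError(f"{chrom_name}: plant of {length} bp exceeds chromosome")
    for _ in range(max_tries):
        start = int(rng.integers(0, chrom_len - length + 1))
        if all(start + length <= s or start >= e for s, e in occupied):
            occupied.append((start, start + length))
            return start
    raise PackingError(
        f"{chrom_name}: could not place a {length}-bp plant after {max_tries} tries "
        "(requested repeats exceed capacity)"
    )


def generate_genome(
    chrom_sizes: Sequence[int],
    te_specs: Sequence[RepeatModelSpec] = (),
    ssr_specs: Sequence[SsrPlantSpec] = (),
    n_stretch_spec: Tuple[int, int] | None = None,
    gene_density: float = 0.0,
    seed: int = 0,
    gc: float = 0.5,
) -> GenomeTruth:
    """Generate a genome with planted, ground-truthed repeats.

    ``n_stretch_spec`` is (count per chromosome, run length); gene-like
    context features (with CpG/S-MAR analogues) are emitted at
    ``gene_density`` features per Mbp on a separate truth track.
    Reproducible: identical inputs and seed give a byte-identical genome.
    """
    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1}" for i in range(len(chrom_sizes))]
    chroms = {n: list(random_sequence(rng, L, gc)) for n, L in zip(names, chrom_sizes)}
    occupied: Dict[str, List[Interval]] = {n: [] for n in names}
    truth_feats: List[Feature] = []
    copy_counter = 0

    total_plant = sum(
        len(s.consensus) * s.copy_count for s in te_specs
    ) + sum(int(s.unit_length * s.copy_number) * s.count for s in ssr_specs)
    if total_plant >= sum(chrom_sizes):
        raise PackingError(
            f"total planted length {total_plant} exceeds genome size {sum(chrom_sizes)}"
        )

    # --- TE copies -------------------------------------------------------
    host_registry: List[Tuple[str, int, int, str, int]] = []  # seqid, s, e, model, copy_id
    for spec in te_specs:
        lo, hi = spec.divergence_range
        for _ in range(spec.copy_count):
            chrom = names[int(rng.integers(0, len(names)))]
            div = float(rng.uniform(lo, hi)) if hi > lo else lo
            t5 = t3 = 0
            if spec.truncation_prob and rng.random() < spec.truncation_prob:
                max_cut = len(spec.consensus) // 3
                t5 = int(rng.integers(0, max_cut + 1))
                t3 = int(rng.integers(0, max_cut + 1))
            copy_seq = mutate_copy(spec.consensus, div, t5, t3, rng)
            copy_counter += 1
            cid = copy_counter
            # single-level nesting: a guest is inserted only into a host of a
            # DIFFERENT model, so the long-join situation is unambiguous
            candidates = [
                h for h in host_registry
                if h[3] != spec.name and h[2] - h[1] >= len(copy_seq) + 2 * 20
            ]
            nested = bool(
                spec.nesting_prob
                and candidates
                and rng.random() < spec.nesting_prob
            )
            if nested:
                host = candidates[int(rng.integers(0, len(candidates)))]
                hseq, hs, he, hmodel, hcid = host
                ins = int(rng.integers(hs + 20, he - 20 - len(copy_seq) + 1))
                _write_nested(
                    chroms[hseq], truth_feats, hseq, hs, he, ins,
                    copy_seq, spec, div, t5, t3, cid, hmodel, hcid,
                )
                host_registry.remove(host)
                continue
            start = _place(rng, occupied[chrom], len(chroms[chrom]), len(copy_seq), chrom)
            chroms[chrom][start : start + len(copy_seq)] = list(copy_seq)
            ident = identity_to(spec.consensus, copy_seq, offset=t5)
            truth_feats.append(
                Feature(
                    seqid=chrom,
                    source="synthetic",
                    feature_type="transposable_element",
                    start=start + 1,
                    end=start + len(copy_seq),
                    strand="+",
                    attributes={
                        "ID": f"copy{cid}",
                        "model": spec.name,
                        "te_type": spec.te_type,
                        "consensus": f"{spec.name}_cons",
                        "identity": f"{ident:.4f}",
                        "divergence": f"{div:.4f}",
                        "truncated_5p": str(t5),
                        "truncated_3p": str(t3),
                        "copy_id": str(cid),
                    },
                )
            )
            if t5 == 0 and t3 == 0:
                host_registry.append((chrom, start, start + len(copy_seq), spec.name, cid))

    # --- SSR arrays ------------------------------------------------------
    ssr_id = 0
    for spec in ssr_specs:
        for _ in range(spec.count):
            chrom = names[int(rng.integers(0, len(names)))]
            if spec.ssr_class == ssr_typing.SIMPLE_POLYA:
                unit = "A"
            elif spec.ssr_class == ssr_typing.SIMPLE_POLYC:
                unit = "C"
            else:
                unit = _random_primitive_unit(rng, spec.unit_length)
            arr_len = int(round(spec.unit_length * spec.copy_number))
            array = (unit * (int(spec.copy_number) + 2))[:arr_len]
            start = _place(rng, occupied[chrom], len(chroms[chrom]), arr_len, chrom)
            chroms[chrom][start : start + arr_len] = list(array)
            ssr_id += 1
            truth_feats.append(
                Feature(
                    seqid=chrom,
                    source="synthetic",
                    feature_type="tandem_repeat",
                    start=start + 1,
                    end=start + arr_len,
                    attributes={
                        "ID": f"ssr{ssr_id}",
                        "ssr_type": spec.ssr_class,
                        "unit_size": str(spec.unit_length),
                        "unit": unit,
                        "array_size": str(arr_len),
                        "copy_number": f"{spec.copy_number:g}",
                    },
                )
            )

    # --- N stretches (never inside planted repeats) ----------------------
    n_runs: Dict[str, List[Interval]] = {n: [] for n in names}
    if n_stretch_spec is not None:
        count, run_len = n_stretch_spec
        for chrom in names:
            for _ in range(count):
                start = _place(rng, occupied[chrom], len(chroms[chrom]), run_len, chrom)
                chroms[chrom][start : start + run_len] = ["N"] * run_len
                n_runs[chrom].append((start, start + run_len))
            n_runs[chrom].sort()

    # --- context features -------------------------------------------------
    context_feats: List[Feature] = []
    if gene_density > 0:
        gid = 0
        for chrom, L in zip(names, chrom_sizes):
            n_genes = max(1, int(round(gene_density * L / 1e6)))
            for _ in range(n_genes):
                glen = int(rng.integers(2000, 8001))
                if glen >= L:
                    continue
                gs = int(rng.integers(0, L - glen))
                gid += 1
                context_feats.append(
                    Feature(chrom, "synthetic", "gene", gs + 1, gs + glen,
                            attributes={"ID": f"gene{gid}"})
                )
                # two exons at the gene ends
                elen = max(200, glen // 8)
                for k, (es, ee) in enumerate(
                    [(gs, gs + elen), (gs + glen - elen, gs + glen)]
                ):
                    context_feats.append(
                        Feature(chrom, "synthetic", "exon", es + 1, ee,
                                attributes={"Parent": f"gene{gid}", "ID": f"gene{gid}.e{k+1}"})
                    )
                # a CpG-island-like and an S/MAR-like element near the gene
                for ftype, length in (("CpG_island", 645), ("SMAR", 444)):
                    fs = int(rng.integers(0, L - length))
                    context_feats.append(
                        Feature(chrom, "synthetic", ftype, fs + 1, fs + length)
                    )

    genome = {n: L for n, L in zip(names, chrom_sizes)}
    truth_feats.sort(key=lambda f: (f.seqid, f.start, f.end))
    return GenomeTruth(
        sequences={n: "".join(chroms[n]) for n in names},
        truth=AnnotationSet(truth_feats, genome),
        context=AnnotationSet(context_feats, genome),
        n_runs=n_runs,
        seed=seed,
    )


def _random_primitive_unit(rng: np.random.Generator, length: int) -> str:
    while True:
        unit = "".join(rng.choice(BASES, size=length))
        if ssr_typing._primitive(unit) and len(set(unit)) > 1:
            return unit


def _write_nested(
    chrom: List[str],
    truth_feats: List[Feature],
    seqid: str,
    hs: int,
    he: int,
    ins: int,
    guest_seq: str,
    guest_spec: RepeatModelSpec,
    div: float,
    t5: int,
    t3: int,
    guest_cid: int,
    host_model: str,
    host_cid: int,
) -> None:
    """Overwrite part of a host copy with a guest copy; the host's truth
    feature is replaced by two flanking features sharing its copy_id."""
    ge = ins + len(guest_seq)
    chrom[ins:ge] = list(guest_seq)
    # locate and split the host truth feature
    for i, f in enumerate(truth_feats):
        if f.get("copy_id") == str(host_cid) and f.seqid == seqid:
            attrs_left = dict(f.attributes)
            attrs_left["part"] = "1"
            attrs_right = dict(f.attributes)
            attrs_right["part"] = "2"
            left = Feature(seqid, f.source, f.feature_type, hs + 1, ins,
                           strand=f.strand, attributes=attrs_left)
            right = Feature(seqid, f.source, f.feature_type, ge + 1, he,
                            strand=f.strand, attributes=attrs_right)
            truth_feats[i : i + 1] = [left, right]
            break
    ident = identity_to(guest_spec.consensus, guest_seq, offset=t5)
    truth_feats.append(
        Feature(
            seqid, "synthetic", "transposable_element", ins + 1, ge, strand="+",
            attributes={
                "ID": f"copy{guest_cid}",
                "model": guest_spec.name,
                "te_type": guest_spec.te_type,
                "consensus": f"{guest_spec.name}_cons",
                "identity": f"{ident:.4f}",
                "divergence": f"{div:.4f}",
                "truncated_5p": str(t5),
                "truncated_3p": str(t3),
                "copy_id": str(guest_cid),
                "nested_in": str(host_cid),
            },
        )
    )
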