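"""Readers and writers for the annotation formats the pipeline exchanges.

GFF3 is the canonical dialect (1-based inclusive coordinates).  The reader is
tolerant: it also accepts GFF2-style ``key value`` attribute strings and maps
them onto the same key->value dictionary, because repeat annotators emit both
dialects.  BED is 0-based half-open and converted explicitly at this
boundary.  FASTA goes through Biopython.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, TextIO, Tuple
from urllib.parse import quote, unquote

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation_algebra import AnnotationSet, Feature


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_attributes(text: str) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    text = text.strip()
    if not text or text == ".":
        return attrs
    if "=" in text.split(";", 1)[0]:
        # GFF3 dialect: key=value;key=value
        for chunk in text.split(";"):
            chunk = chunk.strip()
            if not chunk:
                continue
            key, _, value = chunk.partition("=")
            attrs[unquote(key.strip())] = unquote(value.strip())
    else:
        # GFF2 dialect: key "value"; key value
        for chunk in text.split(";"):
            chunk = chunk.strip()
            if not chunk:
                continue
            key, _, value = chunk.partition(" ")
            attrs[key.strip()] = value.strip().strip('"')
    return attrs


def _format_attributes(attrs: Mapping[str, str]) -> str:
    if not attrs:
        return "."
    return ";".join(
        f"{quote(str(k), safe='')}={quote(str(v), safe=', ')}" for k, v in attrs.items()
    )


def read_gff3(path_or_handle, genome: Mapping[str, int] | None = None) -> AnnotationSet:
    """Parse a GFF3 (or attribute-tolerant GFF2) file into an AnnotationSet."""
    own = isinstance(path_or_handle, (str, Path))
    fh: TextIO = open(path_or_handle) if own else path_or_handle
    feats: List[Feature] = []
    region_sizes: Dict[str, int] = {}
    try:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) == 4:
                    region_sizes[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"line {lineno}: expected 9 columns, got {len(cols)}")
            feats.append(
                Feature(
                    seqid=cols[0],
                    source=cols[1],
                    feature_type=cols[2],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    score=cols[5],
                    strand=cols[6],
                    attributes=_parse_attributes(cols[8]),
                )
            )
    finally:
        if own:
            fh.close()
    return AnnotationSet(feats, genome if genome is not None else region_sizes)


def write_gff3(
    aset: AnnotationSet,
    path_or_handle,
    *,
    seed: int | None = None,
) -> None:
    """Write an AnnotationSet as GFF3, emitting sequence-region directives."""
    own = isinstance(path_or_handle, (str, Path))
    fh: TextIO = open(path_or_handle, "w") if own else path_or_handle
    try:
        fh.write("##gff-version 3\n")
        if seed is not None:
            fh.write(f"#!seed {seed}\n")
        for seqid in sorted(aset.genome):
            fh.write(f"##sequence-region {seqid} 1 {aset.genome[seqid]}\n")
        for f in aset.sorted():
            fh.write(
                "\t".join(
                    [
                        f.seqid,
                        f.source,
                        f.feature_type,
                        str(f.start),
                        str(f.end),
                        str(f.score),
                        f.strand,
                        ".",
                        _format_attributes(f.attributes),
                    ]
                )
                + "\n"
            )
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# BED (0-based half-open)
# ---------------------------------------------------------------------------

def read_bed(path_or_handle, genome: Mapping[str, int] | None = None) -> AnnotationSet:
    own = isinstance(path_or_handle, (str, Path))
    fh: TextIO = open(path_or_handle) if own else path_or_handle
    feats: List[Feature] = []
    try:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            seqid, start, end = cols[0], int(cols[1]), int(cols[2])
            name = cols[3] if len(cols) > 3 else "."
            strand = cols[5] if len(cols) > 5 else "."
            feats.append(
                Feature(
                    seqid=seqid,
                    source="bed",
                    feature_type=name,
                    start=start + 1,
                    end=end,
                    strand=strand,
                )
            )
    finally:
        if own:
            fh.close()
    return AnnotationSet(feats, genome or {})


def write_bed(aset: AnnotationSet, path_or_handle) -> None:
    own = isinstance(path_or_handle, (str, Path))
    fh: TextIO = open(path_or_handle, "w") if own else path_or_handle
    try:
        for f in aset.sorted():
            fh.write(f"{f.seqid}\t{f.start - 1}\t{f.end}\t{f.feature_type}\n")
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# FASTA and genome registries
# ---------------------------------------------------------------------------

def read_fasta(path) -> Dict[str, str]:
    """Load a FASTA file as a seqid -> sequence dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path, *, seed: int | None = None) -> None:
    """Write sequences 60 columns wide; the seed is recorded in descriptions."""
    desc = f"seed={seed}" if seed is not None else ""
    records = [
        SeqRecord(Seq(seq), id=name, description=desc)
        for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def genome_registry_from_fasta(path) -> Dict[str, int]:
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_chrom_sizes(path) -> Dict[str, int]:
    """Two-column <seqid> <length> size file."""
    out: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            name, size = line.split()[:2]
            out[name] = int(size)
    return out


def write_chrom_sizes(genome: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, size in genome.items():
            fh.write(f"{name}\t{size}\n")
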