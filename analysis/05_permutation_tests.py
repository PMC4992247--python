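#!/usr/bin/env python
"""Permutation tests: chromosomal enrichment of TE copies and hotspot scan.

Enrichment redistributes the genome-wide TE copy total across chromosomes
with probability proportional to the reduced genome (chromosome length minus
TE coverage) and calls a chromosome over-/under-represented outside the
1st/99th empirical percentiles.  The hotspot scan tiles each chromosome in
windows, re-places the copies uniformly over non-N space 1000 times, and
flags windows above the pooled 99th percentile.  The window is shrunk to
5 kb here because the simulated chromosomes are tens of kb, not tens of Mb.
"""

from pathlib import Path

from repeatscape import io, nmask, permutation_stats as ps

BASE = Path(__file__).resolve().parent.parent / "results"
SYN = Path(__file__).resolve().parent.parent / "scratch" / "synthetic"
OUT = BASE / "perm"
SEED = 2026
WINDOW = 5000


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = io.read_chrom_sizes(SYN / "genome.sizes")
    te = io.read_gff3(BASE / "te" / "te.gff3", genome)

    reduced = ps.reduced_genome(genome, te)
    counts = {c: 0 for c in genome}
    for f in te:
        counts[f.seqid] += 1
    enrich = ps.chromosome_enrichment(
        counts, reduced, n_perm=100000, alpha=0.01, seed=SEED
    )
    ps.results_to_frame(enrich).to_csv(OUT / "enrichment.tsv", sep="\t",
                                       index=False)

    runs: dict = {}
    for f in io.read_bed(SYN / "n_runs.bed"):
        runs.setdefault(f.seqid, []).append((f.start - 1, f.end))
    indices = nmask.nindex_from_runs(runs, genome)
    hot = ps.hotspot_scan(te, genome, indices, window=WINDOW,
                          n_perm=1000, alpha=0.01, seed=SEED)
    ps.results_to_frame(hot).to_csv(OUT / "hotspots.tsv", sep="\t", index=False)
    hotspots = [r for r in hot if r.call == ps.CALL_HOTSPOT]
    with open(OUT / "hotspots.bed", "w") as fh:
        for r in hotspots:
            chrom, span = r.unit.split(":")
            s, e = span.split("-")
            fh.write(f"{chrom}\t{int(s) - 1}\t{e}\thotspot\n")

    print("chromosome enrichment (100000 permutations, 1%/99% thresholds):")
    for r in enrich:
        print(f"  {r.unit}: observed {r.observed:.0f}, null "
              f"[{r.low_threshold:.0f}, {r.high_threshold:.0f}] -> {r.call}")
    print(f"hotspot scan ({WINDOW/1000:.0f}-kb windows, 1000 permutations): "
          f"{len(hotspots)}/{len(hot)} windows flagged")
    for r in hotspots:
        print(f"  {r.unit}: {r.observed:.0f} copies "
              f"(threshold {r.high_threshold:.0f})")


if __name__ == "__main__":
    main()
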