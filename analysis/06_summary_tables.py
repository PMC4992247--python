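#!/usr/bin/env python
"""Final summary: sizing formulas, genomic-context partition of TE bases,
copy densities, and the coverage arithmetic of the whole annotation.

The worked reference calculations (k-mer sizing of a Gbp-scale genome,
C-value conversion, coverage increase factors) are printed next to the
synthetic-genome results so the arithmetic path is the same one the tests
check.
"""

from pathlib import Path

from repeatscape import annotation_algebra as alg, io, summaries as sm

BASE = Path(__file__).resolve().parent.parent / "results"
SYN = Path(__file__).resolve().parent.parent / "scratch" / "synthetic"
OUT = BASE / "summary"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = io.read_chrom_sizes(SYN / "genome.sizes")
    te = io.read_gff3(BASE / "te" / "te.gff3", genome)
    dm = io.read_gff3(BASE / "dm" / "dm.gff3", genome)
    ssr = io.read_gff3(BASE / "ssr" / "ssr.gff3", genome)
    context = io.read_gff3(SYN / "context.gff3", genome)

    # context partition of TE+DM bases
    te_dm = alg.AnnotationSet(list(te) + list(dm), genome)
    genes = alg.AnnotationSet(
        [f for f in context if f.feature_type in ("gene", "exon")], genome)
    elements = alg.AnnotationSet(
        [f for f in context if f.feature_type in ("CpG_island", "SMAR")], genome)
    part = sm.context_partition(te_dm, genes, elements, flank=3000)
    with open(OUT / "context_partition.tsv", "w") as fh:
        fh.write("scheme\tbin\tbases\n")
        for bin_, v in part.gene_scheme.items():
            fh.write(f"gene\t{bin_}\t{v}\n")
        for bin_, v in part.element_scheme.items():
            fh.write(f"element\t{bin_}\t{v}\n")

    dens = sm.density(te_dm, genome, max_nested_span=5000)
    dens.to_csv(OUT / "density.tsv", sep="\t", index=False)

    cov_ssr = 100 * alg.union_coverage(ssr)
    cov_tedm = 100 * alg.union_coverage(te_dm)
    cov_overlap = 100 * alg.union_coverage(alg.intersect(ssr, te_dm))
    total = sm.coverage_union({"ssr": cov_ssr, "te_dm": cov_tedm},
                              {("ssr", "te_dm"): cov_overlap})

    print("reference calculations:")
    print(f"  oligo size for a 1.047-Gbp genome: "
          f"{sm.kmer_size(1_047_000_000)} nt")
    print(f"  C-value 1.25 pg = "
          f"{sm.round_half_up(sm.cvalue_to_bp(1.25) / 1e9, 3)} Gbp")
    print(f"  coverage increase factor 4.08/1.73 = {sm.fold_change(4.08, 1.73)}")
    print("synthetic genome:")
    print(f"  SSR coverage {cov_ssr:.3f}%, TE+DM {cov_tedm:.3f}%, "
          f"overlap {cov_overlap:.3f}%")
    print(f"  total annotated repeats (inclusion-exclusion): {total:.3f}%")
    print(f"  context partition of TE+DM bases: {part.gene_scheme} / "
          f"{part.element_scheme}")
    print(dens.to_string(index=False))


if __name__ == "__main__":
    main()
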