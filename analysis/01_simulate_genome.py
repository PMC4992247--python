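#!/usr/bin/env python
"""Simulate the study genome: a small multi-chromosome assembly with planted,
ground-truthed repeats.

Three chromosomes (70/50/30 kb) carry four TE models (an abundant LINE, an
LTR retrotransposon, a TIR DNA transposon that nests into other copies, and
an undetermined repeat), tandem arrays of every SSR class, N-stretch
assembly gaps, and gene/CpG/S-MAR-like context features.  Everything the
later stages consume is written under results/synthetic/.
"""

from pathlib import Path

import numpy as np

from repeatscape import io, ssr_typing as st, synthetic_genome as sg

OUT = Path(__file__).resolve().parent.parent / "scratch" / "synthetic"
SEED = 2026

CHROM_SIZES = [70000, 50000, 30000]


def build_specs():
    rng = np.random.default_rng(SEED)
    consensuses = {
        "CR1like": sg.random_sequence(rng, 1500),
        "LTRrem": sg.random_sequence(rng, 900),
        "TIRhop": sg.random_sequence(rng, 400),
        "Ugroup1": sg.random_sequence(rng, 300),
    }
    te_specs = [
        sg.RepeatModelSpec("CR1like", "LINE", consensuses["CR1like"], 14,
                           (0.0, 0.15), truncation_prob=0.4),
        sg.RepeatModelSpec("LTRrem", "LTR", consensuses["LTRrem"], 8,
                           (0.0, 0.10)),
        sg.RepeatModelSpec("TIRhop", "TIR", consensuses["TIRhop"], 10,
                           (0.0, 0.05), nesting_prob=0.4),
        sg.RepeatModelSpec("Ugroup1", "undetermined", consensuses["Ugroup1"], 6,
                           (0.0, 0.20)),
    ]
    ssr_specs = [
        sg.SsrPlantSpec(st.SIMPLE_POLYA, 1, 60, 3),
        sg.SsrPlantSpec(st.SIMPLE_POLYC, 1, 55, 2),
        sg.SsrPlantSpec(st.MICROSATELLITE, 4, 70, 4),
        sg.SsrPlantSpec(st.MINISATELLITE, 20, 55, 3),
        sg.SsrPlantSpec(st.LARGE_TANDEM_REPEAT, 80, 5, 2),
        sg.SsrPlantSpec(st.SATELLITE, 80, 55, 1),
    ]
    return te_specs, ssr_specs, consensuses


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    te_specs, ssr_specs, consensuses = build_specs()
    gt = sg.generate_genome(
        CHROM_SIZES, te_specs, ssr_specs,
        n_stretch_spec=(2, 500), gene_density=40, seed=SEED,
    )
    io.write_fasta(gt.sequences, OUT / "genome.fasta", seed=SEED)
    io.write_fasta({f"{m}_cons": c for m, c in consensuses.items()},
                   OUT / "consensus.fasta", seed=SEED)
    io.write_gff3(gt.truth, OUT / "truth.gff3", seed=SEED)
    io.write_gff3(gt.context, OUT / "context.gff3", seed=SEED)
    io.write_chrom_sizes(gt.genome, OUT / "genome.sizes")
    with open(OUT / "n_runs.bed", "w") as fh:
        for chrom, runs in gt.n_runs.items():
            for s, e in runs:
                fh.write(f"{chrom}\t{s}\t{e}\tN_run\n")

    planted = sum(f.length for f in gt.truth)
    genome = sum(gt.genome.values())
    n_te = sum(1 for f in gt.truth if f.feature_type == "transposable_element")
    n_ssr = sum(1 for f in gt.truth if f.feature_type == "tandem_repeat")
    print(f"genome: {genome} bp over {len(gt.genome)} chromosomes")
    print(f"planted: {n_te} TE features, {n_ssr} SSR arrays, "
          f"{planted / genome:.2%} of the genome")
    print(f"N-gaps: {sum(len(r) for r in gt.n_runs.values())} runs of 500 bp")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
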