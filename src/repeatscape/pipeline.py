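"""Orchestrate the five-step repeat-annotation flow.

1. estimate the overall repeat content (an external oligo-counting tool;
   here we record the k-mer size it would use and optionally consume its
   BED output),
2. detect and classify SSRs (TRF externally, or the exact-tandem detector
   on synthetic genomes),
3. consume a TE annotation (externally produced by a consensus pipeline, or
   the synthetic truth track) and defragment it: stack resolution,
   juxtaposition merging, 20-bp minimum copy size, long-join copy counting,
4. mine the dark matter with conserved copies as probes and subtract
   everything already annotated,
5. merge an optional CNV annotation.

Every stage logs feature counts in/out; a machine-readable run manifest
(inputs, config, seed) and a final Venn coverage table are written to the
output directory.  A fixed seed makes the whole run deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from . import annotation_algebra as alg
from . import dm_mining, io, nmask, ssr_typing, summaries, synthetic_genome

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline thresholds, at their standard defaults."""

    genome_fasta: Optional[str] = None
    te_gff: Optional[str] = None
    trf_dat: Optional[str] = None
    cnv_gff: Optional[str] = None
    repeat_estimate_bed: Optional[str] = None
    out_dir: str = "pipeline_out"
    seed: int = 0

    # TRF invocation parameters (recorded; TRF itself is external)
    trf_parameters: tuple = ssr_typing.TRF_PARAMETERS
    min_ssr_units: float = 50
    tandem_max_unit: int = 60  # unit-size ceiling for the exact-tandem stand-in
    min_copy_len: int = 20
    probe_min_len: int = 500
    probe_min_identity: float = 0.80
    dm_seed_k: int = dm_mining.DEFAULT_SEED_K
    dm_min_hit_identity: float = dm_mining.DEFAULT_MIN_HIT_IDENTITY
    dm_min_hit_len: int = dm_mining.DEFAULT_MIN_HIT_LEN
    max_gap: int = 0
    max_nested_span: int = 50000
    hotspot_window: int = 50000
    n_perm_enrichment: int = 100000
    n_perm_hotspot: int = 1000
    missing_input: str = "skip"  # or "fail"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "trf_parameters" in data:
            data["trf_parameters"] = tuple(data["trf_parameters"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["trf_parameters"] = list(self.trf_parameters)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def run_pipeline(
    config: PipelineConfig,
    genome_truth: synthetic_genome.GenomeTruth | None = None,
) -> Path:
    """Run the five steps and write GFF3/BED/TSV artifacts plus an audit log.

    ``genome_truth`` short-circuits file inputs for synthetic runs: the
    simulated sequences stand in for the genome and the truth track for the
    external TE annotation.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    audit: list[dict] = []
    manifest: Dict[str, object] = {"seed": config.seed, "inputs": {}}

    def log_stage(stage: str, n_in: int, n_out: int, **extra) -> None:
        entry = {"stage": stage, "features_in": n_in, "features_out": n_out, **extra}
        audit.append(entry)
        logger.info("%s: %d -> %d %s", stage, n_in, n_out, extra or "")

    # --- inputs ----------------------------------------------------------
    if genome_truth is not None:
        sequences = genome_truth.sequences
        genome = genome_truth.genome
    elif config.genome_fasta:
        sequences = io.read_fasta(config.genome_fasta)
        genome = {n: len(s) for n, s in sequences.items()}
        manifest["inputs"]["genome_fasta"] = str(config.genome_fasta)
    else:
        raise ValueError("no genome provided (genome_fasta or genome_truth)")

    # --- step 1: overall repeat estimate ---------------------------------
    k = summaries.kmer_size(sum(genome.values()))
    step1 = None
    if config.repeat_estimate_bed:
        step1 = io.read_bed(config.repeat_estimate_bed, genome)
        manifest["inputs"]["repeat_estimate_bed"] = str(config.repeat_estimate_bed)
    log_stage("step1_repeat_estimate", 0, len(step1) if step1 else 0, kmer_size=k)

    # --- step 2: SSRs -----------------------------------------------------
    if config.trf_dat:
        with open(config.trf_dat) as fh:
            arrays = ssr_typing.parse_trf_dat(fh)
        manifest["inputs"]["trf_dat"] = str(config.trf_dat)
    else:
        # exact-tandem detection on N-stripped sequence, restored afterwards
        arrays = []
        for name, seq in sequences.items():
            stripped, idx = nmask.build_index(seq)
            for a in ssr_typing.find_exact_tandems(
                stripped, max_unit=config.tandem_max_unit, min_copies=2
            ):
                pieces = nmask.restore_interval(idx, (a.start - 1, a.end))
                if len(pieces) == 1:
                    a.seqid = name
                    a.start, a.end = pieces[0][0] + 1, pieces[0][1]
                    arrays.append(a)
    ssr_typing.classify_all(arrays, min_units_small=config.min_ssr_units)
    retained = [a for a in arrays if a.ssr_class != ssr_typing.REJECTED]
    ssr_set = ssr_typing.to_gff(retained, genome)
    io.write_gff3(ssr_set, out / "ssr.gff3", seed=config.seed)
    log_stage("step2_ssr", len(arrays), len(ssr_set))

    # --- step 3: TE annotation defragmentation ---------------------------
    if genome_truth is not None:
        te_raw = alg.AnnotationSet(
            [f for f in genome_truth.truth if f.feature_type == "transposable_element"],
            genome,
        )
    elif config.te_gff:
        te_raw = io.read_gff3(config.te_gff, genome)
        manifest["inputs"]["te_gff"] = str(config.te_gff)
    elif config.missing_input == "fail":
        raise ValueError("no TE annotation provided")
    else:
        logger.warning("step 3 skipped: no TE annotation")
        te_raw = alg.AnnotationSet([], genome)

    te_res = alg.resolve_stacks(te_raw)
    log_stage("step3_resolve_stacks", len(te_raw), len(te_res))
    te_merged = alg.merge_juxtaposed(te_res, max_gap=config.max_gap)
    log_stage("step3_merge_juxtaposed", len(te_res), len(te_merged))
    te_final = alg.filter_min_length(te_merged, min_len=config.min_copy_len)
    log_stage("step3_min_length", len(te_merged), len(te_final),
              removed=len(te_merged) - len(te_final))
    copies = alg.long_join_copies(te_final, max_nested_span=config.max_nested_span)
    copies.to_csv(out / "te_copies.tsv", sep="\t", index=False)
    io.write_gff3(te_final, out / "te.gff3", seed=config.seed)

    # --- step 4: dark matter ---------------------------------------------
    probes = dm_mining.select_probes(
        te_final, sequences,
        min_len=config.probe_min_len, min_identity=config.probe_min_identity,
    )
    if probes:
        io.write_fasta(
            {f"{p.model}_probe{i + 1}": p.sequence for i, p in enumerate(probes)},
            out / "probes.fasta",
            seed=config.seed,
        )
        hits = dm_mining.homology_scan(
            probes, sequences,
            seed_k=config.dm_seed_k,
            min_hit_identity=config.dm_min_hit_identity,
            min_hit_len=config.dm_min_hit_len,
        )
    else:
        hits = alg.AnnotationSet([], genome)
    known = alg.AnnotationSet(list(te_final) + list(ssr_set), genome)
    dm = dm_mining.subtract_known(hits, known)
    dm = alg.filter_min_length(dm, min_len=config.min_copy_len)
    dm = dm_mining.classify_dm(dm, te_final)
    io.write_gff3(dm, out / "dm.gff3", seed=config.seed)
    log_stage("step4_dark_matter", len(hits), len(dm), n_probes=len(probes))

    # --- step 5: CNV merge ------------------------------------------------
    if config.cnv_gff:
        cnv = io.read_gff3(config.cnv_gff, genome)
        manifest["inputs"]["cnv_gff"] = str(config.cnv_gff)
    else:
        cnv = alg.AnnotationSet([], genome)
    log_stage("step5_cnv", len(cnv), len(cnv))

    # --- final coverage accounting ---------------------------------------
    te_dm = alg.AnnotationSet(list(te_final) + list(dm), genome)
    named = {"SSR": ssr_set, "TE+DM": te_dm, "CNV": cnv}
    if step1 is not None:
        named["ESTIMATE"] = step1
    venn = alg.venn_coverage(named)
    venn_rows = [
        {"region": "&".join(sorted(k)), "coverage_percent": 100 * v}
        for k, v in sorted(venn.items(), key=lambda kv: sorted(kv[0]))
    ]
    pd.DataFrame(venn_rows).to_csv(out / "venn_coverage.tsv", sep="\t", index=False)
    total_cov = alg.union_coverage(ssr_set, te_dm, cnv)
    summary = {
        "kmer_size": k,
        "ssr_coverage_percent": 100 * alg.union_coverage(ssr_set),
        "te_dm_coverage_percent": 100 * alg.union_coverage(te_dm),
        "cnv_coverage_percent": 100 * alg.union_coverage(cnv) if len(cnv) else 0.0,
        "total_repeat_coverage_percent": 100 * total_cov,
        "n_te_copies": 0 if copies.empty else int(len(copies)),
    }
    manifest["summary"] = summary
    manifest["audit"] = audit
    config.to_yaml(out / "config.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
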