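# Methods

This note records the models and procedures the package implements, the
parameters that matter, the design choices made where the design was open,
and what the synthetic-data tests do and do not demonstrate.

## Coordinate conventions

Internally every interval computation is 0-based, half-open. GFF3 features
(1-based, inclusive) and BED records (0-based, half-open) are converted
exactly once, at the I/O boundary in `repeatscape.io`. The GFF reader also
accepts GFF2-style `key value` attribute strings, because repeat annotators
emit both dialects; attributes are held as a flat key→value map.

## N-stretch stripping and restoration (`nmask`)

Assembly gaps are runs of `N`. Some oligo-counting repeat detectors
misread them (e.g. as stretches of `A`), flooding the output with false
A-rich annotations, so the wrapper strips all maximal N-runs before running
such a tool and lifts the resulting annotations back afterwards. The
`NIndex` stores the removed runs plus the original length; restoration is a
strictly increasing bijection on non-N positions. An annotation spanning a
removed run is **split** into the corresponding original-coordinate pieces
(flagged `split_at_gap`, sharing a `part_of` identifier) rather than
extended across the gap: the gap bases were never scored by the wrapped
tool, so bridging them would fabricate evidence. Case is preserved on
non-N bases; `n` and `N` are treated identically.

## SSR typing (`ssr_typing`)

TRF is external; its `.dat` dialect (`Sequence:` headers followed by
15-field detection records) is parsed as printed, and the invocation
parameters are recorded in the pipeline config as
Match,Mismatch,Delta,PM,PI,Minscore,MaxPeriod = 2,5,7,80,10,25,2000.

Classification is a total function over unit length and copy number; the
boundaries (1 / 2–10 / 11–60 / >60 bp; 50 units) are given in the README.
Two decisions where the convention was unstated:

* Fractional TRF copy numbers are compared directly to the thresholds:
  ≥ 50.0 retains a small-unit array, and strictly > 50.0 promotes a
  large-unit array to satellite. The retention inequality is non-strict
  and exposed as `min_units_small`.
* Simple repeats are sub-typed from the consensus unit alone (A/T → polyA,
  C/G → polyC).

Overlapping detections are all retained and classified independently;
de-duplication is interval algebra's job, since raw detections are loaded
before any selection. The distinct-unit count of the SSR table is an exact
(100 % identity) de-duplication, exposed as a helper; fuzzy clustering of
satellite families is out of scope.

`find_exact_tandems` is a quadratic brute-force detector of **perfect**
maximal tandem runs (leftmost-anchored, smallest primitive unit, fractional
final units allowed). It exists as the independent oracle and the stand-in
for TRF on synthetic genomes, where all planted arrays are perfect; it is
not a general tandem-repeat finder and tolerates no mismatches.

## Annotation algebra (`annotation_algebra`)

* **Stack resolution** is greedy per (chromosome, TE model): the
  priority-best feature survives and all same-model features overlapping it
  are dropped, repeated on the remainder. Priority: highest percent
  identity, then highest fraction of consensus covered, then longer
  interval, then lexicographic consensus name. The last two tie-breaks are
  this package's own choice — any deterministic rule works, and tests pin
  this one. Missing identity attributes are treated as 0 and logged.
* **Juxtaposition merging** fuses same-model features separated by at most
  `max_gap` (default 0 = bookended only; the upstream tool's gap is not
  documented anywhere, so it is configurable and logged). The fused feature
  records the constituent consensus names and a length-weighted identity.
* **Long-join counting**: two consecutive same-model fragments count as one
  copy when their gap is at most `max_nested_span` **and** at least 95 % of
  the gap's bases are covered by features of a different model. The
  gap-fill requirement distinguishes a host split by a nested insertion
  from two independent copies that merely have some repeat between them;
  without it, any same-model pair within the span limit on a dense
  annotation would be joined.
* **Set operations** (intersect, subtract, union coverage, Venn partition
  of named sets) have base-level semantics, verified against a per-base
  bitmap oracle, and independently cross-checked against `bedtools` on a
  small fixture. Strand is ignored for set arithmetic (repeat coverage is
  strand-agnostic) and preserved on surviving features.
* The coverage denominator is the full registered sequence length,
  including N bases — coverage percentages refer to the assembly as
  published, gaps and all.

## Dark-matter mining (`dm_mining`)

Probe selection is strict on length (> 500 bp) and non-strict on identity
(≥ 0.80), reading the feature's recorded identity-to-consensus attribute.
The homology scanner is this package's explicitly specified stand-in for a
full annotation engine: exact k-mer seeding (k = 11, both strands),
ungapped extension with +1/−1 scoring and X-drop 20, hit acceptance at
identity ≥ 0.60 over ≥ 20 bp (matching the 20-bp copy floor). It finds
substitution-diverged copies; it cannot cross indels, which is acceptable
on the substitution-only synthetic genomes and a stated limitation on real
data. Hits are collapsed per model; subtraction of the known annotation is
base-level, so the dark matter is disjoint from it by construction. A
segment within `adjacency_gap` (default 0 = abutting) of a same-model
annotation is labelled `extended`, otherwise `new`.

Validation is by recall on planted copies: with copies at 15 % divergence,
at least 90 % of planted bases are recovered at the default thresholds.
At 15 % divergence the chance of an intact 11-mer at a given offset is
0.85¹¹ ≈ 0.17, so a 600-bp copy carries ~100 expected seeds; the X-drop of
20 against a +0.7/base expected score drift makes premature termination
rare.

## Permutation tests (`permutation_stats`)

* **Enrichment.** The null for copy counts is a multinomial over
  chromosomes with probabilities proportional to reduced sizes — the
  natural formalisation of dropping the genome-wide total uniformly into
  the reduced genome. Coverage mode assigns each element (its observed
  length) to a chromosome with the same probabilities and sums lengths.
  Calls use strict inequalities against the empirical 1st/99th percentiles
  (a central-98 % box); `n_perm` < 100 is refused because such thresholds
  are meaningless. Discreteness of counts makes the realised type-I rate
  slightly conservative; the calibration test budgets for this by checking
  the two-tailed rate within three Monte-Carlo standard deviations of 2 %.
* **Hotspots.** Windows are non-overlapping tiles from position 1; a final
  short window is kept (truncated) and a window more than half N is
  excluded from observed and null tallies — the N accounting had to be
  decided here, and exclusion avoids calling depleted gaps "cold" or their
  flanks "hot". Each permutation re-places the chromosome's copies,
  lengths preserved, uniformly over non-N positions without overlap
  (rejection sampling, capped at 10⁶ attempts per permutation; exceeding
  the cap raises with a hint that coverage is too high for non-overlap
  placement). Null window counts are pooled per chromosome — one
  threshold per chromosome, matching a per-chromosome detection question —
  and a copy belongs to the window containing its start. All randomness
  flows through a single seeded numpy generator recorded in every result.

## Summaries (`summaries`)

Reported tables round half-up to each column's printed precision
(2–4 decimals); machine outputs keep full precision. "Genic" means gene
span minus exons, with priority exon > genic > intergenic, and the element
scheme uses inside > 3-kbp flank > rest with flanks clipped at chromosome
ends and at the elements themselves; both schemes partition the annotated
TE bases exactly, which the tests verify against the bitmap oracle.
Densities count long-joined copies once. The k-mer sizing rule and the
0.978 Gbp/pg C-value conversion are exposed as functions because campaign
calibration starts from them.

## Synthetic genomes (`synthetic_genome`)

The generator emulates the *structure* a repeat annotator faces:
i.i.d. uniform background (configurable GC), TE copies with per-copy
divergence drawn from a model-specific range, optional 5′/3′ truncation,
single-level nesting (a guest of a **different** model inserted inside a
full-length host, splitting the host into two truth features sharing a copy
identifier — the long-join situation), planted tandem arrays of every SSR
class, N-stretches placed after and never inside repeats, and gene/CpG/
S-MAR-like context features on a separate track. Mutation is
substitution-only, so truth identities are exact per-base quantities; the
deliberate omissions — indels, CpG-biased mutation, phylogenetically
structured subfamilies, non-uniform insertion preferences — mean that
passing tests demonstrate correctness of the bookkeeping, thresholds and
statistics, not detector performance on realistic sequence evolution.
Placement is uniform rejection sampling; infeasible packing fails
explicitly, naming the chromosome.

The analysis scripts run the whole study on a 150-kb, three-chromosome
genome with four TE models (38 copies), fifteen SSR arrays spanning all six
classes, six 500-bp N-gaps and ~25 % planted repeat content; the hotspot
window is shrunk to 5 kb there because the simulated chromosomes are tens
of kb rather than tens of Mb. These sizes keep every script and the full
test suite in the tens-of-seconds range while leaving dozens of features
per stage; all thresholds retain their standard defaults.

## Known limitations

* The homology scanner is ungapped; indel-diverged copies fragment into
  multiple hits or are missed.
* GFF3 handling is deliberately flat: Parent/ID hierarchies are carried as
  attributes but not validated as an ontology.
* The exact-tandem oracle is quadratic and only suitable for test-scale
  sequences; real detection should use TRF with the recorded parameters.
* Rejection-sampling placement becomes slow as element coverage of a
  chromosome approaches the packing limit; the attempt cap turns this into
  an explicit error rather than a hang.
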