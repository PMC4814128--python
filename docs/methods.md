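# Methods

## The prediction model

`dmgfinder` treats marker prediction as set subtraction under a sequence
similarity relation. A gene family is a diagnostic marker for target group
A against background group B when (i) a member is annotated in at least a
chosen fraction of A genomes and (ii) no member has a background
counterpart above the similarity thresholds — checked against both the B
ORF sets *and* the raw B genome sequences, because background annotation
cannot be trusted: a gene may be present in a B contig yet missing from
B's gene calls (uncalled, or split by a frameshift from a sequencing
error). Similarity is always expressed as percent identity plus query
coverage of the best local alignment; there is no E-value model, because
every decision the cascade makes is a threshold on identity/coverage and
the high-identity regime (≥ 80%) makes alignment score statistics
unnecessary.

Assumptions worth stating explicitly:

* ORF sets are the unit of comparison — the tool finds discriminating
  *genes*, not arbitrary genomic regions. Consistent annotation of the
  *target* group matters (the equalizer exists to repair it); background
  annotation quality does not, thanks to the genome filter.
* A family is removed if *any* member trips a background filter. A marker
  must discriminate for every allele, so the conservative rule is the
  correct one for PCR assay design.
* Coverage is computed from the single best local alignment per
  query–subject pair, without HSP tiling. A gene split into two distant
  alignments therefore does not count as covered — which is the desired
  behaviour for step 1 (the dc mode exists to bridge *small* internal
  gaps).

## Tunable parameters

| setting | default | meaning |
|---|---|---|
| `megablast_perc_identity_cut` | 95 (%) | identity threshold of steps 1–3; also the identity floor of the step-5 screen |
| `query_cov_cut` / `subject_cov_cut` | 95 / 95 (%) | coverage thresholds; subject coverage applies only where the subject is a gene (steps 1, 3, equalizer ORF screen) |
| `min_occurrence` | 1.0 (fraction) | minimum share of A genomes carrying a family; inclusive (0.02 on 50 genomes keeps singletons) |
| `dc_perc_identity_cut` / `dc_query_cov_cut` | 80 / 60 (%) | step-4 removal thresholds; must not exceed the primary cuts, since step 4 is the *more sensitive* screen |
| `max_blastn_len_cut` | 100 (bp) | step-5 removal threshold on the length of high-identity background hits |
| `mode` | `dna` | `dna`, `dc`, `protein`, `mut_dna`, `mut_protein` |
| `backend` | `builtin` | `builtin` seed-and-extend or `external` NCBI BLAST+ |

Defaults for the dc and short-hit screens are this package's choices,
surfaced in the config and echoed verbatim into every run's settings file.
The 80/60 dc default removes diverged homologs (a family that merely
*resembles* background DNA over most of its length is a poor PCR target)
while leaving genuinely unique genes untouched; 100 bp for step 5 is on
the order of a primer-pair footprint, so any surviving family can host a
primer pair in unique sequence.

## The alignment engine

The builtin engine is seed-and-extend: exact k-mer seeding on both strands
(word size 28 for the primary nucleotide search, 11 for the sensitive and
the short-hit searches, 3 for protein), seeds grouped into diagonal bands
(cluster gap 40), and gapped extension of the query inside the banded
subject window. Extension computes a minimal-edit path (edlib) and
rescores its columns under the engine scoring — nucleotide match +1,
mismatch −2, gap open −5, extend −2; protein BLOSUM62, gap −11/−1 — then
keeps the best-scoring contiguous sub-path as the local hit (a maximum-sum
subsegment over column scores, so ragged ends are trimmed exactly as a
score-maximising local aligner would). Two design points:

* **Two-hit seeding** for word sizes below 16: a random 200 kb contig
  shares many isolated 11-mers with any kilobase query, and requiring two
  seeds in one band suppresses that noise at no sensitivity cost for the
  ≥ 80%-identity homologs the cascade cares about.
* **Exact-containment fast path**: a query found verbatim in a subject
  (either strand) short-circuits extension. On realistic inputs most
  step-1 comparisons are exact (shared core genes), which is what makes
  the pipeline fast without an external aligner.
* The sensitive `dc_like` task is emulated by the small word size and
  gap-tolerant banding rather than by true discontiguous seed templates;
  the cascade only needs its higher sensitivity for diverged homologs and
  small internal gaps, and the emulation is validated against the exact
  oracle in the tests.

`dp_align_oracle` is a full-matrix Smith–Waterman under the identical
scoring (via biotite's C implementation, guarded to 20 kb combined
length). It is used only in tests and in the generator's identity
verification, never on the production path, so engine-vs-oracle checks
remain a genuine dual route. `N` never counts as a match anywhere;
ambiguity codes other than N are mapped to N on input with a warning.

Residual-hit annotation uses small noise floors (dc residuals: score ≥ 20;
short-hit residuals: length ≥ 30 columns) so that `dc_blast_hit` and
`max_blastn` report biologically meaningful leftover similarity instead of
chance word matches against hundreds of kilobases of background. Family
*removal* is governed solely by the configured thresholds; the floors only
affect annotation columns.

## Ties, ordering, degenerate inputs

All output is deterministic: strains sort lexicographically at load time;
family ids are assigned ascending by (representative strain, contig,
start); the representative is the longest member with ties to the
smallest ORF id; multi-copy members are listed with ascending coordinates;
hit tables sort by (query, descending score, subject, position). Identical
inputs and config produce byte-identical output files. An empty candidate
set at any stage short-circuits into a well-formed empty result (exit code
0); an empty *target* ORF set is an error.

## The annotation equalizer

For each strain S and each ORF annotated in another strain of the group:
if it has no passing hit in S's ORF set but does have one in S's genome,
the best hit's subject span is extracted (strand-resolved, unextended —
no lengthening or frame repair, since the goal is to let the gene
participate in comparisons, not to re-annotate it) and appended to S's
ORFs with a marker token in the annotation. Additions overlapping by more
than 50% reciprocally on the same strand collapse to the best-identity
one, preventing combinatorial duplicates when many strains share the
missing gene. The procedure is idempotent and added sequences are exact
substrings (or reverse complements) of the strain's own contigs — both
properties are asserted in the tests.

## Validation statistics

The Fisher exact test is the standard two-sided exact enumeration (sum of
point hypergeometric probabilities not exceeding the observed one, with
the usual 1+1e-7 relative tolerance on the comparison), computed via
scipy and cross-checked in the tests against an independent brute-force
enumeration for all small tables. Spearman's rho uses mid-rank ties with
a two-sided t-approximation for the 95% significance call — sufficient
because downstream use is only the significant/NS dichotomy. The ordinal
spoilage-potential encoding NB < WB < MB < SB maps to 0..3 and a strain
counts as a spoiler from rank 2 (MB) upward; the encoding is exposed
because published tables never print theirs.

## What the synthetic generator emulates — and what it does not

The generator plants, into i.i.d. random genomes at a chosen GC (default
0.40), one gene class per failure mode of real comparative data: shared
core genes; target-exclusive genes (the planted truth, placed on a
plasmid, mirroring where spoilage-associated genes actually live);
partial-occurrence genes; genes embedded unannotated (or with a 1 bp
frameshifting deletion) in a background contig; background homologs at a
verified target identity (default 0.85, checked against the exact oracle
to ±1 point with bounded resampling); genes containing an exact background
segment (default 150 bp); multi-copy genes; and genes annotated in only k
of the target genomes. Planted genes start with ATG and contain no
in-frame stops, so protein mode runs on the same fixtures.

It does **not** model repeats beyond the planted ones (ground truth would
become ill-defined), phylogenetic structure, codon bias, rearrangements,
or realistic intergenic architecture. Passing the recovery tests therefore
shows that the cascade's *logic* is correct under controlled conditions —
it does not certify recall on real genomes, where annotation quality and
repeat content dominate.

Reference problem sizes: the recovery checks run the default 2-vs-3
comparison at 200 kb chromosomes plus a 20 kb plasmid per genome
(~1.1 Mb total) over 20 seeds; the exact-oracle soundness check uses
14 kb genomes so whole contigs fit under the oracle's quadratic-cost
guard. Both sizes are the package's reference fixtures and are stated in
the acceptance script.

## Known limitations

* The builtin engine's hits are near-optimal, not provably optimal; the
  tests bound the deviation (identity within 0.5 points of the oracle on
  planted pairs, scores never above the optimum) and the pass/fail
  behaviour at the cascade's thresholds is what is actually guaranteed.
* Protein-level extension rescoring uses the edit-distance path as the
  alignment shape; for the ≥ 90% identity regimes the cascade operates in
  this is indistinguishable from an optimal BLOSUM62 alignment, but it
  would be inadequate for remote homology searching (out of scope).
* Mutation-level mode flags candidate substitution markers; it is not a
  SNP caller and does not attempt positional resolution.
* The occurrence filter counts genomes, not contigs; draft genomes with
  collapsed repeats can undercount copy numbers.
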