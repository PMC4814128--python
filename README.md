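# dmgfinder

Diagnostic marker gene (DMG) prediction for bacterial strain groups.

Many phenotypes of interest — a pathotype, the ability of lactic acid
bacteria to grow in and spoil beer, adaptation to a niche — track the
presence or absence of specific genes rather than species identity. Given
two phenotype-defined groups of annotated genomes, a **target group A**
(e.g. strong beer spoilers) and a **background group B** (non-spoilers),
`dmgfinder` reports the gene families that are present in (nearly) all
A genomes and absent from every B genome. Those families are directly
usable as markers for PCR screening panels: the output includes one FASTA
per family with every allele, ready for consensus building and primer
design.

The intended users are microbiologists running applied comparative
genomics: the inputs are ordinary genome FASTA files (chromosome plus
plasmid contigs) and ORF FASTA files (all annotated coding sequences, DNA),
one pair per strain, paired by file name.

## Method

Prediction is a six-step filter cascade. Writing `id(q, S)` and
`cov(q, S)` for the percent identity and query coverage of the best local
alignment of a candidate ORF *q* against a sequence set *S*, and
`I = megablast_perc_identity_cut`, `C = query_cov_cut` (defaults 95/95):

1. **ORF filter** — discard every A-ORF *q* with
   `id(q, B_ORFs) ≥ I` and `cov(q, B_ORFs) ≥ C` (subject coverage is also
   required here, both sides being genes);
2. **genome filter** — discard survivors matching the B *genome*
   sequences at the same thresholds (no subject coverage; subjects are
   whole contigs). This catches genes that are present in B but
   unannotated or frameshifted there, so inconsistent background gene
   calling cannot create false markers;
3. **occurrence filter** — single-linkage cluster the survivors into
   families across A genomes (two ORFs are linked iff an alignment between
   them passes the same thresholds) and keep families present in at least
   `min_occurrence` of the A genomes (default 1.0);
4. **dc filter** (optional) — discard families with *long low-identity*
   background hits, using a more sensitive small-word search
   (`dc_perc_identity_cut`/`dc_query_cov_cut`, defaults 80/60); weaker
   residual hits are annotated per family (`dc_blast_hit = yes`);
5. **short-hit filter** (optional) — discard families with *short
   high-identity* background hits longer than `max_blastn_len_cut`
   (default 100 bp); the longest sub-threshold hit is reported as
   `max_blastn`;
6. **output** — representative FASTA, per-family FASTAs, a tabular report,
   gene × strain presence and copy-number matrices, a settings echo and
   the per-step survivor counts.

Alignment runs on a built-in seed-and-extend engine (exact k-mer seeding
on both strands, banded gapped extension) or, optionally, on an external
NCBI BLAST+ installation; every decision is expressed purely in identity
and coverage terms, so the two backends are interchangeable. Additional
modes: `dc` (sensitive search throughout steps 1–3), `protein`
(translated comparison at steps 1 and 3), `mut_dna`/`mut_protein`
(genes identical within A whose best B counterpart is similar but not
identical — candidate SNP markers), and a distribution mode (all genomes
vs a dummy background) that yields complete presence/copy-number matrices.

Two companion modules round the workflow off:

* **annotation equalizer** — adds, to each genome's ORF set, regions
  homologous to genes annotated in other genomes of the same group but
  missing from its own gene calls, so inconsistent annotation inside the
  *target* group does not hide markers;
* **validation** — scores marker presence/absence against a strain
  phenotype table: confusion counts, two-sided Fisher exact test and
  Spearman rank correlation against ordinal phenotype classes.

## Worked example

Generate a synthetic 2-vs-3 comparison with known ground truth (3 planted
target-exclusive genes, one multi-copy gene, shared core genes and one
decoy of every class), then run the pipeline:

```bash
printf 'n_core = 6\ngenome_len = 14000\nplasmid_len = 10000\ngene_len = 500, 800\n' > spec.txt
dmgfinder simulate --spec spec.txt --out demo --seed 42
dmgfinder run \
  --group-a-genomes demo/group_a/genomes --group-a-orfs demo/group_a/orfs \
  --group-b-genomes demo/group_b/genomes --group-b-orfs demo/group_b/orfs \
  --out demo/results
```

The run log shows the cascade at work:

```
step1_orf_filter: 18
step2_genome_filter: 14
step3_occurrence_filter: 6
step4_dc_filter: 5
step5_short_hit_filter: 4
4 DMG(s) written to demo/results
```

Reading the counts: 18 A-ORFs survive the background ORF comparison (the
shared core genes are gone); the genome filter removes 4 more (the decoy
genes that sit unannotated — one of them frameshifted — in a background
contig); clustering and the 100% occurrence requirement leave 6 families
(a half-occurrence gene drops out); the sensitive dc screen removes a
planted 85%-identity homolog, and the short-hit screen removes a gene
carrying a 150 bp exact background segment. The 4 reported families are
exactly the planted target-exclusive genes. `demo/results/DMG_table.tsv`
starts:

```
DMG_ID  percent_occurrence  dc_blast_hit  max_blastn  ORF_ID      ORF_length  annotation          contig     start  stop
DMG_1   100.0               no            0           A1|dmg_001  780         true_dmg protein 1  plasmid_1  351    1130
DMG_1   100.0               no            0           A2|dmg_001  780         true_dmg protein 1  plasmid_1  477    1256
```

One row per member ORF, family rows contiguous: `percent_occurrence` is
the share of target genomes carrying the family, `dc_blast_hit` and
`max_blastn` summarise residual sub-threshold background similarity, and
the coordinates are 1-based inclusive on the named contig.

Marker validation takes a presence matrix and a phenotype table:

```bash
dmgfinder validate --presence presence.tsv --phenotypes phenotypes.tsv --out stats.tsv
```

and reports, per marker, the Fisher exact P, Spearman's rho (`NS` when not
significant at the 95% level), the correct-discrimination percentage and
the false positive/negative counts, sorted by descending P.

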