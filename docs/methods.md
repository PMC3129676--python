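# Methods

This note documents the models, parameter choices and numerical decisions
behind `metaconserve`. It is organised pipeline-first: the synthetic
community generator, the read-to-gene assignment machinery, the derived
statistics, and the validation studies.

## Synthetic communities (`simdata`)

The generator emulates a paired DNA/RNA shotgun experiment on a microbial
community well enough to give every downstream estimator a known truth. It
deliberately does *not* model pyrosequencer homopolymer errors, chimeras,
or within-taxon population microdiversity; reads are exact substrings of
the environmental genes. Consequently, passing the recovery tests shows
that the estimators are correct under clean sampling, not that they are
robust to sequencing error.

**Reference panel.** `n_taxa` taxa each carry `genes_per_taxon` genes.
A fraction `core_fraction` (default 0.5) belongs to orthologous *core
families*: each family has a random-codon ancestor, and every taxon's copy
diverges from it by `intertaxon_divergence` (default 0.12 amino-acid
substitutions per site, so two taxa's orthologs sit near 78% identity —
comfortably above the 55% clustering threshold). Non-core genes are
taxon-unique random sequences. Every core gene additionally has a partner
in its taxon's *sister proteome*, diverged by `sister_divergence` (default
0.10, low enough that reciprocal best hits always clear 50 bits for genes
of typical length); non-core genes have no sister partner. Codons are
drawn uniformly per base with a target GC of `gc_content` (default 0.45,
ocean-like), rejecting stops. Gene lengths are normal
(`mean_gene_len_nt` 600, SD 120, floor 240, rounded to codons).

**Transcription.** The expression model is a zero-inflated lognormal: a
gene is transcriptionally active with probability `expressed_fraction`
(default 0.5); active genes draw i.i.d. lognormal(`mu`=0, `sigma`=1.5)
levels and active *non-core* genes are multiplied by `noncore_expr_boost`
(default 1.34, the published magnitude of the non-core excess). Silent
genes have level exactly 0. The zero-inflation is a deliberate design
choice: the expressed/non-expressed dichotomy of the analysis is
operational (transcripts detected or not), and genes that are simply off
under the sampled conditions are the natural source of the DNA-only
fraction. Core status and activity are coupled through
`core_expression_odds` (default 2): status is drawn once per core family
(orthologs share it) and per gene for non-core genes, with per-class
probabilities solved so the overall active fraction stays at
`expressed_fraction`. No quantitative expression distribution is published
for these communities; the lognormal is an assumption and is flagged as
such.

**Divergence.** Each gene receives a target amino-acid divergence drawn
normal around `divergence_expressed` (default 0.10) for active genes or
`divergence_nonexpressed` (default 0.20) for silent ones (SD
`divergence_sd` = 0.02, clipped to [0,1]), then realised by per-site
Bernoulli substitution at the codon level: a hit site receives a uniformly
random *different* amino acid whose codon is drawn with per-base weights
`gc_to_at_bias` (default 2) for A/T versus 1 for G/C. With bias 1 the
model is symmetric; with bias > 1 diverged (mostly silent) genes drift
AT-rich, which reproduces the direction of the published GC patterns (RNA
pool GC-enriched relative to DNA). The realised divergence per gene is
recorded as ground truth. `graded_divergence=True` switches to a
deterministic coupling for conservation-coupled experiments: active genes'
mean divergence interpolates linearly with expression rank from
`divergence_nonexpressed` (least expressed) to `divergence_expressed`
(most expressed).

**Reads.** DNA reads choose genes with probability ∝ taxon abundance ×
gene length (abundances default uniform), RNA reads ∝ expression level ×
gene length. Lengths are normal (`read_len_mean_nt` 200, SD 40, floor 60 —
FLX-like; an optional shorter RNA mean mimics the shorter transcript-pool
reads), start positions uniform, strands random. Contamination appends
`rrna_fraction` reads sampled from random rRNA reference sequences and
duplicates `duplicate_fraction` of the original reads verbatim, both
flagged, so the pool size is n·(1 + rrna + dup) up to rounding. All
randomness derives from the single `seed` through fixed-order spawned
streams; identical configs give byte-identical FASTA output.

## Preprocessing (`preprocess`)

rRNA filtering aligns each read (both strands) to the rRNA references
under a BLASTN-like scheme (match +1, mismatch −2, gap open 5 / extend 2,
ungapped Karlin–Altschul λ=1.28, K=0.46) and removes reads above 50 bits;
an 11-mer prefilter prunes candidate pairs (exact mode available).
Duplicate removal collapses exact sequence matches (both strands kept
distinct, first occurrence retained) — prefix artifacts are intentionally
not collapsed. ORFs are the longest stop-free translated segment of a read
across all six frames (minimum 20 aa, reads ≥ 60 nt); when several frames
tie for the maximal length the read's frame is genuinely ambiguous and all
tied segments are reported, with single-ORF consumers taking the first in
frame order +1..+3, −1..−3. No ab initio gene model is used: on clean
reads the longest-segment rule recovers the true-frame translation for
well over 95% of reads, and HSP-region counting (available in the
composition module) gives near-identical usage results.

## Translated search (`homology`)

Classic gapped-BLASTX constants: BLOSUM62, gap open 11 / extend 1 (a gap
of length n costs open + n·extend), λ=0.267, K=0.041,
bits = (λ·raw − ln K)/ln 2, cutoff 50 bits. One HSP (the best) per
read×gene; per-read top hits are the genes tying the maximal bit score
after rounding to 0.1 bit (float ties essentially never occur otherwise),
each weighted 1/n_tied so a read contributes one unit of evidence
everywhere counts appear. Identity is
100·identities/(aligned columns − gap columns); stops and unknown residues
map to X, which scores ≤ 0 against everything and never counts as an
identity. A k=4 amino-acid k-mer prefilter (≥ 3 shared k-mers) selects
candidate gene×frame pairs; any alignment able to clear 50 bits (raw ≈ 118,
roughly 26+ aligned residues) retains far more than 3 intact 4-mers, so
the prefilter is conservative in the regime that matters. Exact mode
(every gene × every frame) is what all oracle-equivalence tests run.

## Profiles and expression statistics (`expression`)

Weighted counts and weighted per-gene mean identities; detection is any
weighted count > 0; fractions SHARED / DNA_ONLY / RNA_ONLY; the expression
ratio follows the normalised-proportion formula and is defined only for
SHARED genes. Expression bins are nested by descending ratio with size
ceil(fraction·n) (ties broken by gene id); identity-by-HSP-length uses
10-residue bins with an open >100 bin; 95% CIs are normal approximations
over per-gene means and are flagged unreliable below 2 genes. Gene-level
(not read-level) averaging is used wherever the analysis speaks of
per-gene identity; t-tests treat genes as the unit of replication.

## Core genomes (`coregenome`)

Reciprocal best hits against the sister proteome at > 50 bits, ties broken
by identity then lexicographic id; self-identifiers are never matched.
Core representation compares the core share of the SHARED versus DNA_ONLY
fractions with a 2×2 Pearson chi-square (no continuity correction — counts
are large in intended use) and Bonferroni across taxa within a run; the
core/non-core expression comparison is a two-tailed Welch t-test on
expression ratios. Multi-strain intersection cores are out of scope; only
pairwise RBH is implemented.

## Database-independent clustering (`seqcluster`)

Greedy incremental clustering of pooled read ORFs: descending length
(ties lexicographic), join the *first* existing cluster whose
representative aligns at ≥ 55% gap-excluded identity over the aligned
region, else found a new cluster; representatives are therefore always the
longest member. Because an optimal local alignment between unrelated ORFs
routinely produces a short high-identity segment, the join additionally
requires ≥ 20 aligned (non-gap) columns and ≥ 28 bits (raw ≈ 61, reached by
a ~13-residue perfect match, so any biologically meaningful overlap
qualifies while length-≈10 noise segments do not). Shorter-sequence
coverage is deliberately not enforced. Divergence per cluster is the mean
identity of non-representative DNA members to the representative,
excluding singletons and clusters whose representative is the only DNA
sequence; an RNA-representative cluster with exactly one DNA member
records that member's identity. Cluster sizes count DNA members only.

## Composition (`composition`) and functional statistics (`funcstats`)

Synonymous-codon GC contents are computed from the standard genetic code
(61 sense codons; stops excluded from denominators). Usage counts run over
ORF translations by default (HSP columns optional), excluding sentinel
symbols. Proportional change is exactly ((p_RNA − p_DNA)/p_DNA)·100 with a
per-amino-acid 2×2 chi-square on residue counts and Bonferroni family of
20 per sample pair. Category abundances are weighted read counts as a
proportion of category-mapped reads within a fraction; direction
consistency across S samples compares the count of categories with an
identical nonzero sign (a zero change counts as inconsistent) against
C·2·(1/2)^S by a 1-df goodness-of-fit chi-square. Sample clustering is
average linkage on 1 − centered Pearson (scipy's `correlation` distance).

## Validation studies (`validation`) and problem sizes

The standard studies and their sizes, chosen to run in minutes on one CPU:

* **Gap recovery** — 4 taxa × 50 genes (200 genes), 12,000 DNA + 8,000 RNA
  reads, divergences 0.10/0.20: the SHARED − DNA_ONLY identity gap is
  recovered within ±2 points of the true 10. The residual downward bias
  (≈ 0.5 points) comes from local-alignment end-trimming, which inflates
  identity slightly more at higher divergence, and from the bit-50 cutoff
  selecting higher-identity alignments among short reads.
* **Core recovery** — 80 genes at core fraction 0.75, sister divergence
  0.10: RBH recovers the flagged core exactly.
* **Non-core boost** — 3 taxa × 60 genes, boost 1.34, σ=1.0: ratio of mean
  expression ratios (non-core/core, RBH-derived membership) recovers the
  boost up to lognormal Monte-Carlo error.
* **Oracle equivalence** — 50 seeded trials each for exact-mode search
  (≤ 1,000 read×gene pairs) and exact-mode clustering (≤ 20 sequences)
  against brute-force references that share only the published rules.
* **Bin monotonicity** — graded divergence 0.30→0.05, σ=2.0: mean identity
  is non-decreasing over the nested top-expression bins.
* **Cluster inversion** — 4 taxa × 25 genes, core fraction 0.6,
  core-expression odds 6: DNA-only clusters are internally more identical
  than mixed clusters, reproducing the database-independent inversion.
* **Null calibration** — 1,000 replicates: core-representation and
  composition chi-squares reject at the nominal 5% rate on null draws.

## Known limitations

Reads carry no sequencing error, so identity estimates are upper bounds
relative to real 454 data; the expression model is an assumption; E-values
are not computed (bit scores only); the clustering does not reproduce any
external tool's heuristics (word filters, banding) — it implements the
stated greedy rule exactly; hierarchical clustering tie-breaking follows
scipy's deterministic ordering, which matters only for exactly tied
distances.
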