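# metaconserve

Comparative analysis of **coupled metagenome (DNA) and metatranscriptome
(RNA) read sets** from microbial communities, centred on one question: do
expressed genes evolve more slowly than non-expressed genes in the wild?

The package is aimed at microbial ecologists and bioinformaticians working
with shotgun pyrosequencing-style read pools (one DNA FASTA and one RNA
FASTA per sample plus an annotated protein reference panel). It
reimplements the full analysis as a tested library and CLI, and ships a
synthetic community generator that provides ground truth for every
estimator.

## The method

Reads are assigned to reference genes by six-frame translated local
alignment (BLOSUM62, affine gaps, Karlin–Altschul bit scores). A read's
top hits are the gene(s) with the maximal bit score above 50 bits; ties
share weight 1/n. Percent identity is taken from the top HSP with gap
columns excluded. A reference gene is then

* **expressed** when it recruits reads in *both* pools (fraction `SHARED`),
* **non-expressed** when it appears in the DNA pool only (`DNA_ONLY`),

and its relative expression is the ratio

```
expression ratio = (RNA reads per gene / total matched RNA reads)
                 / (DNA reads per gene / total matched DNA reads)
```

On top of the per-gene profiles the package computes: identity gaps between
the expressed and non-expressed fractions; identity over nested
top-expression bins; reciprocal-best-hit core genomes against a sister
proteome (cutoff 50 bits) and core representation per fraction (chi-square);
a database-independent analysis that pools read ORFs and clusters them
greedily at 55% identity over the aligned region, typing clusters as
DNA-only / RNA-only / mixed and scoring DNA-member divergence to the
longest-member representative; amino-acid usage shifts
`((p_RNA − p_DNA)/p_DNA)·100` with per-residue chi-squares, organised by the
GC content of each amino acid's synonymous codons (e.g. Ala 0.83, Trp 0.67,
Ile 0.11); and average-linkage clustering of samples on 1 − centered
Pearson correlation.

The simulator (`metaconserve.simdata`) generates multi-taxon communities
with cross-taxon orthologous core families and taxon-unique accessory
genes, zero-inflated lognormal transcription with a high-expression
non-core tail, codon-level divergence from the reference that is lower for
transcribed genes, a GC→AT substitution bias, 454-like read lengths, and
rRNA/duplicate contamination — with every read carrying its ground-truth
origin.

## Worked example

A small end-to-end run (3 taxa × 30 genes, 1,500 DNA + 1,000 RNA reads, 5%
rRNA and 5% duplicate contamination, transcribed genes at 10% amino-acid
divergence from the panel versus 20% for silent genes):

```python
from metaconserve.simdata import CommunityConfig
from metaconserve.pipeline import run_pipeline

cfg = CommunityConfig(n_taxa=3, genes_per_taxon=30,
                      n_dna_reads=1500, n_rna_reads=1000,
                      rrna_fraction=0.05, duplicate_fraction=0.05, seed=7)
res = run_pipeline(cfg, outdir="demo_out")
print(res.summaries["fraction_identity"].round(1))
```

prints

```
     SHARED  DNA_ONLY  RNA_ONLY   ALL
DNA    91.1      83.6       NaN  87.5
RNA    90.9       NaN       NaN  90.9
```

i.e. genes detected in both pools are estimated at 91.1% mean identity to
the panel versus 83.6% for DNA-only genes — the pipeline recovers the
conservation gap imposed by the generator (at the default acceptance scale
of 200 genes / 20,000 reads the recovered gap is within ±2 points of the
true 10). The same run's database-independent clustering shows the
characteristic *inversion*: DNA-only clusters are internally more similar
(97.0%) than mixed clusters (93.9%), because non-expressed genes are
enriched in taxon-unique sequences that can only cluster with themselves:

```
       type  n_clusters  mean_identity
0  DNA_ONLY          93           97.0
1     MIXED          71           93.9
```

The packaged transcriptions of the published per-sample summary tables can
be summarised from the shell:

```
$ metaconserve published-summaries
RNA-DNA identity difference: mean 8.9, range 4.4-14.7 (n=12)
expressed vs non-expressed identity gap (DNA rows): 10.6
cluster identity difference (DNA-only - mixed, ocean rows): 5.3
ocean GC differences: RNA-DNA 6.0, DNA-only - shared 1.9
```

Other subcommands (`simulate`, `preprocess`, `search`, `profile`, `core`,
`cluster`, `composition`, `functional`, `report`) expose each pipeline
stage over plain FASTA/TSV files; see `metaconserve --help`.

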