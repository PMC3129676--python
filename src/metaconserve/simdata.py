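"""Synthetic microbial communities with paired DNA and RNA read pools.

The generator emulates the statistical structure assumed by the analysis
modules: several taxa whose gene complements split into an orthologous core
(families shared across taxa, each with a partner in an external sister
proteome) and taxon-unique non-core genes; transcription that is on for a
subset of genes with lognormal levels and a high-expression tail among
non-core genes; amino-acid divergence from the reference panel that is lower
for transcribed genes; codon-level substitution with a GC->AT bias;
shotgun read sampling proportional to gene length times genome abundance
(DNA) or transcript level (RNA) with pyrosequencer-like read lengths; and
rRNA plus exact-duplicate contamination.

Every read carries its ground-truth origin so that downstream estimates
(identity gaps, core percentages, expression ratios, taxon mixtures) can be
scored against the simulated truth.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.Data import CodonTable
from scipy.optimize import brentq

__all__ = [
    "CommunityConfig",
    "ReferencePanel",
    "EnvironmentalGene",
    "ReadRecord",
    "SimulatedSample",
    "build_panel",
    "assign_expression",
    "evolve_genes",
    "sample_reads",
    "spike_contaminants",
    "simulate_community",
]

_CODE = CodonTable.unambiguous_dna_by_id[1]
#: sense codon -> amino acid, standard genetic code
CODON_TO_AA = dict(_CODE.forward_table)
STOP_CODONS = tuple(_CODE.stop_codons)
SENSE_CODONS = tuple(sorted(CODON_TO_AA))
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _c, _a in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_a, ())
    AA_TO_CODONS[_a] = AA_TO_CODONS[_a] + (_c,)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


class ConfigError(ValueError):
    """Raised for out-of-range or inconsistent community parameters."""


@dataclass
class CommunityConfig:
    """Parameters of a simulated community and its paired read pools.

    Defaults are the study conditions used throughout the test-suite and the
    acceptance runs; see docs/methods.md for the rationale behind each value.
    """

    n_taxa: int = 4
    genes_per_taxon: int = 50
    core_fraction: float = 0.5
    mean_gene_len_nt: int = 600
    gene_len_sd_nt: float = 120.0
    min_gene_len_nt: int = 240
    # amino-acid divergence of the environmental population from the
    # reference panel, by expression status
    divergence_expressed: float = 0.10
    divergence_nonexpressed: float = 0.20
    divergence_sd: float = 0.02
    #: couple divergence continuously to expression rank within the
    #: transcribed genes (conservation increases with expression level)
    #: instead of the default two-level expressed/non-expressed model
    graded_divergence: bool = False
    # transcription model
    expr_lognormal_mu: float = 0.0
    expr_lognormal_sigma: float = 1.5
    expressed_fraction: float = 0.5
    core_expression_odds: float = 2.0
    noncore_expr_boost: float = 1.34
    # nucleotide composition
    gc_content: float = 0.45
    gc_to_at_bias: float = 2.0
    # community structure
    taxon_abundances: Optional[Sequence[float]] = None
    # read model (454 FLX-like)
    read_len_mean_nt: float = 200.0
    read_len_sd_nt: float = 40.0
    rna_read_len_mean_nt: Optional[float] = None
    min_read_len_nt: int = 60
    n_dna_reads: int = 5000
    n_rna_reads: int = 5000
    # contamination
    rrna_fraction: float = 0.0
    duplicate_fraction: float = 0.0
    n_rrna_refs: int = 2
    rrna_len_nt: int = 1500
    # orthology ground truth
    sister_divergence: float = 0.10
    intertaxon_divergence: float = 0.12
    # functional annotation
    n_categories: int = 10
    pathways_per_category: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1 or self.genes_per_taxon < 1:
            raise ConfigError("n_taxa and genes_per_taxon must be positive")
        for name in (
            "core_fraction",
            "expressed_fraction",
            "rrna_fraction",
            "duplicate_fraction",
            "gc_content",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        for name in (
            "divergence_expressed",
            "divergence_nonexpressed",
            "sister_divergence",
            "intertaxon_divergence",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.expr_lognormal_sigma < 0:
            raise ConfigError("expr_lognormal_sigma must be >= 0")
        if self.noncore_expr_boost < 1:
            raise ConfigError("noncore_expr_boost must be >= 1")
        if self.gc_to_at_bias < 1:
            raise ConfigError("gc_to_at_bias must be >= 1")
        if self.n_dna_reads < 0 or self.n_rna_reads < 0:
            raise ConfigError("read counts must be >= 0")
        if self.mean_gene_len_nt % 3 != 0:
            raise ConfigError("mean_gene_len_nt must be a multiple of 3")
        if self.taxon_abundances is not None:
            ab = np.asarray(self.taxon_abundances, dtype=float)
            if len(ab) != self.n_taxa:
                raise ConfigError("taxon_abundances length != n_taxa")
            if (ab < 0).any() or abs(ab.sum() - 1.0) > 1e-9:
                raise ConfigError("taxon_abundances must be a simplex vector")
            self.taxon_abundances = tuple(float(x) for x in ab)

    @property
    def abundances(self) -> np.ndarray:
        if self.taxon_abundances is None:
            return np.full(self.n_taxa, 1.0 / self.n_taxa)
        return np.asarray(self.taxon_abundances, dtype=float)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        if d["taxon_abundances"] is not None:
            d["taxon_abundances"] = list(d["taxon_abundances"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CommunityConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class ReferencePanel:
    """Reference protein database plus orthology/annotation ground truth.

    ``genes`` has one row per reference gene: gene_id, taxon_id, is_core,
    family_id, category_id, pathway_id, aa_seq, nt_seq.  ``sister_proteomes``
    maps each taxon to its sister taxon's protein set; every core gene has an
    ortholog there (``sister_pairs``: gene_id -> sister gene id) and non-core
    genes have none.
    """

    genes: pd.DataFrame
    sister_proteomes: dict[str, dict[str, str]]
    sister_pairs: dict[str, str]
    rrna_refs: list[str] = field(default_factory=list)

    @property
    def proteomes(self) -> dict[str, dict[str, str]]:
        out: dict[str, dict[str, str]] = {}
        for row in self.genes.itertuples():
            out.setdefault(row.taxon_id, {})[row.gene_id] = row.aa_seq
        return out

    def protein_db(self) -> dict[str, str]:
        return dict(zip(self.genes.gene_id, self.genes.aa_seq))

    def annotation(self) -> pd.DataFrame:
        return self.genes[
            ["gene_id", "taxon_id", "is_core", "category_id", "pathway_id"]
        ].copy()


@dataclass
class EnvironmentalGene:
    """One gene of the sampled (environmental) population."""

    gene_id: str
    taxon_id: str
    nt_seq: str
    aa_seq: str
    target_divergence: float
    realized_divergence: float
    expression_level: float = 0.0


@dataclass
class ReadRecord:
    """A single sequencing read with optional ground-truth provenance."""

    read_id: str
    pool: Optional[str]  # "DNA" | "RNA" | None
    nt_seq: str
    truth: Optional[tuple[str, str, int]] = None  # (gene_id, taxon_id, offset)
    is_rrna: bool = False
    is_duplicate: bool = False

    def __post_init__(self) -> None:
        self.nt_seq = self.nt_seq.upper()
        if len(self.nt_seq) == 0:
            raise ValueError(f"read {self.read_id} has empty sequence")


@dataclass
class SimulatedSample:
    """Bundle returned by :func:`simulate_community`."""

    config: CommunityConfig
    panel: ReferencePanel
    expression: pd.DataFrame  # gene_id, expressed, level
    genomes: dict[str, EnvironmentalGene]
    dna_reads: list[ReadRecord]
    rna_reads: list[ReadRecord]

    def truth_table(self) -> pd.DataFrame:
        rows = []
        expr = self.expression.set_index("gene_id")
        for g in self.genomes.values():
            rows.append(
                dict(
                    gene_id=g.gene_id,
                    taxon_id=g.taxon_id,
                    expressed=bool(expr.loc[g.gene_id, "expressed"]),
                    expression_level=g.expression_level,
                    target_divergence=g.target_divergence,
                    realized_divergence=g.realized_divergence,
                )
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sequence generation and evolution


def _random_codons(n_codons: int, gc: float, rng: np.random.Generator) -> list[str]:
    """Draw sense codons whose base composition targets GC fraction ``gc``."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    bases = np.array(list("ACGT"))
    out: list[str] = []
    while len(out) < n_codons:
        draw = rng.choice(bases, size=3 * (n_codons - len(out)), p=p)
        for i in range(0, len(draw), 3):
            codon = "".join(draw[i : i + 3])
            if codon not in STOP_CODONS:
                out.append(codon)
    return out[:n_codons]


def _codon_weights(bias: float) -> dict[str, np.ndarray]:
    """Per-amino-acid codon weights implementing the GC->AT replacement bias.

    A codon's weight is the product of per-base weights (A/T: ``bias``,
    G/C: 1), so with bias > 1 substitutions preferentially land on AT-rich
    codons, mimicking an underlying GC-to-AT mutational pressure.
    """
    w: dict[str, np.ndarray] = {}
    for aa, codons in AA_TO_CODONS.items():
        vals = np.array(
            [
                math.prod(bias if b in "AT" else 1.0 for b in codon)
                for codon in codons
            ]
        )
        w[aa] = vals / vals.sum()
    return w


def _evolve_codons(
    codons: list[str],
    divergence: float,
    rng: np.random.Generator,
    bias: float,
) -> tuple[list[str], float]:
    """Substitute amino acids at per-site rate ``divergence``.

    Each selected site receives a random *different* amino acid, whose codon
    is drawn with the GC->AT bias.  Returns the evolved codons and the
    realized amino-acid divergence.
    """
    weights = _codon_weights(bias)
    aas = sorted(AA_TO_CODONS)
    out = list(codons)
    hit = rng.random(len(codons)) < divergence
    n_changed = 0
    for i in np.flatnonzero(hit):
        old_aa = CODON_TO_AA[out[i]]
        choices = [a for a in aas if a != old_aa]
        new_aa = choices[rng.integers(len(choices))]
        codon_set = AA_TO_CODONS[new_aa]
        out[i] = codon_set[rng.choice(len(codon_set), p=weights[new_aa])]
        n_changed += 1
    return out, n_changed / len(codons) if codons else 0.0


def _translate_codons(codons: Sequence[str]) -> str:
    return "".join(CODON_TO_AA[c] for c in codons)


# ---------------------------------------------------------------------------
# panel construction


def build_panel(config: CommunityConfig) -> ReferencePanel:
    """Construct the reference protein panel and sister proteomes.

    Core genes form orthologous families: every taxon carries a copy of each
    family, diverged by ``intertaxon_divergence`` from a common ancestor, and
    each copy has a partner in that taxon's sister proteome diverged by
    ``sister_divergence``.  Non-core genes are taxon-unique random sequences
    with no sister partner.
    """
    ss = np.random.SeedSequence(config.seed).spawn(1)[0]
    rng = np.random.default_rng(ss)
    n_core = round(config.core_fraction * config.genes_per_taxon)
    n_genes = config.genes_per_taxon

    def gene_length() -> int:
        ln = rng.normal(config.mean_gene_len_nt, config.gene_len_sd_nt)
        n_cod = max(config.min_gene_len_nt // 3, int(round(ln / 3.0)))
        return n_cod

    # family ancestors for the core
    ancestors = [
        (_random_codons(gene_length(), config.gc_content, rng))
        for _ in range(n_core)
    ]
    categories = [f"K{k:02d}" for k in range(config.n_categories)]

    rows = []
    sister_proteomes: dict[str, dict[str, str]] = {}
    sister_pairs: dict[str, str] = {}
    for t in range(config.n_taxa):
        taxon = f"T{t:02d}"
        sister_proteomes[taxon] = {}
        for i in range(n_genes):
            gene_id = f"{taxon}_G{i:04d}"
            is_core = i < n_core
            if is_core:
                family = f"F{i:04d}"
                codons, _ = _evolve_codons(
                    ancestors[i], config.intertaxon_divergence, rng,
                    config.gc_to_at_bias,
                )
            else:
                family = gene_id
                codons = _random_codons(gene_length(), config.gc_content, rng)
            cat = categories[rng.integers(config.n_categories)]
            path = f"{cat}_p{rng.integers(config.pathways_per_category)}"
            nt = "".join(codons)
            rows.append(
                dict(
                    gene_id=gene_id,
                    taxon_id=taxon,
                    is_core=is_core,
                    family_id=family,
                    category_id=cat,
                    pathway_id=path,
                    aa_seq=_translate_codons(codons),
                    nt_seq=nt,
                )
            )
            if is_core:
                sis_id = f"S{t:02d}_G{i:04d}"
                sis_codons, _ = _evolve_codons(
                    codons, config.sister_divergence, rng, config.gc_to_at_bias
                )
                sister_proteomes[taxon][sis_id] = _translate_codons(sis_codons)
                sister_pairs[gene_id] = sis_id
    rrna_refs = [
        "".join(
            rng.choice(
                list("ACGT"),
                size=config.rrna_len_nt,
                p=[
                    (1 - config.gc_content) / 2,
                    config.gc_content / 2,
                    config.gc_content / 2,
                    (1 - config.gc_content) / 2,
                ],
            )
        )
        for _ in range(config.n_rrna_refs)
    ]
    return ReferencePanel(
        genes=pd.DataFrame(rows),
        sister_proteomes=sister_proteomes,
        sister_pairs=sister_pairs,
        rrna_refs=rrna_refs,
    )


# ---------------------------------------------------------------------------
# expression


def _class_probabilities(frac: float, core_frac: float, odds: float) -> tuple[float, float]:
    """Per-class expression probabilities (core, non-core).

    Solves for p_core/(1-p_core) = odds * p_non/(1-p_non) subject to
    core_frac*p_core + (1-core_frac)*p_non = frac.
    """
    if odds == 1.0 or core_frac in (0.0, 1.0):
        return frac, frac
    if frac in (0.0, 1.0):
        return frac, frac

    def f(p_non: float) -> float:
        o = odds * p_non / (1 - p_non)
        p_core = o / (1 + o)
        return core_frac * p_core + (1 - core_frac) * p_non - frac

    p_non = brentq(f, 1e-12, 1 - 1e-12)
    o = odds * p_non / (1 - p_non)
    return o / (1 + o), p_non


def assign_expression(
    panel: ReferencePanel, config: CommunityConfig
) -> pd.DataFrame:
    """Assign a relative transcription level to every panel gene.

    A gene is transcriptionally active with probability ``expressed_fraction``
    overall; core genes are more likely active by ``core_expression_odds``
    (status drawn once per core family so orthologs share it).  Active genes
    draw i.i.d. lognormal(mu, sigma) levels; active non-core genes are
    multiplied by ``noncore_expr_boost``.  Silent genes have level 0.
    """
    if config.expr_lognormal_sigma < 0:
        raise ConfigError("expr_lognormal_sigma must be >= 0")
    ss = np.random.SeedSequence(config.seed).spawn(2)[1]
    rng = np.random.default_rng(ss)
    p_core, p_non = _class_probabilities(
        config.expressed_fraction, config.core_fraction, config.core_expression_odds
    )
    genes = panel.genes
    family_status: dict[str, bool] = {}
    for fam in sorted(genes.loc[genes.is_core, "family_id"].unique()):
        family_status[fam] = bool(rng.random() < p_core)
    rows = []
    for row in genes.itertuples():
        if row.is_core:
            expressed = family_status[row.family_id]
        else:
            expressed = bool(rng.random() < p_non)
        if expressed:
            level = float(
                rng.lognormal(config.expr_lognormal_mu, config.expr_lognormal_sigma)
            )
            if not row.is_core:
                level *= config.noncore_expr_boost
        else:
            level = 0.0
        rows.append(dict(gene_id=row.gene_id, expressed=expressed, level=level))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# evolution of the sampled population


def evolve_genes(
    panel: ReferencePanel,
    config: CommunityConfig,
    expression: Optional[pd.DataFrame] = None,
) -> dict[str, EnvironmentalGene]:
    """Derive the environmental gene pool from the reference panel.

    Each gene's target amino-acid divergence is drawn around
    ``divergence_expressed`` (transcribed genes) or ``divergence_nonexpressed``
    (silent genes) and imposed by codon-level substitution with the GC->AT
    bias.  Ground-truth realized divergence is recorded per gene.
    """
    if expression is None:
        expression = assign_expression(panel, config)
    expr = expression.set_index("gene_id")
    ss = np.random.SeedSequence(config.seed).spawn(3)[2]
    rng = np.random.default_rng(ss)
    rank_pct: dict[str, float] = {}
    if config.graded_divergence:
        active = expr[expr["expressed"]]["level"].sort_values()
        n_active = len(active)
        for i, gid in enumerate(active.index):
            rank_pct[gid] = i / (n_active - 1) if n_active > 1 else 1.0
    out: dict[str, EnvironmentalGene] = {}
    for row in panel.genes.itertuples():
        expressed = bool(expr.loc[row.gene_id, "expressed"])
        if config.graded_divergence and expressed:
            # most expressed -> divergence_expressed, least -> _nonexpressed
            u = rank_pct[row.gene_id]
            mean_d = config.divergence_nonexpressed + u * (
                config.divergence_expressed - config.divergence_nonexpressed
            )
        elif expressed:
            mean_d = config.divergence_expressed
        else:
            mean_d = config.divergence_nonexpressed
        target = float(np.clip(rng.normal(mean_d, config.divergence_sd), 0.0, 1.0))
        codons = [row.nt_seq[i : i + 3] for i in range(0, len(row.nt_seq), 3)]
        evolved, realized = _evolve_codons(codons, target, rng, config.gc_to_at_bias)
        out[row.gene_id] = EnvironmentalGene(
            gene_id=row.gene_id,
            taxon_id=row.taxon_id,
            nt_seq="".join(evolved),
            aa_seq=_translate_codons(evolved),
            target_divergence=target,
            realized_divergence=realized,
            expression_level=float(expr.loc[row.gene_id, "level"]),
        )
    return out


# ---------------------------------------------------------------------------
# read sampling


def _draw_read(
    seq: str,
    mean_len: float,
    sd_len: float,
    min_len: int,
    rng: np.random.Generator,
) -> tuple[str, int]:
    ln = int(round(rng.normal(mean_len, sd_len)))
    ln = max(min_len, ln)
    ln = min(ln, len(seq))
    start = int(rng.integers(0, len(seq) - ln + 1))
    return seq[start : start + ln], start


def sample_reads(
    genomes: dict[str, EnvironmentalGene],
    config: CommunityConfig,
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Sample the DNA and RNA read pools from the environmental genes.

    DNA reads pick genes proportional to taxon abundance x gene length; RNA
    reads proportional to expression level x gene length.  Read lengths are
    normal (454 FLX-like), floored at ``min_read_len_nt`` and truncated at
    gene ends; strands are random.
    """
    if not genomes:
        raise ValueError("empty genome set")
    genes = sorted(genomes.values(), key=lambda g: g.gene_id)
    taxa = sorted({g.taxon_id for g in genes})
    ab = dict(zip(taxa, config.abundances))
    lengths = np.array([len(g.nt_seq) for g in genes], dtype=float)

    ss = np.random.SeedSequence(config.seed).spawn(4)[3]
    rng = np.random.default_rng(ss)

    def pool(n_reads, weights, prefix, mean_len):
        if n_reads == 0 or weights.sum() == 0:
            return []
        p = weights / weights.sum()
        counts = rng.multinomial(n_reads, p)
        reads = []
        i = 0
        for gi in np.flatnonzero(counts):
            g = genes[gi]
            for _ in range(counts[gi]):
                seq, start = _draw_read(
                    g.nt_seq, mean_len, config.read_len_sd_nt,
                    config.min_read_len_nt, rng,
                )
                if rng.random() < 0.5:
                    seq = revcomp(seq)
                reads.append(
                    ReadRecord(
                        read_id=f"{prefix}{i:07d}",
                        pool="DNA" if prefix == "D" else "RNA",
                        nt_seq=seq,
                        truth=(g.gene_id, g.taxon_id, start),
                    )
                )
                i += 1
        return reads

    dna_w = np.array([ab[g.taxon_id] for g in genes]) * lengths
    rna_w = np.array([g.expression_level for g in genes]) * lengths
    rna_mean = (
        config.rna_read_len_mean_nt
        if config.rna_read_len_mean_nt is not None
        else config.read_len_mean_nt
    )
    dna = pool(config.n_dna_reads, dna_w, "D", config.read_len_mean_nt)
    rna = pool(config.n_rna_reads, rna_w, "R", rna_mean)
    return dna, rna


def spike_contaminants(
    reads: list[ReadRecord],
    config: CommunityConfig,
    rrna_refs: Sequence[str],
    rng: Optional[np.random.Generator] = None,
) -> list[ReadRecord]:
    """Append rRNA-derived reads and verbatim duplicates to a pool.

    Adds ``round(rrna_fraction * n)`` reads sampled from the rRNA references
    (flagged ``is_rrna``) and duplicates ``round(duplicate_fraction * n)`` of
    the original reads exactly (flagged ``is_duplicate``), so the pool grows
    to n * (1 + rrna_fraction + duplicate_fraction) up to rounding.
    """
    if not 0 <= config.rrna_fraction <= 1 or not 0 <= config.duplicate_fraction <= 1:
        raise ConfigError("contaminant fractions must lie in [0, 1]")
    if config.rrna_fraction > 0 and not rrna_refs:
        raise ConfigError("rrna_fraction > 0 requires rRNA reference sequences")
    if rng is None:
        ss = np.random.SeedSequence(config.seed).spawn(5)[4]
        rng = np.random.default_rng(ss)
    n = len(reads)
    out = list(reads)
    pool = reads[0].pool if reads else "DNA"
    prefix = (pool or "DNA")[0]
    n_rrna = int(round(config.rrna_fraction * n))
    for i in range(n_rrna):
        ref = rrna_refs[int(rng.integers(len(rrna_refs)))]
        seq, _ = _draw_read(
            ref, config.read_len_mean_nt, config.read_len_sd_nt,
            config.min_read_len_nt, rng,
        )
        if rng.random() < 0.5:
            seq = revcomp(seq)
        out.append(
            ReadRecord(
                read_id=f"{prefix}RRNA{i:06d}", pool=pool, nt_seq=seq,
                truth=None, is_rrna=True,
            )
        )
    n_dup = int(round(config.duplicate_fraction * n))
    if n_dup > 0:
        idx = rng.choice(n, size=n_dup, replace=False)
        for j, i in enumerate(sorted(idx)):
            src = reads[i]
            out.append(
                ReadRecord(
                    read_id=f"{prefix}DUP{j:06d}",
                    pool=src.pool,
                    nt_seq=src.nt_seq,
                    truth=src.truth,
                    is_duplicate=True,
                )
            )
    return out


def simulate_community(config: CommunityConfig) -> SimulatedSample:
    """Run the full generator: panel -> expression -> evolution -> reads."""
    panel = build_panel(config)
    expression = assign_expression(panel, config)
    genomes = evolve_genes(panel, config, expression)
    dna, rna = sample_reads(genomes, config)
    if config.rrna_fraction > 0 or config.duplicate_fraction > 0:
        ss = np.random.SeedSequence(config.seed).spawn(5)[4]
        rng = np.random.default_rng(ss)
        dna = spike_contaminants(dna, config, panel.rrna_refs, rng)
        rna = spike_contaminants(rna, config, panel.rrna_refs, rng)
    return SimulatedSample(
        config=config,
        panel=panel,
        expression=expression,
        genomes=genomes,
        dna_reads=dna,
        rna_reads=rna,
    )
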