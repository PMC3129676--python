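"""End-to-end orchestration: simulate -> preprocess -> search -> profiles
-> core genome -> clustering -> composition -> functional statistics.

``run_pipeline`` executes the full analysis on a simulated community and
writes every summary table to an output directory; all randomness flows
from the community config's single seed, so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import composition, coregenome, expression, funcstats, seqcluster
from .homology import ScoringParams, search_reads, taxon_abundance, top_taxa, write_hit_table
from .preprocess import FilterReport, dedup_exact, filter_rrna, orfs_from_reads, write_fasta
from .simdata import CommunityConfig, SimulatedSample, simulate_community

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    sample: SimulatedSample
    dna_report: FilterReport
    rna_report: FilterReport
    dna_hits: pd.DataFrame
    rna_hits: pd.DataFrame
    profiles: pd.DataFrame
    taxon_abundance: pd.Series
    core_sets: dict[str, coregenome.CoreSet]
    core_summary: pd.DataFrame
    clusters: list[seqcluster.Cluster]
    cluster_counts: dict[str, int]
    cluster_divergence: pd.DataFrame
    composition_delta: composition.CompositionDelta
    read_gc: pd.Series
    category_change: Optional[pd.DataFrame]
    summaries: dict = field(default_factory=dict)


def _preprocess_pool(reads, rrna_refs, config):
    if config.rrna_fraction > 0 and rrna_refs:
        reads, r1 = filter_rrna(reads, rrna_refs)
    else:
        r1 = FilterReport(len(reads), 0, 0, len(reads))
    reads, r2 = dedup_exact(reads)
    report = FilterReport(
        r1.input_count, r1.rrna_removed, r2.duplicates_removed, r2.retained_count
    )
    return reads, report


def run_pipeline(
    config: CommunityConfig,
    outdir: Optional[str | Path] = None,
    scoring: Optional[ScoringParams] = None,
    cluster_params: Optional[seqcluster.ClusterParams] = None,
    n_top_taxa: int = 5,
    do_core: bool = True,
    do_cluster: bool = True,
) -> PipelineResult:
    """Run the complete analysis on one simulated community."""
    scoring = scoring or ScoringParams()
    cluster_params = cluster_params or seqcluster.ClusterParams(scoring=scoring)
    logger.info("simulating community (seed=%d)", config.seed)
    sample = simulate_community(config)
    panel = sample.panel
    ref_db = panel.protein_db()
    annotation = panel.annotation()

    logger.info("preprocessing read pools")
    dna_reads, dna_report = _preprocess_pool(sample.dna_reads, panel.rrna_refs, config)
    rna_reads, rna_report = _preprocess_pool(sample.rna_reads, panel.rrna_refs, config)

    logger.info("translated search: %d DNA + %d RNA reads vs %d genes",
                len(dna_reads), len(rna_reads), len(ref_db))
    dna_hits = search_reads(dna_reads, ref_db, scoring)
    rna_hits = search_reads(rna_reads, ref_db, scoring)

    profiles = expression.tabulate_genes(dna_hits, rna_hits, annotation)
    abundance = taxon_abundance(dna_hits, annotation)

    logger.info("core genomes (reciprocal best hits)")
    core_sets: dict[str, coregenome.CoreSet] = {}
    core_rows = []
    proteomes = panel.proteomes
    taxa = top_taxa(abundance, n=n_top_taxa) if do_core else []
    for taxon in taxa:
        sister = panel.sister_proteomes.get(taxon, {})
        if not sister:
            continue
        cs = coregenome.reciprocal_best_hits(
            proteomes[taxon], sister, scoring, taxon_id=taxon, sister_id=f"S_{taxon}"
        )
        core_sets[taxon] = cs
        sub = profiles[profiles["taxon_id"] == taxon]
        row = dict(taxon_id=taxon, core_pct=cs.core_pct(len(proteomes[taxon])))
        try:
            pe, pn, chi2, p = coregenome.core_representation(sub, cs)
            row.update(pct_core_expressed=pe, pct_core_nonexpressed=pn,
                       chi2=chi2, p=p)
        except ValueError as e:
            logger.warning("core representation skipped for %s: %s", taxon, e)
        try:
            mc, mn, t, tp = coregenome.core_vs_noncore_expression(sub, cs)
            row.update(mean_ratio_core=mc, mean_ratio_noncore=mn, t=t, t_p=tp)
        except ValueError as e:
            logger.warning("core expression comparison skipped for %s: %s", taxon, e)
        core_rows.append(row)
    if core_rows:
        core_summary = pd.DataFrame(core_rows)
        if "p" in core_summary:
            core_summary["p_adj"] = funcstats.bonferroni(
                core_summary["p"].fillna(1.0).tolist(), len(core_summary)
            )
    else:
        core_summary = pd.DataFrame()

    orfs = orfs_from_reads(dna_reads) + orfs_from_reads(rna_reads)
    if do_cluster:
        logger.info("database-independent clustering of %d ORFs", len(orfs))
        clusters = seqcluster.greedy_cluster(orfs, cluster_params)
        cluster_counts = seqcluster.classify_and_count(clusters)
        cluster_div = seqcluster.cluster_divergence(clusters)
    else:
        clusters = []
        cluster_counts = {}
        cluster_div = pd.DataFrame()

    logger.info("composition and functional statistics")
    dna_orfs = [o for o in orfs if o.pool == "DNA"]
    rna_orfs = [o for o in orfs if o.pool == "RNA"]
    if dna_orfs and rna_orfs:
        delta = composition.proportional_change(
            composition.usage([o.aa_seq for o in dna_orfs]),
            composition.usage([o.aa_seq for o in rna_orfs]),
        )
    else:
        delta = composition.CompositionDelta(table=pd.DataFrame())
        logger.warning("composition skipped: a pool has no ORFs")
    gc = composition.read_gc([o.nt_seq for o in orfs]) if orfs else pd.Series(dtype=float)

    category_change = None
    try:
        expr_ab = funcstats.category_abundance(profiles, "SHARED")
        nonexpr_ab = funcstats.category_abundance(profiles, "DNA_ONLY")
        if len(expr_ab) and len(nonexpr_ab):
            category_change = funcstats.fraction_change(expr_ab, nonexpr_ab)
    except Exception as e:  # degenerate communities
        logger.warning("functional statistics skipped: %s", e)

    summaries: dict = {}
    try:
        fs = expression.fraction_summary(profiles)
        summaries["fraction_identity"] = fs.identity
        summaries["fraction_counts"] = fs.counts
    except Exception as e:
        logger.warning("fraction summary skipped: %s", e)
    try:
        summaries["expression_bins"] = expression.rank_expression_bins(profiles)
        summaries["identity_ratio_r2"] = expression.correlate_identity_ratio(profiles)
    except ValueError as e:
        logger.warning("expression summaries skipped: %s", e)

    result = PipelineResult(
        sample=sample,
        dna_report=dna_report,
        rna_report=rna_report,
        dna_hits=dna_hits,
        rna_hits=rna_hits,
        profiles=profiles,
        taxon_abundance=abundance,
        core_sets=core_sets,
        core_summary=core_summary,
        clusters=clusters,
        cluster_counts=cluster_counts,
        cluster_divergence=cluster_div,
        composition_delta=delta,
        read_gc=gc,
        category_change=category_change,
        summaries=summaries,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir), config)
    return result


def _write_outputs(res: PipelineResult, outdir: Path, config: CommunityConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    write_fasta(res.sample.dna_reads, outdir / "reads_dna.fasta")
    write_fasta(res.sample.rna_reads, outdir / "reads_rna.fasta")
    res.sample.panel.annotation().to_csv(
        outdir / "annotation.tsv", sep="\t", index=False
    )
    res.sample.truth_table().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    res.dna_report.to_tsv(outdir / "filter_dna.tsv")
    res.rna_report.to_tsv(outdir / "filter_rna.tsv")
    write_hit_table(res.dna_hits, outdir / "hits_dna.tsv")
    write_hit_table(res.rna_hits, outdir / "hits_rna.tsv")
    res.profiles.to_csv(outdir / "profiles.tsv", sep="\t", index=False, float_format="%.4f")
    res.taxon_abundance.to_csv(outdir / "taxon_abundance.tsv", sep="\t")
    if len(res.core_summary):
        res.core_summary.to_csv(outdir / "core_summary.tsv", sep="\t", index=False, float_format="%.4f")
    for taxon, cs in res.core_sets.items():
        cs.to_tsv(outdir / f"core_{taxon}.tsv")
    seqcluster.write_clusters(res.clusters, outdir / "clusters.txt")
    pd.Series(res.cluster_counts).to_csv(outdir / "cluster_counts.tsv", sep="\t")
    res.cluster_divergence.to_csv(outdir / "cluster_divergence.tsv", sep="\t", index=False, float_format="%.4f")
    if len(res.composition_delta.table):
        res.composition_delta.table.to_csv(
            outdir / "aa_usage_change.tsv", sep="\t", index=False, float_format="%.6g"
        )
    if len(res.read_gc):
        res.read_gc.to_csv(outdir / "read_gc.tsv", sep="\t")
    if res.category_change is not None:
        res.category_change.to_csv(outdir / "category_change.tsv", sep="\t", float_format="%.6g")
    for name, obj in res.summaries.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(outdir / f"{name}.tsv", sep="\t", float_format="%.4f")
        else:
            (outdir / f"{name}.txt").write_text(f"{obj}\n")
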