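"""Per-gene profiles: detection fractions, identities, expression ratios.

A reference gene is "expressed" when it recruits top-hit reads in both the
DNA and RNA pools of a sample (fraction SHARED) and "non-expressed" when it
appears in the DNA pool only (DNA_ONLY).  Identities of multiple reads
matching the same gene are averaged (tie weights respected) to per-gene
values.  The expression ratio normalises transcript abundance by gene
abundance:

    (RNA reads per gene / total matched RNA reads)
    / (DNA reads per gene / total matched DNA reads)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "tabulate_genes",
    "expression_ratio",
    "fraction_summary",
    "rank_expression_bins",
    "identity_by_hsp_length",
    "correlate_identity_ratio",
    "PROFILE_COLUMNS",
]

logger = logging.getLogger(__name__)

PROFILE_COLUMNS = [
    "gene_id",
    "dna_count",
    "rna_count",
    "mean_identity_dna",
    "mean_identity_rna",
    "fraction",
    "expression_ratio",
    "is_core",
    "taxon_id",
    "category_id",
    "pathway_id",
]


def _per_gene(hits: pd.DataFrame) -> pd.DataFrame:
    if hits.empty:
        return pd.DataFrame(columns=["gene_id", "count", "identity"]).set_index(
            "gene_id"
        )
    g = hits.groupby("gene_id")
    count = g["weight"].sum()
    ident = g.apply(
        lambda d: np.average(d["pct_identity"], weights=d["weight"]),
        include_groups=False,
    )
    return pd.DataFrame({"count": count, "identity": ident})


def expression_ratio(
    rna_count: float, dna_count: float, total_rna: float, total_dna: float
) -> float:
    """(rna/total_rna) / (dna/total_dna); defined only for SHARED genes."""
    if total_rna <= 0 or total_dna <= 0:
        raise ValueError("totals must be positive")
    if dna_count <= 0 or rna_count <= 0:
        return math.nan
    return (rna_count / total_rna) / (dna_count / total_dna)


def tabulate_genes(
    dna_hits: pd.DataFrame,
    rna_hits: pd.DataFrame,
    annotation: Optional[pd.DataFrame] = None,
    core_gene_ids: Optional[set] = None,
) -> pd.DataFrame:
    """Build per-gene profiles from the two pools' hit tables.

    Weighted read counts and weighted mean identities per gene; fraction
    labels SHARED / DNA_ONLY / RNA_ONLY; expression ratios for SHARED genes.
    Genes absent from the annotation are retained with missing annotation.
    """
    dna = _per_gene(dna_hits)
    rna = _per_gene(rna_hits)
    total_dna = float(dna_hits["weight"].sum()) if not dna_hits.empty else 0.0
    total_rna = float(rna_hits["weight"].sum()) if not rna_hits.empty else 0.0
    gene_ids = sorted(set(dna.index) | set(rna.index))
    rows = []
    for gid in gene_ids:
        dc = float(dna["count"].get(gid, 0.0))
        rc = float(rna["count"].get(gid, 0.0))
        fraction = (
            "SHARED" if dc > 0 and rc > 0 else ("DNA_ONLY" if dc > 0 else "RNA_ONLY")
        )
        ratio = (
            expression_ratio(rc, dc, total_rna, total_dna)
            if fraction == "SHARED"
            else math.nan
        )
        rows.append(
            dict(
                gene_id=gid,
                dna_count=dc,
                rna_count=rc,
                mean_identity_dna=float(dna["identity"].get(gid, np.nan)),
                mean_identity_rna=float(rna["identity"].get(gid, np.nan)),
                fraction=fraction,
                expression_ratio=ratio,
            )
        )
    profiles = pd.DataFrame(rows, columns=PROFILE_COLUMNS[:7])
    if annotation is not None:
        ann = annotation.drop_duplicates("gene_id").set_index("gene_id")
        for col in ("taxon_id", "category_id", "pathway_id"):
            if col in ann:
                profiles[col] = profiles["gene_id"].map(ann[col])
        if "is_core" in ann and core_gene_ids is None:
            profiles["is_core"] = profiles["gene_id"].map(ann["is_core"])
        missing = profiles["gene_id"][~profiles["gene_id"].isin(ann.index)]
        if len(missing):
            logger.info(
                "%d genes in hits absent from annotation (kept, unannotated)",
                len(missing),
            )
    if core_gene_ids is not None:
        profiles["is_core"] = profiles["gene_id"].isin(core_gene_ids)
    for col in PROFILE_COLUMNS:
        if col not in profiles:
            profiles[col] = np.nan
    return profiles[PROFILE_COLUMNS]


@dataclass
class FractionSummary:
    """Mean-over-genes identities and gene counts per detection fraction.

    ``identity`` and ``counts`` are indexed by pool (DNA, RNA) and fraction
    (SHARED, DNA_ONLY, RNA_ONLY, ALL) in the layout of the printed summary
    tables; cells that have no genes are NaN / 0.
    """

    identity: pd.DataFrame
    counts: pd.DataFrame


def fraction_summary(profiles: pd.DataFrame) -> FractionSummary:
    cols = ["SHARED", "DNA_ONLY", "RNA_ONLY", "ALL"]
    ident = pd.DataFrame(index=["DNA", "RNA"], columns=cols, dtype=float)
    counts = pd.DataFrame(0, index=["DNA", "RNA"], columns=cols, dtype=int)
    for pool, id_col, present in (
        ("DNA", "mean_identity_dna", profiles["dna_count"] > 0),
        ("RNA", "mean_identity_rna", profiles["rna_count"] > 0),
    ):
        sub = profiles[present]
        for frac in ("SHARED", "DNA_ONLY", "RNA_ONLY"):
            cell = sub[sub["fraction"] == frac]
            counts.loc[pool, frac] = len(cell)
            ident.loc[pool, frac] = (
                cell[id_col].mean() if len(cell) else np.nan
            )
        counts.loc[pool, "ALL"] = len(sub)
        ident.loc[pool, "ALL"] = sub[id_col].mean() if len(sub) else np.nan
    return FractionSummary(identity=ident, counts=counts)


def _ci95(values: np.ndarray) -> float:
    if len(values) < 2:
        return math.nan
    return 1.96 * values.std(ddof=1) / math.sqrt(len(values))


def rank_expression_bins(
    profiles: pd.DataFrame,
    fractions: Sequence[float] = (1.0, 0.10, 0.01, 0.001),
) -> pd.DataFrame:
    """Mean per-gene DNA identity in nested top-expression bins.

    SHARED genes are ranked by descending expression ratio (ties broken by
    gene id); each bin holds the top ceil(fraction * n) genes.  95% CIs use
    the normal approximation and are flagged unreliable below 2 genes.
    """
    shared = profiles[profiles["fraction"] == "SHARED"].copy()
    if shared.empty:
        raise ValueError("no SHARED genes to bin")
    shared = shared.sort_values(
        ["expression_ratio", "gene_id"], ascending=[False, True]
    )
    n = len(shared)
    rows = []
    for f in fractions:
        size = max(1, math.ceil(f * n))
        top = shared.head(size)
        ident = top["mean_identity_dna"].to_numpy(dtype=float)
        rows.append(
            dict(
                bin_fraction=f,
                n_genes=size,
                mean_identity=float(np.nanmean(ident)),
                ci95=_ci95(ident[~np.isnan(ident)]),
                reliable=size >= 2,
            )
        )
    return pd.DataFrame(rows)


def identity_by_hsp_length(
    hits: pd.DataFrame,
    bin_edges: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Gene-level mean identity binned by HSP alignment length.

    Reads fall into length bins by their HSP aligned length; within a bin,
    identities are first averaged per gene (weights respected) and then over
    genes.  Default edges are every 10 residues up to 100 with a final
    open ">100" bin.  Empty bins are absent from the output.
    """
    if hits.empty:
        raise ValueError("empty hit table")
    if bin_edges is None:
        bin_edges = list(range(0, 101, 10)) + [math.inf]
    edges = list(bin_edges)
    labels = [
        (f">{int(lo)}" if math.isinf(hi) else f"({int(lo)}-{int(hi)}]")
        for lo, hi in zip(edges[:-1], edges[1:])
    ]
    binned = hits.assign(
        length_bin=pd.cut(hits["aligned_len"], bins=edges, labels=labels)
    ).dropna(subset=["length_bin"])
    rows = []
    for label in labels:
        sub = binned[binned["length_bin"] == label]
        if sub.empty:
            continue
        per_gene = sub.groupby("gene_id").apply(
            lambda d: np.average(d["pct_identity"], weights=d["weight"]),
            include_groups=False,
        )
        vals = per_gene.to_numpy(dtype=float)
        rows.append(
            dict(
                length_bin=label,
                n_genes=len(vals),
                mean_identity=float(vals.mean()),
                ci95=_ci95(vals),
            )
        )
    return pd.DataFrame(rows)


def correlate_identity_ratio(profiles: pd.DataFrame) -> float:
    """Squared Pearson correlation between per-gene DNA identity and
    expression ratio over SHARED genes."""
    shared = profiles[profiles["fraction"] == "SHARED"].dropna(
        subset=["mean_identity_dna", "expression_ratio"]
    )
    if len(shared) < 3:
        raise ValueError("need >= 3 SHARED genes")
    x = shared["mean_identity_dna"].to_numpy()
    y = shared["expression_ratio"].to_numpy()
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return 0.0
    r = stats.pearsonr(x, y).statistic
    return float(r * r)
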