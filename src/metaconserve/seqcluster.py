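"""Database-independent greedy identity-threshold clustering of read ORFs.

Amino-acid sequences from the pooled DNA and RNA reads are clustered
greedily: sequences are processed in descending length order and join the
first existing cluster whose (longest-member) representative aligns to them
above the identity threshold (default 55%) over the aligned region, else
they found a new cluster.  Clusters are typed DNA_ONLY / RNA_ONLY / MIXED by
their members' pools; the divergence statistic is the per-cluster mean of
DNA-member identities to the representative, with the exclusion rules for
singletons and representative-only-DNA clusters applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .homology import ScoringParams, _KmerIndex, align_local
from .preprocess import OrfRecord

__all__ = [
    "ClusterParams",
    "ClusterMember",
    "Cluster",
    "greedy_cluster",
    "classify_and_count",
    "cluster_divergence",
    "cluster_size_stats",
    "write_clusters",
]

logger = logging.getLogger(__name__)


@dataclass
class ClusterParams:
    """Greedy clustering parameters.

    ``identity_threshold`` applies to gap-excluded identity over the aligned
    region.  To keep short spurious local segments from joining unrelated
    sequences, the joining alignment must additionally span at least
    ``min_aligned_cols`` non-gap columns and score at least ``min_bits``
    bits (default 28, low enough that a ~20-residue exact overlap
    qualifies).  ``exact`` disables the k-mer candidate prefilter.
    """

    identity_threshold: float = 0.55
    min_aligned_cols: int = 20
    min_bits: float = 28.0
    kmer_size: int = 4
    min_kmer_hits: int = 2
    exact: bool = False
    scoring: ScoringParams = field(default_factory=ScoringParams)

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold <= 1:
            raise ValueError("identity_threshold must lie in (0, 1]")


@dataclass
class ClusterMember:
    seq_id: str
    pool: Optional[str]  # "DNA" | "RNA"
    identity: float  # percent identity to the representative
    is_representative: bool = False


@dataclass
class Cluster:
    cluster_id: str
    representative_id: str
    representative_seq: str
    members: list[ClusterMember] = field(default_factory=list)

    @property
    def type(self) -> str:
        pools = {m.pool for m in self.members}
        if pools == {"DNA"}:
            return "DNA_ONLY"
        if pools == {"RNA"}:
            return "RNA_ONLY"
        return "MIXED"

    @property
    def dna_size(self) -> int:
        return sum(1 for m in self.members if m.pool == "DNA")

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1

    def dna_member_identities(self) -> list[float]:
        """Identities of non-representative DNA members to the
        representative."""
        return [
            m.identity
            for m in self.members
            if m.pool == "DNA" and not m.is_representative
        ]


def _join_identity(
    query: str, rep: str, params: ClusterParams
) -> Optional[float]:
    """Percent identity of query to a representative if the alignment
    qualifies under the join rule, else None."""
    hsp = align_local(query, rep, params.scoring)
    if hsp is None:
        return None
    if hsp.bit_score < params.min_bits:
        return None
    if hsp.aligned_len - hsp.gap_columns < params.min_aligned_cols:
        return None
    if hsp.pct_identity < 100.0 * params.identity_threshold:
        return None
    return hsp.pct_identity


def greedy_cluster(
    orfs: Sequence[OrfRecord], params: Optional[ClusterParams] = None
) -> list[Cluster]:
    """Greedy incremental clustering of amino-acid sequences.

    Sequences are processed in descending length (ties: lexicographic id)
    and join the FIRST existing cluster, in creation order, whose
    representative qualifies under the join rule; otherwise they found a new
    cluster with themselves as representative.  The result is an exhaustive,
    disjoint partition and every representative is at least as long as every
    member of its cluster.
    """
    params = params or ClusterParams()
    ordered = sorted(orfs, key=lambda o: (-len(o.aa_seq), o.read_id))
    clusters: list[Cluster] = []
    index: Optional[_KmerIndex] = None
    rep_db: dict[str, str] = {}
    rep_to_cluster: dict[str, int] = {}
    if not params.exact:
        index = _KmerIndex({}, params.kmer_size)
    for orf in ordered:
        joined = False
        if params.exact:
            candidates = range(len(clusters))
        else:
            hits = index.candidates(orf.aa_seq, params.min_kmer_hits)
            candidates = sorted(rep_to_cluster[r] for r in hits)
        for ci in candidates:
            cl = clusters[ci]
            ident = _join_identity(orf.aa_seq, cl.representative_seq, params)
            if ident is not None:
                cl.members.append(
                    ClusterMember(orf.read_id, orf.pool, ident, False)
                )
                joined = True
                break
        if not joined:
            cid = f"C{len(clusters):06d}"
            clusters.append(
                Cluster(
                    cluster_id=cid,
                    representative_id=orf.read_id,
                    representative_seq=orf.aa_seq,
                    members=[ClusterMember(orf.read_id, orf.pool, 100.0, True)],
                )
            )
            if not params.exact:
                rep_to_cluster[orf.read_id] = len(clusters) - 1
                # extend the k-mer index with the new representative
                s = orf.aa_seq
                for i in range(len(s) - params.kmer_size + 1):
                    kmer = s[i : i + params.kmer_size]
                    if "X" in kmer:
                        continue
                    index.index.setdefault(kmer, set()).add(orf.read_id)
                rep_db[orf.read_id] = s
    return clusters


def classify_and_count(clusters: Sequence[Cluster]) -> dict[str, int]:
    """Cluster tallies: total, singletons, and counts per type."""
    counts = dict(total=len(clusters), singleton=0, MIXED=0, DNA_ONLY=0, RNA_ONLY=0)
    for cl in clusters:
        if cl.is_singleton:
            counts["singleton"] += 1
        counts[cl.type] += 1
    return counts


def _divergence_value(cl: Cluster) -> Optional[float]:
    """Per-cluster DNA divergence value under the exclusion rules, or None
    when the cluster is excluded."""
    if cl.is_singleton:
        return None
    rep_pool = next(m.pool for m in cl.members if m.is_representative)
    dna_ids = cl.dna_member_identities()
    if rep_pool == "DNA" and not dna_ids:
        # representative is the only DNA sequence
        return None
    if rep_pool != "DNA" and len(dna_ids) == 1:
        # RNA representative with a single DNA member: record its identity
        return dna_ids[0]
    if not dna_ids:
        return None
    return float(np.mean(dna_ids))


def cluster_divergence(clusters: Sequence[Cluster]) -> pd.DataFrame:
    """Mean of per-cluster DNA-member identities by cluster type.

    Only DNA_ONLY and MIXED clusters enter; singletons and clusters whose
    representative is the sole DNA sequence are excluded.  Returns one row
    per type with the number of eligible clusters and the type-level mean of
    cluster means.
    """
    rows = []
    for ctype in ("DNA_ONLY", "MIXED"):
        vals = [
            v
            for cl in clusters
            if cl.type == ctype and (v := _divergence_value(cl)) is not None
        ]
        if not vals:
            logger.warning("no eligible %s clusters for divergence", ctype)
            continue
        rows.append(
            dict(type=ctype, n_clusters=len(vals), mean_identity=float(np.mean(vals)))
        )
    return pd.DataFrame(rows, columns=["type", "n_clusters", "mean_identity"])


def cluster_size_stats(
    clusters: Sequence[Cluster], high_identity_cut: float = 98.0
) -> pd.DataFrame:
    """Mean DNA-member count and identity histogram by cluster type.

    Sizes count DNA members only (RNA members of MIXED clusters are not
    counted).  The histogram bins per-cluster divergence values in 1% steps
    with a final > ``high_identity_cut`` tally.
    """
    rows = []
    for ctype in ("DNA_ONLY", "MIXED"):
        sub = [cl for cl in clusters if cl.type == ctype and not cl.is_singleton]
        vals = [v for cl in sub if (v := _divergence_value(cl)) is not None]
        sizes = [cl.dna_size for cl in sub]
        hist = np.zeros(101, dtype=int)
        high = 0
        for v in vals:
            hist[min(100, int(math.floor(v)))] += 1
            if v > high_identity_cut:
                high += 1
        rows.append(
            dict(
                type=ctype,
                n_clusters=len(sub),
                mean_dna_size=float(np.mean(sizes)) if sizes else math.nan,
                n_high_identity=high,
                frac_high_identity=high / len(vals) if vals else math.nan,
            )
        )
    return pd.DataFrame(rows)


def write_clusters(clusters: Sequence[Cluster], path) -> None:
    """Plain-text cluster listing: representative first, one member per
    line (member_id, pool, identity, representative flag)."""
    with open(path, "w") as fh:
        for cl in clusters:
            fh.write(f"#cluster\t{cl.cluster_id}\ttype={cl.type}\n")
            ordered = sorted(cl.members, key=lambda m: not m.is_representative)
            for m in ordered:
                fh.write(
                    f"{m.seq_id}\t{m.pool or '-'}\t{m.identity:.1f}\t"
                    f"{'*' if m.is_representative else '.'}\n"
                )
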