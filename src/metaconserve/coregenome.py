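"""Core genomes by reciprocal best hits against a sister proteome.

A gene belongs to the core set of its taxon when its best hit in the sister
proteome points back to it (both directions above 50 bits).  Core
representation compares the share of core genes between the expressed
(SHARED) and non-expressed (DNA_ONLY) fractions; expression-ratio means are
compared between core and non-core SHARED genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from . import funcstats
from .homology import ScoringParams, _KmerIndex, align_local

__all__ = [
    "CoreSet",
    "reciprocal_best_hits",
    "core_representation",
    "core_vs_noncore_expression",
]


@dataclass
class CoreSet:
    taxon_id: str
    sister_id: str
    pairs: dict[str, str]  # gene_id -> sister gene_id

    @property
    def core_gene_ids(self) -> set[str]:
        return set(self.pairs)

    def core_pct(self, proteome_size: int) -> float:
        return 100.0 * len(self.pairs) / proteome_size if proteome_size else 0.0

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tpartner_id\n")
            for g in sorted(self.pairs):
                fh.write(f"{g}\t{self.pairs[g]}\n")


def _best_hits(
    queries: Mapping[str, str],
    targets: Mapping[str, str],
    params: ScoringParams,
) -> dict[str, tuple[str, float]]:
    """Best target per query by bit score; ties broken by highest identity,
    then lexicographic target id.  Self ids are never matched."""
    index = None if params.exact else _KmerIndex(targets, params.kmer_size)
    out: dict[str, tuple[str, float]] = {}
    for qid in sorted(queries):
        qseq = queries[qid]
        if params.exact:
            cand = [t for t in sorted(targets) if t != qid]
        else:
            cand = sorted(
                t
                for t in index.candidates(qseq, params.min_kmer_hits)
                if t != qid
            )
        best = None  # (bits, identity, tid)
        for tid in cand:
            hsp = align_local(qseq, targets[tid], params, qid, tid)
            if hsp is None or hsp.bit_score <= params.bit_threshold:
                continue
            key = (hsp.bit_score, hsp.pct_identity)
            if (
                best is None
                or key > (best[0], best[1])
                or (key == (best[0], best[1]) and tid < best[2])
            ):
                best = (hsp.bit_score, hsp.pct_identity, tid)
        if best is not None:
            out[qid] = (best[2], best[0])
    return out


def reciprocal_best_hits(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    params: Optional[ScoringParams] = None,
    taxon_id: str = "A",
    sister_id: str = "B",
) -> CoreSet:
    """Reciprocal-best-hit core set of proteome A against sister proteome B.

    g is core iff best(g in B) = h, best(h in A) = g, and both bit scores
    exceed ``params.bit_threshold`` (default 50).
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    params = params or ScoringParams()
    a_best = _best_hits(proteome_a, proteome_b, params)
    b_best = _best_hits(proteome_b, proteome_a, params)
    pairs = {
        g: h
        for g, (h, _) in a_best.items()
        if h in b_best and b_best[h][0] == g
    }
    return CoreSet(taxon_id=taxon_id, sister_id=sister_id, pairs=pairs)


def core_representation(
    profiles: pd.DataFrame, core_set: CoreSet
) -> tuple[float, float, float, float]:
    """Percentage of expressed (SHARED) and non-expressed (DNA_ONLY) genes
    falling within the core set, with a 2x2 chi-square.

    ``profiles`` should already be restricted to genes of the taxon.
    Returns (pct_core_expressed, pct_core_nonexpressed, chi2, p).
    """
    core = core_set.core_gene_ids
    expressed = profiles[profiles["fraction"] == "SHARED"]["gene_id"]
    nonexpr = profiles[profiles["fraction"] == "DNA_ONLY"]["gene_id"]
    if expressed.empty or nonexpr.empty:
        raise ValueError("need genes in both the SHARED and DNA_ONLY fractions")
    a = int(expressed.isin(core).sum())  # core, expressed
    b = len(expressed) - a
    c = int(nonexpr.isin(core).sum())  # core, non-expressed
    d = len(nonexpr) - c
    chi2, p = funcstats.chisq_2x2(a, b, c, d)
    return 100.0 * a / len(expressed), 100.0 * c / len(nonexpr), chi2, p


def core_vs_noncore_expression(
    profiles: pd.DataFrame, core_set: CoreSet
) -> tuple[float, float, float, float]:
    """Mean expression ratio of core versus non-core SHARED genes plus a
    two-tailed Welch t-test.  Returns (mean_core, mean_noncore, t, p)."""
    shared = profiles[profiles["fraction"] == "SHARED"].dropna(
        subset=["expression_ratio"]
    )
    is_core = shared["gene_id"].isin(core_set.core_gene_ids)
    core_ratios = shared.loc[is_core, "expression_ratio"].to_numpy()
    non_ratios = shared.loc[~is_core, "expression_ratio"].to_numpy()
    if len(core_ratios) < 2 or len(non_ratios) < 2:
        raise ValueError("need >= 2 SHARED genes in each class")
    t, p = funcstats.t_test(core_ratios, non_ratios)
    return float(core_ratios.mean()), float(non_ratios.mean()), t, p
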