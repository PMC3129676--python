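"""Amino-acid usage, synonymous-codon GC content, and usage shifts.

Each amino acid is scored by the GC fraction of its synonymous codons
(e.g. alanine: 4 codons, 10 of 12 bases G/C, 0.83).  Usage tables count
residues over read ORFs; proportional change from the DNA to the RNA pool
is ((p_RNA - p_DNA)/p_DNA) x 100 per amino acid with a per-amino-acid 2x2
chi-square and Bonferroni correction; significant shifts are tallied by GC
class to expose the GC-directed usage signature of the expressed gene pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import funcstats
from .simdata import AA_TO_CODONS

__all__ = [
    "AminoAcidInfo",
    "UsageTable",
    "CompositionDelta",
    "aa_gc_table",
    "usage",
    "proportional_change",
    "gc_category_tally",
    "read_gc",
]

AMINO_ACIDS = tuple(sorted(AA_TO_CODONS))


@dataclass(frozen=True)
class AminoAcidInfo:
    aa: str
    codons: tuple[str, ...]
    gc_content: float  # GC bases among synonymous codons / total bases


def aa_gc_table() -> dict[str, AminoAcidInfo]:
    """Synonymous-codon GC content for all 20 amino acids (standard code;
    stop codons excluded from all denominators)."""
    out = {}
    for aa in AMINO_ACIDS:
        codons = AA_TO_CODONS[aa]
        bases = "".join(codons)
        gc = sum(1 for b in bases if b in "GC") / len(bases)
        out[aa] = AminoAcidInfo(aa=aa, codons=codons, gc_content=gc)
    return out


@dataclass
class UsageTable:
    """Residue counts and proportions for a sequence set."""

    counts: pd.Series  # indexed by amino acid
    total: int

    @property
    def proportions(self) -> pd.Series:
        return self.counts / self.total


def usage(aa_seqs: Sequence[str]) -> UsageTable:
    """Count amino acids across a sequence set.

    Sentinel/unknown symbols (X, *, etc.) are excluded from counts and from
    the total.
    """
    if not aa_seqs:
        raise ValueError("empty sequence set")
    counts = pd.Series(0, index=list(AMINO_ACIDS), dtype=int)
    joined = "".join(aa_seqs)
    vc = pd.Series(list(joined)).value_counts()
    for aa in AMINO_ACIDS:
        counts[aa] = int(vc.get(aa, 0))
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no standard residues in input")
    return UsageTable(counts=counts, total=total)


@dataclass
class CompositionDelta:
    """Per-amino-acid proportional change from DNA to RNA usage."""

    table: pd.DataFrame  # aa, gc, p_dna, p_rna, change_pct, chi2, p, p_adj, significant


def proportional_change(
    usage_dna: UsageTable,
    usage_rna: UsageTable,
    bonferroni_m: int = 20,
    alpha: float = 0.05,
) -> CompositionDelta:
    """Proportional usage change per amino acid with chi-square tests.

    change = ((p_RNA - p_DNA) / p_DNA) x 100.  Each amino acid gets a 2x2
    chi-square on residue counts (this aa vs all others, DNA vs RNA pool);
    Bonferroni correction uses family size ``bonferroni_m`` (20 per sample
    pair by default; multiply by the number of pairs for multi-sample runs).
    Amino acids absent from the DNA pool have undefined change (NaN,
    flagged).
    """
    gc = aa_gc_table()
    rows = []
    for aa in AMINO_ACIDS:
        cd = int(usage_dna.counts[aa])
        cr = int(usage_rna.counts[aa])
        p_dna = cd / usage_dna.total
        p_rna = cr / usage_rna.total
        if p_dna > 0:
            change = (p_rna - p_dna) / p_dna * 100.0
        else:
            change = math.nan
        chi2, p = funcstats.chisq_2x2(
            cd, usage_dna.total - cd, cr, usage_rna.total - cr
        )
        p_adj = funcstats.bonferroni([p], bonferroni_m)[0]
        rows.append(
            dict(
                aa=aa,
                gc=gc[aa].gc_content,
                p_dna=p_dna,
                p_rna=p_rna,
                change_pct=change,
                chi2=chi2,
                p=p,
                p_adj=p_adj,
                significant=bool(p_adj < alpha and not math.isnan(change)),
                defined=not math.isnan(change),
            )
        )
    return CompositionDelta(table=pd.DataFrame(rows))


def gc_category_tally(
    deltas: Sequence[CompositionDelta],
) -> pd.DataFrame:
    """Counts of significant usage increases/decreases by GC class.

    GC classes are < 0.5, = 0.5, > 0.5; samples are pooled.  Returns a 3x2
    table indexed by gc_class with columns increase/decrease.
    """
    classes = ["<0.5", "=0.5", ">0.5"]
    tally = pd.DataFrame(0, index=classes, columns=["increase", "decrease"])
    for delta in deltas:
        sig = delta.table[delta.table["significant"]]
        for row in sig.itertuples():
            if row.gc < 0.5:
                cls = "<0.5"
            elif row.gc > 0.5:
                cls = ">0.5"
            else:
                cls = "=0.5"
            if row.change_pct > 0:
                tally.loc[cls, "increase"] += 1
            elif row.change_pct < 0:
                tally.loc[cls, "decrease"] += 1
    return tally


def read_gc(
    nt_seqs: Sequence[str],
    groups: Optional[Sequence[str]] = None,
) -> pd.Series:
    """Mean GC percent per read, averaged over reads.

    With ``groups`` (one label per sequence, e.g. the detection fraction of
    the gene a read matches), returns per-group means plus an "ALL" row;
    otherwise a single "ALL" row.
    """
    if len(nt_seqs) == 0:
        raise ValueError("empty input")
    gc = np.array(
        [
            100.0 * sum(1 for b in s.upper() if b in "GC") / len(s)
            for s in nt_seqs
        ]
    )
    if groups is None:
        return pd.Series({"ALL": float(gc.mean())})
    ser = pd.Series(gc, index=list(groups))
    out = ser.groupby(level=0).mean().to_dict()
    out["ALL"] = float(gc.mean())
    return pd.Series(out)
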