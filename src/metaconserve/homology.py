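"""Translated (six-frame) read-versus-protein search with bit-score cutoffs.

Reads are translated in all six frames and locally aligned to a reference
protein database under BLOSUM62 with affine gaps.  For each read the best
HSP per reference gene is kept; genes whose bit score exceeds the cutoff
(default 50) *and* ties the per-read maximum become top hits, with each tied
gene weighted 1/(number of tied genes) so that one read always contributes
one unit of evidence.  Percent identity is computed over aligned columns
with gap columns excluded.

A k-mer (k=4) candidate prefilter accelerates database-scale searches; exact
mode (every gene x every frame) is available and is what the brute-force
oracle tests run.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import biotite.sequence as bseq
import biotite.sequence.align as balign
from Bio.Seq import Seq

from .simdata import ReadRecord, revcomp

__all__ = [
    "ScoringParams",
    "HSP",
    "translate_frames",
    "align_local",
    "bit_score",
    "search_reads",
    "taxon_abundance",
    "top_taxa",
    "HIT_COLUMNS",
    "write_hit_table",
    "read_hit_table",
]

logger = logging.getLogger(__name__)

_BLOSUM62 = balign.SubstitutionMatrix.std_protein_matrix()
_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class ScoringParams:
    """Alignment scoring and search parameters.

    Defaults are classic gapped-BLASTX constants: BLOSUM62, gap open 11 /
    extend 1 (a gap of length n costs open + n*extend), Karlin-Altschul
    lambda=0.267 and K=0.041, cutoff 50 bits.  ``tie_decimals`` rounds bit
    scores before tie detection, mirroring reported-precision ties.
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    k: float = 0.041
    bit_threshold: float = 50.0
    tie_decimals: int = 1
    kmer_size: int = 4
    min_kmer_hits: int = 3
    exact: bool = False

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.matrix != "BLOSUM62":
            raise ValueError("only BLOSUM62 is provided")


@dataclass
class HSP:
    """Best-scoring local alignment segment of a read frame to a gene."""

    read_id: str
    gene_id: str
    frame: int
    raw_score: float
    bit_score: float
    aligned_len: int  # alignment columns, gaps included
    identities: int  # identical residue pairs (gap columns excluded)
    gap_columns: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int

    @property
    def pct_identity(self) -> float:
        denom = self.aligned_len - self.gap_columns
        return 100.0 * self.identities / denom if denom else 0.0


def bit_score(raw_score: float, params: ScoringParams) -> float:
    """Karlin-Altschul rescaling: (lambda * raw - ln K) / ln 2."""
    return (params.lam * raw_score - math.log(params.k)) / math.log(2.0)


def translate_frames(nt_seq: str) -> dict[int, str]:
    """Translations of frames +1..+3 and (reverse complement) -1..-3.

    Stop codons are rendered as '*'; trailing partial codons are dropped.
    """
    nt_seq = nt_seq.upper()
    if len(nt_seq) < 3:
        raise ValueError("sequence shorter than one codon")
    out: dict[int, str] = {}
    rc = revcomp("".join(b if b in "ACGT" else "N" for b in nt_seq))
    fwd = "".join(b if b in "ACGT" else "N" for b in nt_seq)
    for f in (1, 2, 3):
        for strand, seq in ((1, fwd), (-1, rc)):
            sub = seq[f - 1 :]
            sub = sub[: len(sub) - len(sub) % 3]
            out[strand * f] = str(Seq(sub).translate(table=1)) if sub else ""
    return out


_SANITIZE_TABLE = str.maketrans(
    {chr(i): "X" for i in range(256) if chr(i) not in _STANDARD_AA}
)


def _sanitize_aa(seq: str) -> str:
    """Map stops and non-standard residues to X (non-positive BLOSUM62
    scores against everything)."""
    return seq.translate(_SANITIZE_TABLE)


@lru_cache(maxsize=65536)
def _encode(aa_seq: str) -> bseq.ProteinSequence:
    return bseq.ProteinSequence(_sanitize_aa(aa_seq))


_X_CODE = int(bseq.ProteinSequence.alphabet.encode("X"))


def align_local(
    query_aa: str,
    ref_aa: str,
    params: Optional[ScoringParams] = None,
    read_id: str = "",
    gene_id: str = "",
    frame: int = 0,
) -> Optional[HSP]:
    """Optimal local alignment of two amino-acid sequences.

    Returns the HSP with gap-excluded identity, or None when the best raw
    score maps below 0 bits.  Identities are counted only between standard
    residues (X never matches anything, including itself).
    """
    params = params or ScoringParams()
    if not query_aa or not ref_aa:
        raise ValueError("empty sequence")
    q = _encode(query_aa)
    r = _encode(ref_aa)
    alns = balign.align_optimal(
        q,
        r,
        _BLOSUM62,
        gap_penalty=(-(params.gap_open + params.gap_extend), -params.gap_extend),
        local=True,
        max_number=1,
    )
    if not alns:
        return None
    aln = alns[0]
    bits = bit_score(aln.score, params)
    if bits < 0:
        return None
    trace = aln.trace
    qi, ri = trace[:, 0], trace[:, 1]
    gap_cols = int(((qi < 0) | (ri < 0)).sum())
    both = (qi >= 0) & (ri >= 0)
    qres = q.code[qi[both]]
    rres = r.code[ri[both]]
    identities = int(((qres == rres) & (qres != _X_CODE)).sum())
    return HSP(
        read_id=read_id,
        gene_id=gene_id,
        frame=frame,
        raw_score=float(aln.score),
        bit_score=bits,
        aligned_len=len(trace),
        identities=identities,
        gap_columns=gap_cols,
        q_start=int(qi[qi >= 0].min()),
        q_end=int(qi[qi >= 0].max()) + 1,
        s_start=int(ri[ri >= 0].min()),
        s_end=int(ri[ri >= 0].max()) + 1,
    )


# ---------------------------------------------------------------------------
# database search

HIT_COLUMNS = [
    "read_id",
    "gene_id",
    "pct_identity",
    "aligned_len",
    "mismatches",
    "gap_columns",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bit_score",
    "frame",
    "weight",
]


class _KmerIndex:
    """gene_id sets keyed by amino-acid k-mers of the reference proteins."""

    def __init__(self, ref_db: Mapping[str, str], k: int):
        self.k = k
        self.index: dict[str, set[str]] = {}
        for gid, seq in ref_db.items():
            s = _sanitize_aa(seq)
            for i in range(len(s) - k + 1):
                kmer = s[i : i + k]
                if "X" in kmer:
                    continue
                self.index.setdefault(kmer, set()).add(gid)

    def candidates(self, frame_aa: str, min_hits: int) -> Counter:
        s = _sanitize_aa(frame_aa)
        counts: Counter = Counter()
        for i in range(len(s) - self.k + 1):
            kmer = s[i : i + self.k]
            if "X" in kmer:
                continue
            for gid in self.index.get(kmer, ()):
                counts[gid] += 1
        return Counter({g: c for g, c in counts.items() if c >= min_hits})


def search_reads(
    reads: Sequence[ReadRecord],
    ref_db: Mapping[str, str],
    params: Optional[ScoringParams] = None,
) -> pd.DataFrame:
    """Six-frame translated search of reads against a protein database.

    For each read, the best HSP per gene is computed; genes whose bit score
    exceeds ``params.bit_threshold`` and ties the per-read maximum (after
    rounding to ``tie_decimals``) are reported with weight 1/n_tied.
    Reads with no qualifying hit are absent from the output.
    """
    params = params or ScoringParams()
    if not ref_db:
        raise ValueError("empty reference database")
    index = None if params.exact else _KmerIndex(ref_db, params.kmer_size)
    rows = []
    gene_ids = sorted(ref_db)
    for read in reads:
        if len(read.nt_seq) < 3:
            continue
        frames = translate_frames(read.nt_seq)
        # candidate (gene, frames) to align
        if params.exact:
            cand: dict[str, list[int]] = {g: list(frames) for g in gene_ids}
        else:
            cand = {}
            for f, aa in frames.items():
                if len(aa) < params.kmer_size:
                    continue
                for g in index.candidates(aa, params.min_kmer_hits):
                    cand.setdefault(g, []).append(f)
        best: dict[str, HSP] = {}
        for g, fs in cand.items():
            ref = ref_db[g]
            for f in fs:
                aa = frames[f]
                if not aa:
                    continue
                hsp = align_local(aa, ref, params, read.read_id, g, f)
                if hsp is None:
                    continue
                if g not in best or hsp.bit_score > best[g].bit_score:
                    best[g] = hsp
        qualifying = {
            g: h for g, h in best.items() if h.bit_score > params.bit_threshold
        }
        if not qualifying:
            continue
        top_bits = max(
            round(h.bit_score, params.tie_decimals) for h in qualifying.values()
        )
        tied = sorted(
            g
            for g, h in qualifying.items()
            if round(h.bit_score, params.tie_decimals) == top_bits
        )
        w = 1.0 / len(tied)
        for g in tied:
            h = qualifying[g]
            denom = h.aligned_len - h.gap_columns
            rows.append(
                dict(
                    read_id=h.read_id,
                    gene_id=g,
                    pct_identity=h.pct_identity,
                    aligned_len=h.aligned_len,
                    mismatches=denom - h.identities,
                    gap_columns=h.gap_columns,
                    q_start=h.q_start,
                    q_end=h.q_end,
                    s_start=h.s_start,
                    s_end=h.s_end,
                    evalue=np.nan,
                    bit_score=h.bit_score,
                    frame=h.frame,
                    weight=w,
                )
            )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def taxon_abundance(hits: pd.DataFrame, annotation: pd.DataFrame) -> pd.Series:
    """Weighted read counts per reference taxon (tie weights summed)."""
    ann = annotation.set_index("gene_id")["taxon_id"]
    taxa = hits["gene_id"].map(ann)
    return (
        hits.assign(taxon_id=taxa)
        .groupby("taxon_id", dropna=False)["weight"]
        .sum()
        .sort_values(ascending=False)
    )


def top_taxa(abundance: pd.Series, n: int = 5) -> list[str]:
    """The n most abundant taxa (ties broken by taxon id)."""
    df = abundance.rename("w").reset_index()
    df = df.sort_values(["w", "taxon_id"], ascending=[False, True])
    return df["taxon_id"].head(n).tolist()


def write_hit_table(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_hit_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
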