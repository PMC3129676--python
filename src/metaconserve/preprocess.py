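"""Read preprocessing: FASTA I/O, rRNA filtering, duplicate removal, ORFs.

Mirrors the pre-analysis filtering applied to pyrosequencing read pools:
reads whose best nucleotide local alignment against an rRNA reference
exceeds 50 bits are discarded, exact replicate sequences (identical string
and length, a pyrosequencing artifact) are collapsed to one copy, and the
longest stop-free translated segment of each read provides the amino-acid
sequence used by composition and clustering analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import biotite.sequence as bseq
import biotite.sequence.align as balign
from Bio.Seq import Seq

from .simdata import ReadRecord, revcomp

__all__ = [
    "FilterReport",
    "OrfRecord",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "filter_rrna",
    "dedup_exact",
    "find_orfs",
    "orfs_from_reads",
]

logger = logging.getLogger(__name__)

#: BLASTN-like nucleotide scoring: match +1, mismatch -2, gap open 5, extend 2
NT_MATCH = 1
NT_MISMATCH = -2
NT_GAP_OPEN = 5
NT_GAP_EXTEND = 2
#: ungapped BLASTN-like Karlin-Altschul parameters
NT_LAMBDA = 1.28
NT_K = 0.46

_TRUTH_TAG = "mc|"


class FastaParseError(ValueError):
    """Malformed FASTA input; carries the offending line number."""


@dataclass
class FilterReport:
    """Accounting of a filtering step; the partition identity
    input_count == rrna_removed + duplicates_removed + retained_count holds
    exactly."""

    input_count: int
    rrna_removed: int
    duplicates_removed: int
    retained_count: int

    def __post_init__(self) -> None:
        assert (
            self.input_count
            == self.rrna_removed + self.duplicates_removed + self.retained_count
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("input\trrna_removed\tduplicates_removed\tretained\n")
            fh.write(
                f"{self.input_count}\t{self.rrna_removed}\t"
                f"{self.duplicates_removed}\t{self.retained_count}\n"
            )


@dataclass
class OrfRecord:
    """Longest stop-free translated segment of a read."""

    read_id: str
    pool: Optional[str]
    frame: int  # -3..-1, +1..+3
    aa_seq: str
    nt_seq: str  # in-frame nucleotide segment backing aa_seq
    nt_start: int  # offset within the (frame-oriented) read
    truth: Optional[tuple[str, str, int]] = None


# ---------------------------------------------------------------------------
# FASTA


def _format_header(r: ReadRecord) -> str:
    if r.truth is None and r.pool is None and not (r.is_rrna or r.is_duplicate):
        return r.read_id
    gene, taxon, off = r.truth if r.truth else ("-", "-", -1)
    return (
        f"{r.read_id} {_TRUTH_TAG}pool={r.pool or '-'}|gene={gene}|taxon={taxon}"
        f"|off={off}|rrna={int(r.is_rrna)}|dup={int(r.is_duplicate)}"
    )


def _parse_header(header: str) -> ReadRecord:
    parts = header.split(None, 1)
    read_id = parts[0]
    rec = ReadRecord(read_id=read_id, pool=None, nt_seq="N")
    if len(parts) > 1 and parts[1].startswith(_TRUTH_TAG):
        fields = dict(
            kv.split("=", 1) for kv in parts[1][len(_TRUTH_TAG):].split("|") if "=" in kv
        )
        pool = fields.get("pool", "-")
        rec.pool = None if pool == "-" else pool
        if fields.get("gene", "-") != "-":
            rec.truth = (fields["gene"], fields.get("taxon", "-"), int(fields.get("off", -1)))
        rec.is_rrna = fields.get("rrna", "0") == "1"
        rec.is_duplicate = fields.get("dup", "0") == "1"
    return rec


def read_fasta(path, pool: Optional[str] = None) -> list[ReadRecord]:
    """Parse a (wrapped or unwrapped) FASTA file into ReadRecords.

    Sequence case is normalised to upper.  Headers written by
    :func:`write_fasta` round-trip their ground-truth fields; plain headers
    yield records with no truth and the ``pool`` argument (if given).
    """
    records: list[ReadRecord] = []
    header: Optional[str] = None
    header_line = 0
    chunks: list[str] = []

    def flush():
        if header is None:
            return
        rec = _parse_header(header)
        seq = "".join(chunks).upper()
        if not seq:
            raise FastaParseError(f"record at line {header_line} has no sequence")
        rec.nt_seq = seq
        if rec.pool is None:
            rec.pool = pool
        records.append(rec)

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"line {lineno}: sequence data before any '>' header"
                    )
                chunks.append(line)
        flush()
    if not records:
        logger.warning("no FASTA records parsed from %s", path)
    return records


def write_fasta(records: Sequence[ReadRecord], path, width: int = 70) -> None:
    """Write ReadRecords as FASTA; truth fields are encoded in the header."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{_format_header(r)}\n")
            for i in range(0, len(r.nt_seq), width):
                fh.write(r.nt_seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# rRNA filtering


def nt_bit_score(raw: float) -> float:
    return (NT_LAMBDA * raw - np.log(NT_K)) / np.log(2.0)


_NT_ALPHABET = bseq.NucleotideSequence.alphabet_unamb
_NT_MATRIX = balign.SubstitutionMatrix(
    _NT_ALPHABET,
    _NT_ALPHABET,
    np.where(np.eye(4, dtype=bool), NT_MATCH, NT_MISMATCH).astype(np.int32),
)


def _sanitize_nt(seq: str) -> str:
    return "".join(b if b in "ACGT" else "A" for b in seq.upper())


def _nt_local_score(query: str, ref: str) -> float:
    q = bseq.NucleotideSequence(_sanitize_nt(query))
    r = bseq.NucleotideSequence(_sanitize_nt(ref))
    alns = balign.align_optimal(
        q,
        r,
        _NT_MATRIX,
        gap_penalty=(-(NT_GAP_OPEN + NT_GAP_EXTEND), -NT_GAP_EXTEND),
        local=True,
        max_number=1,
    )
    return float(alns[0].score) if alns else 0.0


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def filter_rrna(
    reads: Sequence[ReadRecord],
    rrna_refs: Sequence[str],
    bit_threshold: float = 50.0,
    exact: bool = False,
    kmer_size: int = 11,
    min_kmer_hits: int = 5,
) -> tuple[list[ReadRecord], FilterReport]:
    """Remove reads whose best local alignment to any rRNA reference exceeds
    ``bit_threshold`` bits (both strands searched).

    By default candidate read/reference pairs are pruned with a shared
    ``kmer_size``-mer count; ``exact=True`` aligns every pair.
    """
    reads = list(reads)
    if not rrna_refs:
        logger.warning("filter_rrna: empty rRNA reference set, returning input")
        return reads, FilterReport(len(reads), 0, 0, len(reads))
    ref_kmers = [_kmer_set(_sanitize_nt(r), kmer_size) for r in rrna_refs]
    kept: list[ReadRecord] = []
    removed = 0
    for read in reads:
        hit = False
        for strand_seq in (read.nt_seq, revcomp(_sanitize_nt(read.nt_seq))):
            qk = _kmer_set(_sanitize_nt(strand_seq), kmer_size)
            for ref, rk in zip(rrna_refs, ref_kmers):
                if not exact and len(qk & rk) < min_kmer_hits:
                    continue
                if nt_bit_score(_nt_local_score(strand_seq, ref)) > bit_threshold:
                    hit = True
                    break
            if hit:
                break
        if hit:
            removed += 1
        else:
            kept.append(read)
    return kept, FilterReport(len(reads), removed, 0, len(kept))


def dedup_exact(
    reads: Sequence[ReadRecord],
) -> tuple[list[ReadRecord], FilterReport]:
    """Collapse classes of reads with identical sequence (and hence length)
    to the first member by input order."""
    seen: set[str] = set()
    kept: list[ReadRecord] = []
    removed = 0
    for read in reads:
        if read.nt_seq in seen:
            removed += 1
        else:
            seen.add(read.nt_seq)
            kept.append(read)
    return kept, FilterReport(len(reads), 0, removed, len(kept))


# ---------------------------------------------------------------------------
# ORF identification


def _frame_seqs(nt: str) -> list[tuple[int, str, str]]:
    """(frame, oriented nt, translation) for frames +1..+3, -1..-3."""
    out = []
    rc = revcomp(nt)
    for frame in (1, 2, 3):
        for strand, seq in ((1, nt), (-1, rc)):
            sub = seq[frame - 1 :]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            aa = str(Seq(sub).translate(table=1))
            out.append((strand * frame, sub, aa))
    order = [1, 2, 3, -1, -2, -3]
    out.sort(key=lambda t: order.index(t[0]))
    return out


def find_orfs(
    read: ReadRecord, min_len_aa: int = 20, min_read_len_nt: int = 60
) -> list[OrfRecord]:
    """Longest stop-free translated segment of a read across all six frames.

    Returns the maximal segments, ordered +1, +2, +3, -1, -2, -3: usually a
    single ORF, but when several frames tie for the maximal length (a read
    whose wrong frame happens to be stop-free as well) every tied candidate
    is reported, since the frame is genuinely ambiguous.  Empty list when no
    stop-free segment of at least ``min_len_aa`` residues exists (such reads
    are skipped by the composition and clustering analyses).
    """
    if len(read.nt_seq) < min_read_len_nt:
        return []
    found: list[OrfRecord] = []
    for frame, nt, aa in _frame_seqs(read.nt_seq):
        pos = 0
        for segment in aa.split("*"):
            if len(segment) >= min_len_aa:
                found.append(
                    OrfRecord(
                        read_id=read.read_id,
                        pool=read.pool,
                        frame=frame,
                        aa_seq=segment,
                        nt_seq=nt[3 * pos : 3 * (pos + len(segment))],
                        nt_start=3 * pos,
                        truth=read.truth,
                    )
                )
            pos += len(segment) + 1
    if not found:
        return []
    longest = max(len(o.aa_seq) for o in found)
    return [o for o in found if len(o.aa_seq) == longest]


def orfs_from_reads(
    reads: Sequence[ReadRecord], min_len_aa: int = 20, min_read_len_nt: int = 60
) -> list[OrfRecord]:
    """One ORF per read: the first (lowest-frame) maximal segment."""
    out: list[OrfRecord] = []
    for r in reads:
        orfs = find_orfs(r, min_len_aa=min_len_aa, min_read_len_nt=min_read_len_nt)
        if orfs:
            out.append(orfs[0])
    return out
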