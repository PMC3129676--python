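"""Translated search: frames, local alignment, bit scores, tie weighting."""

import math

import numpy as np
import pytest

from metaconserve.homology import (
    ScoringParams,
    align_local,
    bit_score,
    search_reads,
    taxon_abundance,
    top_taxa,
    translate_frames,
)
from metaconserve.simdata import (
    CODON_TO_AA,
    CommunityConfig,
    ReadRecord,
    revcomp,
    simulate_community,
)

import pandas as pd

AAS = "ACDEFGHIKLMNPQRSTVWY"

# standard BLOSUM62 scores feed the independent Smith-Waterman oracle;
# the DP recursion below shares no code with the implementation under test
import biotite.sequence.align as _balign

_MAT = _balign.SubstitutionMatrix.std_protein_matrix()


def _b62(a, b):
    return _MAT.get_score(a, b)


def sw_score(q: str, r: str, gap_open=11, gap_extend=1) -> int:
    """Independent affine-gap Smith-Waterman (Gotoh) on raw scores.

    A gap of length n costs open + n*extend, matching the BLAST convention.
    """
    n, m = len(q), len(r)
    neg = -(10**9)
    best = 0
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in r (up)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in q (left)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - gap_open - gap_extend, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open - gap_extend, F[i][j - 1] - gap_extend)
            diag = H[i - 1][j - 1] + _b62(q[i - 1], r[j - 1])
            H[i][j] = max(0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestTranslateFrames:
    def test_simple_codon_lookup(self):
        assert translate_frames("ATGGCC")[1] == "MA"

    def test_reverse_complement_symmetry(self, rng):
        nt = "".join(rng.choice(list("ACGT"), 99))
        assert translate_frames(revcomp(nt))[1] == translate_frames(nt)[-1]

    def test_against_codon_table_oracle(self, rng):
        nt = "".join(rng.choice(list("ACGT"), 300))
        frames = translate_frames(nt)
        stops = {"TAA", "TAG", "TGA"}

        def oracle(seq):
            return "".join(
                CODON_TO_AA.get(seq[i : i + 3], "*")
                if seq[i : i + 3] not in stops
                else "*"
                for i in range(0, len(seq) - len(seq) % 3, 3)
            )

        rc = revcomp(nt)
        for f in (1, 2, 3):
            assert frames[f] == oracle(nt[f - 1 :])
            assert frames[-f] == oracle(rc[f - 1 :])

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            translate_frames("AT")


class TestAlignLocal:
    def test_identical_sequences(self, rng):
        seq = "".join(rng.choice(list(AAS), 50))
        hsp = align_local(seq, seq)
        assert hsp.pct_identity == 100.0
        assert hsp.gap_columns == 0
        assert hsp.aligned_len == 50

    def test_single_mismatch(self):
        hsp = align_local("ACDEFG", "ACDYFG")
        assert hsp.aligned_len == 6
        assert hsp.identities == 5
        assert hsp.pct_identity == pytest.approx(83.3, abs=0.05)

    def test_gap_columns_excluded_from_identity(self):
        # the optimal alignment is AC-DEFWW / ACGDEFWW: one gap column,
        # all aligned residues identical
        hsp = align_local("ACDEFWWKLM", "ACGDEFWWKLM")
        assert hsp.gap_columns == 1
        assert hsp.pct_identity == 100.0

    def test_scores_match_independent_smith_waterman(self, rng):
        for _ in range(25):
            q = "".join(rng.choice(list(AAS), rng.integers(10, 30)))
            r = "".join(rng.choice(list(AAS), rng.integers(10, 30)))
            hsp = align_local(q, r)
            expected = sw_score(q, r)
            got = 0 if hsp is None else hsp.raw_score
            assert got == expected


class TestBitScore:
    def test_closed_form_values(self):
        p = ScoringParams()
        assert bit_score(0, p) == pytest.approx(4.61, abs=0.01)
        assert bit_score(100, p) == pytest.approx(43.1, abs=0.05)

    def test_monotone(self):
        p = ScoringParams()
        assert bit_score(120, p) > bit_score(80, p)


def _brute_force_hits(reads, ref_db, params):
    """Oracle: exhaustive all-frames x all-genes alignment + the published
    top-hit/tie rule, written independently of search_reads internals."""
    rows = []
    for read in reads:
        frames = translate_frames(read.nt_seq)
        best = {}
        for g, ref in ref_db.items():
            for f, aa in frames.items():
                if not aa:
                    continue
                hsp = align_local(aa, ref, params, read.read_id, g, f)
                if hsp is None:
                    continue
                if g not in best or hsp.bit_score > best[g].bit_score:
                    best[g] = hsp
        qual = {g: h for g, h in best.items() if h.bit_score > params.bit_threshold}
        if not qual:
            continue
        top = max(round(h.bit_score, params.tie_decimals) for h in qual.values())
        tied = sorted(
            g for g, h in qual.items()
            if round(h.bit_score, params.tie_decimals) == top
        )
        for g in tied:
            rows.append((read.read_id, g, 1.0 / len(tied)))
    return sorted(rows)


class TestSearchReads:
    def test_verbatim_read_hits_its_gene(self):
        sim = simulate_community(
            CommunityConfig(n_taxa=1, genes_per_taxon=10, divergence_expressed=0,
                            divergence_nonexpressed=0, divergence_sd=0,
                            n_dna_reads=20, n_rna_reads=0, seed=31)
        )
        db = sim.panel.protein_db()
        hits = search_reads(sim.dna_reads, db)
        for read in sim.dna_reads:
            sub = hits[hits["read_id"] == read.read_id]
            assert len(sub) == 1
            assert sub["gene_id"].iloc[0] == read.truth[0]
            assert sub["weight"].iloc[0] == 1.0
            assert sub["pct_identity"].iloc[0] == 100.0

    def test_duplicated_gene_splits_weight(self):
        sim = simulate_community(
            CommunityConfig(n_taxa=1, genes_per_taxon=3, divergence_expressed=0,
                            divergence_nonexpressed=0, divergence_sd=0,
                            n_dna_reads=10, n_rna_reads=0, seed=32)
        )
        db = sim.panel.protein_db()
        gid = sim.dna_reads[0].truth[0]
        db["copy_of_" + gid] = db[gid]
        hits = search_reads([sim.dna_reads[0]], db)
        assert len(hits) == 2
        assert set(hits["gene_id"]) == {gid, "copy_of_" + gid}
        assert np.allclose(hits["weight"], 0.5)

    def test_tie_weights_sum_to_one(self, small_result):
        per_read = small_result.dna_hits.groupby("read_id")["weight"].sum()
        assert np.allclose(per_read, 1.0)

    @pytest.mark.parametrize("seed", [41, 42, 43])
    def test_matches_brute_force_oracle(self, seed):
        cfg = CommunityConfig(n_taxa=2, genes_per_taxon=8, n_dna_reads=25,
                              n_rna_reads=0, divergence_nonexpressed=0.3,
                              seed=seed)
        sim = simulate_community(cfg)
        db = sim.panel.protein_db()
        params = ScoringParams(exact=True)
        hits = search_reads(sim.dna_reads, db, params)
        got = sorted(zip(hits["read_id"], hits["gene_id"], hits["weight"]))
        assert got == _brute_force_hits(sim.dna_reads, db, params)

    def test_prefilter_agrees_with_exact_on_assignments(self):
        cfg = CommunityConfig(n_taxa=2, genes_per_taxon=10, n_dna_reads=60,
                              n_rna_reads=0, seed=44)
        sim = simulate_community(cfg)
        db = sim.panel.protein_db()
        fast = search_reads(sim.dna_reads, db, ScoringParams(exact=False))
        exact = search_reads(sim.dna_reads, db, ScoringParams(exact=True))
        fast_pairs = set(zip(fast["read_id"], fast["gene_id"]))
        exact_pairs = set(zip(exact["read_id"], exact["gene_id"]))
        assert fast_pairs == exact_pairs

    def test_empty_db_raises(self):
        with pytest.raises(ValueError):
            search_reads([], {})


class TestTaxonAbundance:
    def test_weights_grouped_by_taxon(self):
        hits = pd.DataFrame(
            dict(read_id=["r1", "r2", "r2"], gene_id=["a", "a", "b"],
                 weight=[1.0, 0.5, 0.5])
        )
        ann = pd.DataFrame(dict(gene_id=["a", "b"], taxon_id=["T1", "T2"]))
        ab = taxon_abundance(hits, ann)
        assert ab["T1"] == 1.5
        assert ab["T2"] == 0.5
        assert top_taxa(ab, 1) == ["T1"]

    def test_mixture_recovery(self):
        cfg = CommunityConfig(n_taxa=2, genes_per_taxon=15,
                              taxon_abundances=(0.7, 0.3),
                              n_dna_reads=1200, n_rna_reads=0, seed=45)
        sim = simulate_community(cfg)
        hits = search_reads(sim.dna_reads, sim.panel.protein_db())
        ab = taxon_abundance(hits, sim.panel.annotation())
        props = ab / ab.sum()
        assert props["T00"] == pytest.approx(0.7, abs=0.04)
        assert props["T01"] == pytest.approx(0.3, abs=0.04)
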