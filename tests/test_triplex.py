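"""Hoogsteen code, purine tracts and the TFO↔TTS search."""

import numpy as np
import pytest

import triplexkit as tk
from triplexkit import sequences as sq
from triplexkit.triplex import TRIPLEX_CODES, find_tts_many

from _oracles import brute_force_hits, brute_force_purine_tracts
from conftest import random_dna, random_rna


class TestHoogsteenCode:
    @pytest.mark.parametrize("third,purine,motif,expected", [
        ("G", "G", "antiparallel_purine", True),
        ("A", "A", "antiparallel_purine", True),
        ("T", "A", "antiparallel_purine", True),
        ("C", "A", "antiparallel_purine", False),
        ("C", "G", "antiparallel_purine", False),
        ("C", "G", "parallel_pyrimidine", True),
        ("T", "A", "parallel_pyrimidine", True),
        ("U", "A", "parallel_pyrimidine", True),   # U normalized to T
        ("G", "G", "parallel_pyrimidine", False),
        ("G", "G", "parallel_mixed", True),
        ("T", "A", "parallel_mixed", True),
        ("A", "A", "parallel_mixed", False),
    ])
    def test_code_table_entries(self, third, purine, motif, expected):
        assert tk.hoogsteen_allowed(third, purine, motif) is expected

    def test_rules_are_total(self):
        for motif in TRIPLEX_CODES:
            for a in "ACGT":
                for b in "ACGTU":
                    assert tk.hoogsteen_allowed(a, b, motif) in (True, False)

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(ValueError, match="ambiguity"):
            tk.hoogsteen_allowed("N", "A", "antiparallel_purine")
        with pytest.raises(ValueError, match="unknown motif"):
            tk.hoogsteen_allowed("A", "A", "sideways")

    def test_default_motif_tables_exact(self):
        """The purine motif allows exactly G·G, A·A, T·A; pyrimidine C·G, T·A."""
        purine_pairs = {(t, p) for t in "ACGT" for p in "ACGT"
                        if tk.hoogsteen_allowed(t, p, "antiparallel_purine")}
        assert purine_pairs == {("G", "G"), ("A", "A"), ("T", "A")}
        pyr_pairs = {(t, p) for t in "ACGT" for p in "ACGT"
                     if tk.hoogsteen_allowed(t, p, "parallel_pyrimidine")}
        assert pyr_pairs == {("C", "G"), ("T", "A")}


class TestNucleicSeq:
    def test_alphabet_enforced(self):
        with pytest.raises(ValueError):
            tk.NucleicSeq("x", "DNA", "ACGU")
        with pytest.raises(ValueError):
            tk.NucleicSeq("x", "RNA", "ACGT")
        with pytest.raises(ValueError):
            tk.NucleicSeq("x", "DNA", "ACGN")
        with pytest.raises(ValueError):
            tk.NucleicSeq("x", "DNA", "")

    def test_u_t_equivalence_on_comparison_only(self):
        rna = tk.NucleicSeq("r", "RNA", "GAUC")
        assert rna.bases == "GAUC"
        assert rna.dna_bases == "GATC"


class TestPurineTracts:
    def test_homopolymer_tracts(self):
        plus = tk.purine_tracts("A" * 20, min_len=12, max_pyrimidine_interruptions=2)
        assert [(t.start, t.end, t.strand) for t in plus] == [(0, 20, "+")]
        # all-C: the purine run lives on the complementary strand
        minus = tk.purine_tracts("C" * 20, min_len=12, max_pyrimidine_interruptions=2)
        assert [(t.start, t.end, t.strand) for t in minus] == [(0, 20, "-")]

    def test_epha2_ga_strand_against_enumeration(self):
        seq = sq.EPHA2_GA.bases
        got = sorted((t.start, t.end, t.strand)
                     for t in tk.purine_tracts(seq, 12, 2))
        assert got == brute_force_purine_tracts(seq, 12, 2)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_sequences_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(int(rng.integers(20, 60)), rng)
        min_len = int(rng.integers(6, 14))
        budget = int(rng.integers(0, 4))
        got = sorted((t.start, t.end, t.strand)
                     for t in tk.purine_tracts(seq, min_len, budget))
        assert got == brute_force_purine_tracts(seq, min_len, budget)

    def test_interruption_count_recorded(self):
        tracts = tk.purine_tracts("AAAAACAAAAAA", min_len=12,
                                  max_pyrimidine_interruptions=1)
        (t,) = [t for t in tracts if t.strand == "+"]
        assert t.n_interruptions == 1


class TestFindTts:
    def test_perfect_polya_hit(self):
        tfo = tk.NucleicSeq("a15", "RNA", "A" * 15)
        duplex = tk.NucleicSeq("d", "DNA", "A" * 15)
        hits = tk.find_tts(tfo, duplex, min_len=12)
        purine_hits = [h for h in hits if h.motif == "antiparallel_purine"]
        assert any(h.mismatches == 0 and h.length == 15 for h in purine_hits)

    def test_tfo2_23_finds_epha2_target(self):
        """The TFR2 third strand hits its intron-1 EPHA2 site (>= 12 nt,
        antiparallel purine motif), from either printed strand."""
        for duplex in (sq.EPHA2_GA, sq.EPHA2_CT):
            hits = tk.find_tts(sq.TFO2_23, duplex)
            ap = [h for h in hits if h.motif == "antiparallel_purine"]
            assert ap, f"no purine-motif hit on {duplex.id}"
            assert max(h.length for h in ap) >= 12
        # exact coordinates agree with exhaustive enumeration
        got = tk.find_tts(sq.TFO2_23, sq.EPHA2_GA)
        assert got == brute_force_hits(sq.TFO2_23, sq.EPHA2_GA, 12, 0.2,
                                       tk.DEFAULT_MOTIFS)

    def test_matchless_alphabets_give_empty(self):
        # all-C TFO pairs only with G; an A/T-only duplex has no G on
        # either strand, so no window can even start
        rng = np.random.default_rng(5)
        tfo = tk.NucleicSeq("c", "RNA", "C" * 20)
        duplex = tk.NucleicSeq("d", "DNA",
                               "".join("AT"[b] for b in rng.integers(0, 2, 200)))
        assert tk.find_tts(tfo, duplex) == []

    def test_min_len_longer_than_tfo_warns_empty(self):
        tfo = tk.NucleicSeq("t", "RNA", "A" * 10)
        duplex = tk.NucleicSeq("d", "DNA", "A" * 30)
        with pytest.warns(UserWarning, match="min_len"):
            assert tk.find_tts(tfo, duplex, min_len=12) == []

    @pytest.mark.parametrize("seed", range(60))
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(900 + seed)
        tfo = tk.NucleicSeq("t", "RNA", random_rna(int(rng.integers(12, 26)), rng))
        duplex = tk.NucleicSeq("d", "DNA", random_dna(int(rng.integers(12, 41)), rng))
        min_len = int(rng.integers(12, 16))
        rate = float(rng.choice([0.0, 0.1, 0.2, 0.25]))
        assert tk.find_tts(tfo, duplex, min_len, rate) == \
            brute_force_hits(tfo, duplex, min_len, rate, tk.DEFAULT_MOTIFS)

    @pytest.mark.parametrize("seed", range(20))
    def test_strand_symmetry(self, seed):
        """Reverse-complementing the duplex mirrors coordinates and strands."""
        rng = np.random.default_rng(300 + seed)
        n = int(rng.integers(20, 60))
        tfo = tk.NucleicSeq("t", "RNA", random_rna(int(rng.integers(14, 24)), rng))
        duplex = tk.NucleicSeq("d", "DNA", random_dna(n, rng))
        flipped = tk.NucleicSeq("d", "DNA", tk.reverse_complement(duplex.bases))
        fwd = tk.find_tts(tfo, duplex, 12, 0.2)
        rev = tk.find_tts(tfo, flipped, 12, 0.2)
        mirrored = sorted(
            (n - h.end, n - h.start, {"+": "-", "-": "+"}[h.strand],
             h.tfo_start, h.tfo_end, h.motif, h.mismatches)
            for h in rev
        )
        assert mirrored == sorted(
            (h.start, h.end, h.strand, h.tfo_start, h.tfo_end, h.motif,
             h.mismatches) for h in fwd
        )

    @pytest.mark.parametrize("seed", range(15))
    def test_relaxing_constraints_never_loses_coverage(self, seed):
        """Every hit at strict settings lies inside a hit at looser ones."""
        rng = np.random.default_rng(700 + seed)
        tfo = tk.NucleicSeq("t", "RNA", random_rna(22, rng))
        duplex = tk.NucleicSeq("d", "DNA", random_dna(40, rng))
        strict = tk.find_tts(tfo, duplex, min_len=14, max_error_rate=0.1)
        loose = tk.find_tts(tfo, duplex, min_len=12, max_error_rate=0.2)
        for h in strict:
            assert any(
                g.motif == h.motif and g.strand == h.strand
                and g.start <= h.start and g.end >= h.end
                and g.tfo_start <= h.tfo_start and g.tfo_end >= h.tfo_end
                for g in loose
            ), f"hit {h} lost after relaxing constraints"

    @pytest.mark.parametrize("seed", range(15))
    def test_hits_satisfy_their_own_invariants(self, seed):
        rng = np.random.default_rng(40 + seed)
        tfo = tk.NucleicSeq("t", "RNA", random_rna(25, rng))
        duplex = tk.NucleicSeq("d", "DNA", random_dna(60, rng))
        min_len, rate = 12, 0.2
        hits = tk.find_tts(tfo, duplex, min_len, rate)
        for h in hits:
            assert h.length >= min_len
            assert h.mismatches / h.length <= rate + 1e-9
            assert h.end - h.start == h.length == h.tfo_end - h.tfo_start
            assert h.score == h.length - h.mismatches
        assert hits == sorted(hits, key=lambda h: (h.chrom, h.start, h.tfo_start,
                                                   h.motif, h.strand))

    def test_batch_scan_equals_individual_scans(self):
        rng = np.random.default_rng(77)
        tfo = tk.NucleicSeq("t", "RNA", random_rna(40, rng))
        duplexes = [
            tk.NucleicSeq(f"d{k}", "DNA", random_dna(int(rng.integers(15, 90)), rng))
            for k in range(12)
        ]
        assert find_tts_many(tfo, duplexes) == [tk.find_tts(tfo, d) for d in duplexes]
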