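"""Unit and property tests of the structural 3'-terminus scanner."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracle import naive_termini
from heliscan import (
    EmptyInputError,
    InvalidAlphabetError,
    ScanParameters,
    SequenceRecord,
    find_3prime_termini,
    find_5prime_ends,
    find_hairpins,
    reverse_complement,
    scan_genome,
)

ARM = "GCGGCGGC"
ARM_RC = "GCCGCCGC"  # reverse complement of ARM


def cassette(arm=ARM, loop="ATAT", spacer="ATT", lead="A" + "TC" + "AT" * 20):
    return lead + arm + loop + reverse_complement(arm) + spacer + "CTAG" + "T"


@pytest.mark.parametrize(
    "seq,expected",
    [("ACGT", "ACGT"), ("TC", "GA"), ("AACGT", "ACGTT"), ("NAN", "NTN"),
     ("acgt", "acgt")],
)
def test_reverse_complement(seq, expected):
    assert reverse_complement(seq) == expected


def test_reverse_complement_rejects_bad_character():
    with pytest.raises(InvalidAlphabetError, match="position 2"):
        reverse_complement("ACXGT")


class TestFindHairpins:
    def test_single_planted_hairpin(self):
        rec = SequenceRecord("x", "AAAA" + ARM + "ATAT" + ARM_RC + "AAAA")
        hits = find_hairpins(rec, ScanParameters(arm_min=6))
        assert len(hits) == 1
        (h,) = hits
        assert h.arm_seq == ARM
        assert h.loop_len == 4
        assert (h.left_start, h.left_end, h.right_start, h.right_end) == (4, 12, 16, 24)

    def test_right_arm_is_reverse_complement(self):
        rec = SequenceRecord("x", "TT" + ARM + "AAA" + ARM_RC + "TT")
        (h,) = find_hairpins(rec)
        seq = rec.seq
        assert seq[h.right_start : h.right_end] == reverse_complement(
            seq[h.left_start : h.left_end]
        )

    def test_no_gc_no_hairpins(self):
        assert find_hairpins(SequenceRecord("x", "A" * 1000)) == []

    def test_too_short_sequence(self):
        p = ScanParameters()
        rec = SequenceRecord("x", "G" * (2 * p.arm_min - 1))
        assert find_hairpins(rec, p) == []


class TestFind3PrimeTermini:
    def test_planted_cassette_found_once(self):
        seq = "AT" * 60 + cassette() + "TA" * 60
        cands = find_3prime_termini(SequenceRecord("c", seq))
        assert len(cands) == 1
        (c,) = cands
        assert c.strand == "+"
        assert c.end3_motif == "CTAG"
        assert seq[c.end3_pos - 4 : c.end3_pos] == "CTAG"

    def test_spacer_beyond_bound_rejected(self):
        seq = "AT" * 60 + cassette(spacer="A" * 11) + "TA" * 60
        assert find_3prime_termini(SequenceRecord("c", seq)) == []

    def test_reverse_complement_fixture_maps_back(self):
        seq = "AT" * 60 + cassette() + "TA" * 60
        fwd = find_3prime_termini(SequenceRecord("c", seq))
        rev = find_3prime_termini(SequenceRecord("c", reverse_complement(seq)))
        assert len(rev) == 1
        (f,), (r,) = fwd, rev
        assert r.strand == "-"
        # the motif occupies the same forward-strand interval after mapping
        n = len(seq)
        assert r.end3_pos == n - f.end3_pos + 1
        assert (r.hairpin.left_start, r.hairpin.right_end) == (
            n - f.hairpin.right_end,
            n - f.hairpin.left_start,
        )

    def test_all_n_record(self):
        assert find_3prime_termini(SequenceRecord("n", "N" * 500)) == []

    def test_lowercase_input_scanned_uppercase(self):
        seq = ("AT" * 60 + cassette() + "TA" * 60).lower()
        assert len(find_3prime_termini(SequenceRecord("c", seq))) == 1


class TestFind5PrimeEnds:
    def _scan_one(self, seq):
        rec = SequenceRecord("c", seq)
        (cand,) = find_3prime_termini(rec)
        return find_5prime_ends(cand, rec), rec

    def test_single_atc_upstream(self):
        lead = "A" + "TC" + "AT" * 74 + "AA"  # one TC, 150 bases from hairpin
        seq = "AA" + cassette(lead=lead) + "TT"
        cand, rec = self._scan_one(seq)
        assert len(cand.five_prime_positions) == 1
        (pos,) = cand.five_prime_positions
        assert rec.seq[pos - 1 : pos + 1] == "TC"
        assert cand.target_site_ok

    def test_no_tc_in_window_keeps_candidate(self):
        seq = "AA" + cassette(lead="A" * 100) + "TT"
        cand, _ = self._scan_one(seq)
        assert cand.five_prime_positions == []
        assert not cand.target_site_ok

    def test_multiple_tc_nearest_first(self):
        lead = "ATC" + "A" * 40 + "TC" + "A" * 40 + "TC" + "A" * 40
        seq = cassette(lead=lead)
        cand, rec = self._scan_one(seq)
        assert len(cand.five_prime_positions) == 3
        assert cand.five_prime_positions == sorted(
            cand.five_prime_positions, reverse=True
        )

    def test_upstream_window_limits_search(self):
        lead = "ATC" + "A" * 200
        seq = cassette(lead=lead)
        rec = SequenceRecord("c", seq)
        p = ScanParameters(upstream_window=50)
        (cand,) = find_3prime_termini(rec, p)
        assert find_5prime_ends(cand, rec, p).five_prime_positions == []


class TestScanGenome:
    def test_one_candidate_per_record(self):
        recs = [
            SequenceRecord(f"r{i}", "AT" * 50 + cassette() + "TA" * 50)
            for i in range(10)
        ]
        cands = scan_genome(recs)
        assert len(cands) == 10
        assert [c.seq_id for c in cands] == [f"r{i}" for i in range(10)]
        assert [c.id for c in cands] == [f"r{i}H1" for i in range(10)]

    def test_worker_count_does_not_change_output(self, rng):
        from conftest import random_seq

        recs = [
            SequenceRecord(f"r{i}", random_seq(rng, 3000)) for i in range(6)
        ]
        one = scan_genome(recs, ScanParameters(worker_count=1))
        four = scan_genome(recs, ScanParameters(worker_count=4))
        assert one == four

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInputError):
            scan_genome([])

    def test_all_n_record_yields_nothing(self):
        assert scan_genome([SequenceRecord("n", "N" * 300)]) == []


def _key_set(cands):
    return {
        (
            c.strand,
            c.end3_pos,
            (
                c.hairpin.left_start,
                c.hairpin.left_end,
                c.hairpin.loop_len,
                c.hairpin.right_start,
                c.hairpin.right_end,
            ),
        )
        for c in cands
    }


class TestProperties:
    @pytest.mark.parametrize("seed", range(12))
    @pytest.mark.parametrize("fuzzy", [1, 3])
    def test_matches_naive_enumerator(self, seed, fuzzy):
        """The fast motif-anchored scan equals exhaustive enumeration of
        every (arm length, arm start, loop, spacer) combination."""
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ATGC"), size=2000))
        p = ScanParameters(fuzzy_level=fuzzy)
        got = _key_set(find_3prime_termini(SequenceRecord("s", seq), p))
        assert got == naive_termini(seq, p)

    def test_matches_naive_on_planted_genome(self, planted):
        rec, _ = planted
        p = ScanParameters()
        got = _key_set(find_3prime_termini(rec, p))
        assert got == naive_termini(rec.seq, p)

    @pytest.mark.parametrize("seed", range(8))
    def test_strand_symmetry(self, seed):
        """Scanning the reverse complement swaps strands and preserves
        forward-strand hairpin intervals."""
        rng = np.random.default_rng(100 + seed)
        seq = "".join(rng.choice(list("ATGC"), size=2000))
        n = len(seq)
        fwd = find_3prime_termini(SequenceRecord("s", seq))
        rev = find_3prime_termini(SequenceRecord("s", reverse_complement(seq)))

        def intervals(cands):
            return sorted(
                (
                    {"+": "-", "-": "+"}[c.strand],
                    n - c.hairpin.right_end,
                    n - c.hairpin.left_start,
                )
                for c in cands
            )

        assert intervals(fwd) == sorted(
            (c.strand, c.hairpin.left_start, c.hairpin.right_end) for c in rev
        )
        assert len(fwd) == len(rev)

    @pytest.mark.parametrize("seed", range(6))
    def test_fuzzy_level_monotone(self, seed):
        """Stricter terminal-motif levels yield subsets of looser ones."""
        rng = np.random.default_rng(300 + seed)
        seq = "".join(rng.choice(list("ATGC"), size=4000))
        rec = SequenceRecord("s", seq)
        keys = {
            lvl: {
                (c.strand, c.end3_pos)
                for c in find_3prime_termini(rec, ScanParameters(fuzzy_level=lvl))
            }
            for lvl in (0, 1, 2, 3)
        }
        assert keys[0] <= keys[1] <= keys[2] <= keys[3]

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_planting_completeness(self, seed):
        """Every planted cassette in an A/T background is recovered, with
        at least one 5' end, and nothing else is reported."""
        from heliscan import PlantSpec, make_planted_genome

        k = seed % 6
        rec, truth = make_planted_genome(
            PlantSpec(n_cassettes=k, background_length=8000, seed=seed)
        )
        cands = scan_genome([rec])
        assert len(cands) == k
        assert sorted(c.end3_pos for c in cands) == sorted(truth.end3_pos)
        assert all(len(c.five_prime_positions) >= 1 for c in cands)
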