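import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirddr.annotate import UniqueTag
from mirddr.formats import revcomp
from mirddr.hairpin import (
    HairpinCandidate,
    HairpinParams,
    check_criteria,
    discover_novel,
    excise_precursors,
    fold,
    pair_table,
    star_support,
)

MIN_LOOP = 3


def max_pairs_bruteforce(seq: str) -> int:
    """Independent exhaustive recursion over all nested structures."""
    pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}

    def best(i: int, j: int) -> int:
        if j - i <= MIN_LOOP:
            return 0
        result = best(i + 1, j)  # i unpaired
        for k in range(i + MIN_LOOP + 1, j + 1):
            if (seq[i], seq[k]) in pairs:
                result = max(result, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return result

    return best(0, len(seq) - 1)


class TestFold:
    def test_simple_hairpin(self):
        structure, n = fold("GGGAAACCC")
        assert structure == "(((...)))"
        assert n == 3

    def test_no_complementarity(self):
        structure, n = fold("AAAAAA")
        assert structure == "......"
        assert n == 0

    def test_perfect_inverted_repeat(self):
        arm = "GACGTACGGTACC"  # 13 nt
        seq = arm + "AAAA" + revcomp(arm)  # 30 nt, 4-nt loop
        structure, n = fold(seq)
        assert n == 13
        assert structure == "(" * 13 + "...." + ")" * 13

    def test_length_guard(self):
        with pytest.raises(ValueError):
            fold("")
        with pytest.raises(ValueError):
            fold("A" * 401)

    def test_matches_bruteforce_on_random_sequences(self):
        rng = random.Random(42)
        for _ in range(60):
            n = rng.randint(1, 14)
            seq = "".join(rng.choice("ACGT") for _ in range(n))
            structure, pairs = fold(seq)
            assert pairs == max_pairs_bruteforce(seq), seq

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=12))
    def test_structure_always_valid(self, seq):
        structure, pairs = fold(seq)
        partner = pair_table(structure)  # raises on imbalance
        assert sum(p >= 0 for p in partner) == 2 * pairs
        for i, p in enumerate(partner):
            if p > i:
                assert p - i > MIN_LOOP  # min hairpin loop respected
                assert (seq[i], seq[p]) in {
                    ("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")
                }


class TestExcision:
    GENOME = {"c": "A" * 200 + "GATTACAGATTACAGATTACA" + "C" * 200}

    def _tag(self, seq, hits):
        tag = UniqueTag(seq, 2, 0)
        tag.genome_hits = hits
        return tag

    def test_two_windows_per_hit(self):
        tag = self._tag("GATTACAGATTACAGATTACA", [("c", 200, "+")])
        wins = excise_precursors(tag, self.GENOME, flank=50)
        assert len(wins) == 2
        assert (wins[0].start, wins[0].end) == (150, 221)
        assert (wins[1].start, wins[1].end) == (200, 271)
        assert wins[0].mature_offset == 50 and wins[1].mature_offset == 0

    def test_clipped_at_contig_start(self):
        tag = self._tag("A" * 21, [("c", 5, "+")])
        wins = excise_precursors(tag, self.GENOME, flank=120)
        assert wins[0].start == 0 and wins[0].end == 26

    def test_minus_strand_reverse_complemented(self):
        tag = self._tag(revcomp("GATTACAGATTACAGATTACA"), [("c", 200, "-")])
        wins = excise_precursors(tag, self.GENOME, flank=10)
        assert wins[0].seq.startswith(revcomp("C" * 0))  # oriented 5'->3' on '-'
        assert wins[0].seq[wins[0].mature_offset : wins[0].mature_offset + 21] == tag.sequence

    def test_two_hits_four_windows(self):
        tag = self._tag("GATTACAGATTACAGATTACA", [("c", 200, "+"), ("c", 200, "-")])
        assert len(excise_precursors(tag, self.GENOME, flank=30)) == 4


def perfect_candidate(arm_len=30, mature_len=21, loop=8, seed=3):
    rng = random.Random(seed)
    mature = "".join(rng.choice("ACGT") for _ in range(mature_len))
    arm = mature + "".join(rng.choice("ACGT") for _ in range(arm_len - mature_len))
    precursor = arm + "".join(rng.choice("ACGT") for _ in range(loop)) + revcomp(arm)
    structure, n = fold(precursor)
    return HairpinCandidate(
        contig="c", start=0, end=len(precursor), strand="+",
        precursor_seq=precursor, structure=structure, n_pairs=n,
        mature_arm=(0, mature_len),
    )


class TestCriteria:
    def test_perfect_inverted_repeat_passes(self):
        cand = check_criteria(perfect_candidate())
        assert cand.verdict and cand.reasons == []
        assert cand.duplex_mismatches <= 4
        assert cand.star_arm is not None

    def test_too_many_duplex_mismatches(self):
        # mature arm placed over the loop region: mostly unpaired
        cand = perfect_candidate()
        cand.mature_arm = (25, 21)  # straddles the 8-nt loop
        check_criteria(cand)
        assert not cand.verdict

    def test_unstructured_precursor_fails_pairing_fraction(self):
        seq = "AAAAAAAAAAGGAAAAAAAAAAAGGAAAAAAAAAAAAAGGAAAAAAAAAAAAAAAGGAAAAA"
        structure, n = fold(seq)
        cand = HairpinCandidate("c", 0, len(seq), "+", seq, structure, n, (0, 21))
        check_criteria(cand)
        assert "pairing_fraction" in cand.reasons

    def test_mature_length_bounds(self):
        cand = perfect_candidate(mature_len=19)
        check_criteria(cand)
        assert "mature_length" in cand.reasons

    def test_mature_outside_precursor_is_error(self):
        cand = perfect_candidate()
        cand.mature_arm = (100, 21)
        with pytest.raises(ValueError):
            check_criteria(cand)

    def test_asymmetric_bulge_detected(self):
        # hand-built structure: mature pairs jump 4 positions on the star side
        seq = "A" * 60
        structure = list("." * 60)
        partners = [(0, 59), (1, 58), (2, 53), (3, 52), (4, 51)]
        for a, b in partners:
            structure[a], structure[b] = "(", ")"
        cand = HairpinCandidate(
            "c", 0, 60, "+", seq, "".join(structure), len(partners), (0, 5),
        )
        params = HairpinParams(
            max_duplex_mismatches=0, min_pairing_fraction=0.0,
            mature_length_range=(5, 24),
        )
        check_criteria(cand, params)
        assert cand.max_asym_bulge == 4
        assert "asymmetric_bulge" in cand.reasons


class TestStarSupport:
    def _setup(self):
        cand = check_criteria(perfect_candidate())
        star_start = cand.star_expected_start
        star_seq = cand.precursor_seq[star_start : star_start + 21]
        return cand, star_start, star_seq

    def _tag_at(self, seq, pos):
        tag = UniqueTag(seq, 1, 1)
        tag.genome_hits = [("c", pos, "+")]
        return tag

    def test_star_tag_at_expected_start(self):
        cand, start, star_seq = self._setup()
        assert star_support(cand, [self._tag_at(star_seq, start)])

    def test_offset_within_tolerance(self):
        cand, start, star_seq = self._setup()
        assert star_support(cand, [self._tag_at(star_seq, start + 2)])

    def test_five_nt_offset_rejected(self):
        cand, start, star_seq = self._setup()
        assert not star_support(cand, [self._tag_at(star_seq, start + 5)])

    def test_no_star_tag(self):
        cand, _, _ = self._setup()
        assert not star_support(cand, [])


class TestRediscovery:
    def test_planted_loci_rediscovered(self, default_sim):
        found = {l.candidate.contig for l in default_sim.result.novel}
        for locus in default_sim.truth.novel_loci:
            assert locus.contig in found, locus.name

    def test_star_support_matches_truth_exactly(self, default_sim):
        found = {l.candidate.contig: l.star_supported for l in default_sim.result.novel}
        for locus in default_sim.truth.novel_loci:
            assert found[locus.contig] == locus.star_supported, locus.name

    def test_low_support_tags_not_considered(self, default_sim):
        for locus in default_sim.result.novel:
            assert locus.tag.total >= HairpinParams().min_read_support
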