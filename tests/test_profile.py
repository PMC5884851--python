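"""Codon-position substitution profiles and mtDNA expectation comparisons."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from numtscan.codon import FrameSpec, GeneticCode
from numtscan.distance import pair_distance
from numtscan.errors import ComparisonUndefinedError
from numtscan.profile import (
    METRICS,
    MTDNA_EXPECTATION,
    PairProfile,
    compare_to_reference,
    pair_profile,
    round_half_up,
)

CODE5 = GeneticCode.from_ncbi_id(5)

codon_seq = st.lists(
    st.sampled_from([c for c, aa in CODE5.codon_map.items() if aa != "*"]),
    min_size=2,
    max_size=20,
).map("".join)


def frame_for(seq):
    return FrameSpec.for_length(len(seq), 0)


class TestPairProfile:
    def test_identical_sequences_are_zero_profile(self, code5):
        seq = "ATGAAACCC"
        prof = pair_profile(seq, seq, frame_for(seq), code5)
        assert prof.is_zero
        with pytest.raises(ComparisonUndefinedError):
            _ = prof.share_pos1

    def test_single_synonymous_third_position_transition(self, code5):
        # AAA and AAG are both Lysine under the invertebrate mito code
        a, b = "ATGAAACCC", "ATGAAGCCC"
        prof = pair_profile(a, b, frame_for(a), code5)
        assert (prof.s1, prof.s2, prof.s3) == (0, 0, 1)
        assert (prof.share_pos1, prof.share_pos2, prof.share_pos3) == (0.0, 0.0, 100.0)
        assert prof.share_ts3 == 100.0 and prof.ts3 == 1 and prof.tv3 == 0
        assert prof.n_nonsyn == 0 and prof.share_nonsyn == 0.0

    def test_nonsynonymous_second_position_change(self, code5):
        # AAA (Lys) vs ACA (Thr): 2nd-position transversion, nonsynonymous
        a, b = "ATGAAACCC", "ATGACACCC"
        prof = pair_profile(a, b, frame_for(a), code5)
        assert (prof.s1, prof.s2, prof.s3) == (0, 1, 0)
        assert prof.n_nonsyn == 1 and prof.share_nonsyn == 100.0

    def test_codon_position_assignment_respects_frame_offset(self, code5):
        # same biological change, alignment shifted by one column
        a, b = "TATGAAACCC", "TATGAAGCCC"
        frame = FrameSpec.for_length(len(a), offset=1)
        prof = pair_profile(a, b, frame, code5)
        assert (prof.s1, prof.s2, prof.s3) == (0, 0, 1)

    def test_differences_outside_complete_codons_are_discarded(self, code5):
        a = "ATGAAACC"  # 8 columns, frame 0: codons cover 6
        b = "ATGAAACT"
        prof = pair_profile(a, b, frame_for(a), code5)
        assert prof.total == 0 and prof.n_discarded == 1

    def test_gapped_sites_excluded_pairwise(self, code5):
        a, b = "ATGAAACCC", "ATG-AGCCC"
        prof = pair_profile(a, b, frame_for(a), code5)
        # column 3 is deleted pairwise; only the pos-3 A/G difference scores
        assert (prof.s1, prof.s2, prof.s3) == (0, 0, 1)

    @given(codon_seq, st.data())
    def test_symmetric_in_its_two_sequences(self, seq, data):
        rng = random.Random(data.draw(st.integers(0, 10_000)))
        other = list(seq)
        for _ in range(rng.randint(1, 6)):
            i = rng.randrange(len(seq))
            other[i] = rng.choice("ACGT")
        other = "".join(other)
        f = frame_for(seq)
        p_ab = pair_profile(seq, other, f, CODE5)
        p_ba = pair_profile(other, seq, f, CODE5)
        assert p_ab == p_ba

    @given(codon_seq, st.data())
    def test_position_counts_conserve_pairwise_differences(self, seq, data):
        rng = random.Random(data.draw(st.integers(0, 10_000)))
        other = list(seq)
        for _ in range(rng.randint(1, 8)):
            other[rng.randrange(len(seq))] = rng.choice("ACGT")
        other = "".join(other)
        prof = pair_profile(seq, other, frame_for(seq), CODE5)
        pd = pair_distance(seq, other)  # whole alignment = complete codons here
        assert prof.total + prof.n_discarded == pd.n_diff
        assert prof.n_nonsyn + prof.n_syn + prof.n_unclassified == prof.total

    @given(codon_seq, st.data())
    def test_shares_sum_to_one_hundred(self, seq, data):
        rng = random.Random(data.draw(st.integers(0, 10_000)))
        other = list(seq)
        for _ in range(rng.randint(1, 8)):
            other[rng.randrange(len(seq))] = rng.choice("ACGT")
        other = "".join(other)
        prof = pair_profile(seq, other, frame_for(seq), CODE5)
        if prof.is_zero:
            return
        assert prof.share_pos1 + prof.share_pos2 + prof.share_pos3 == pytest.approx(100.0)
        if prof.s3 > 0:
            assert prof.share_ts3 + prof.share_tv3 == pytest.approx(100.0)
        assert 0 <= prof.n_nonsyn <= prof.total

    def test_pure_third_position_transitions_profile(self, code5):
        # swap NNR/NNY partners codon-by-codon: all synonymous under table 5
        a = "TTTAAACATGGA" * 3
        b = "TTCAAGCACGGG" * 3
        prof = pair_profile(a, b, frame_for(a), code5)
        assert prof.share_pos3 == 100.0
        assert prof.share_ts3 == 100.0
        assert prof.share_nonsyn == 0.0

    def test_nonsyn_rule_any_vs_both(self, code5):
        # CTA (Leu) vs ATT: the 3rd-position A/T swap is synonymous on the
        # CTA background (4-fold Leu) but nonsynonymous on the ATT
        # background (ATA is Met under table 5): the OR-rule counts it, the
        # stricter both-backgrounds rule does not
        a, b = "CTA", "ATT"
        f = FrameSpec.for_length(3, 0)
        assert pair_profile(a, b, f, code5, nonsyn_rule="any").n_nonsyn == 2
        assert pair_profile(a, b, f, code5, nonsyn_rule="both").n_nonsyn == 1

    def test_rounding_half_up(self):
        assert round_half_up(15.5) == 16
        assert round_half_up(15.4) == 15
        assert round_half_up(64.5) == 65


class TestCompareToReference:
    def make_profile(self, s1, s2, s3, ts3, tv3, nonsyn):
        return PairProfile(
            s1=s1, s2=s2, s3=s3, ts3=ts3, tv3=tv3, n_nonsyn=nonsyn,
            n_syn=s1 + s2 + s3 - nonsyn,
        )

    def test_profile_at_the_interval_means_is_inside_everywhere(self):
        # 1000 substitutions laid out exactly at the expectation means
        prof = self.make_profile(149, 45, 806, 684, 122, 75)
        rep = compare_to_reference(prof)
        # shares: 14.9, 4.5, 80.6, ts3 84.9..., nonsyn 7.5
        assert rep.n_outside == 0
        assert rep.n_suspicious == 0

    def test_numt_like_profile_deviates_on_the_suspicious_side(self):
        # uniform positions, transversion-rich, half nonsynonymous
        prof = self.make_profile(33, 33, 34, 17, 17, 50)
        rep = compare_to_reference(prof)
        assert rep.n_suspicious >= 4
        assert set(rep.suspicious_metrics()) >= {"pos2", "tv3", "nonsyn"}

    def test_ultra_clean_profile_is_outside_but_not_suspicious(self):
        # every substitution a synonymous third-position transition: beyond
        # several intervals at the mtDNA-like extreme, zero numt evidence
        prof = self.make_profile(0, 0, 10, 10, 0, 0)
        rep = compare_to_reference(prof)
        assert rep.n_outside >= 3
        assert rep.n_suspicious == 0

    def test_exceedance_definition(self):
        prof = self.make_profile(33, 33, 34, 17, 17, 50)
        rep = compare_to_reference(prof)
        for m, check in rep.checks.items():
            mean, hw = MTDNA_EXPECTATION.intervals[m]
            if check.inside:
                assert check.exceedance == 0.0
            else:
                assert check.exceedance == pytest.approx(
                    (abs(check.observed - mean) - hw) / hw
                )
                assert check.exceedance >= 0

    def test_third_position_free_profile_skips_ts_tv(self):
        prof = self.make_profile(3, 2, 0, 0, 0, 5)
        rep = compare_to_reference(prof)
        assert set(rep.skipped) == {"ts3", "tv3"}
        assert set(rep.checks) == set(METRICS) - {"ts3", "tv3"}

    def test_zero_profile_raises(self):
        prof = self.make_profile(0, 0, 0, 0, 0, 0)
        with pytest.raises(ComparisonUndefinedError):
            compare_to_reference(prof)
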