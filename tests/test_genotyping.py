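"""Aligner and outcome-classification behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from ampscreen import (BiasModel, LocusSpec, OutcomeCategory, align_read,
                       classify_outcome, make_synthetic_locus,
                       simulate_edited_reads, single_guide_spectrum,
                       tabulate_outcomes)
from ampscreen.errors import InputError
from ampscreen.genotyping import Indel, ReadAlignment, left_align_indels


def _call(read, locus):
    return classify_outcome(align_read(read, locus), locus)


class TestAlignRead:
    def test_identity_read(self, single_cut_locus):
        aln = align_read(single_cut_locus.reference_seq, single_cut_locus)
        assert aln.aligned
        assert aln.indels == ()
        assert (aln.left_boundary_offset, aln.right_boundary_offset) == (0, 0)

    def test_two_bp_deletion_left_of_cut(self, single_cut_locus):
        ref = single_cut_locus.reference_seq
        c = single_cut_locus.cut_sites[0]
        read = ref[:c - 2] + ref[c:]
        aln = align_read(read, single_cut_locus)
        assert len(aln.indels) == 1
        ind = aln.indels[0]
        assert ind.kind == "deletion" and ind.length == 2
        # leftmost placement: shifting one base further left must change
        # the implied read
        s = ind.ref_start
        if s > 0:
            assert ref[s - 1] != ref[s + 1]
        assert oracles.apply_alignment(ref, aln) == read

    def test_spanning_deletion_between_outer_cut_sites(self, triple_cut_locus):
        ref = triple_cut_locus.reference_seq
        c1, _, c3 = triple_cut_locus.cut_sites
        read = ref[:c1] + ref[c3:]
        aln = align_read(read, triple_cut_locus)
        assert len(aln.indels) == 1
        ind = aln.indels[0]
        assert ind.kind == "deletion" and ind.length == c3 - c1
        call = classify_outcome(aln, triple_cut_locus)
        assert call.category is OutcomeCategory.SPANNING_DELETION

    def test_insertion_reported_with_sequence(self, single_cut_locus):
        ref = single_cut_locus.reference_seq
        c = single_cut_locus.cut_sites[0]
        read = ref[:c] + "TA" + ref[c:]
        aln = align_read(read, single_cut_locus)
        assert len(aln.indels) == 1
        ind = aln.indels[0]
        assert ind.kind == "insertion" and ind.length == 2
        assert oracles.apply_alignment(ref, aln) == read

    def test_random_sequence_is_unaligned(self, single_cut_locus, rng):
        junk = "".join(rng.choice(list("ACGT"), size=80))
        aln = align_read(junk, single_cut_locus)
        assert not aln.aligned

    @pytest.mark.parametrize("bad", ["", "ACGU", "acgt"])
    def test_invalid_reads_rejected(self, bad, single_cut_locus):
        with pytest.raises(InputError):
            align_read(bad, single_cut_locus)


class TestAlignerOracle:
    """Equivalence with an exhaustive DP oracle on small loci."""

    def _edit_cases(self, ref, margin):
        """Single edits and two-edit combinations at least ``margin`` bp
        from the read ends (Cas9 edits sit at interior cut sites, which
        amplicon design keeps well away from the primers)."""
        cases = []
        for k in (1, 2, 3):
            for pos in range(margin, len(ref) - k - margin):
                cases.append(ref[:pos] + ref[pos + k:])  # deletion
        for base in "ACGT":
            for pos in range(margin, len(ref) - margin):
                cases.append(ref[:pos] + base + ref[pos:])  # insertion
        # well-separated two-edit combinations
        for p1 in range(margin, len(ref) // 2 - 4, 3):
            p2 = p1 + len(ref) // 2 - margin
            if margin < p2 < len(ref) - margin:
                edited = ref[:p1] + ref[p1 + 1:]
                cases.append(edited[:p2 - 1] + "T" + edited[p2 - 1:])
        return cases

    def test_matches_bruteforce_on_small_loci(self):
        for seed in (1, 2, 3):
            locus = LocusSpec("tiny",
                              "".join(np.random.default_rng(seed)
                                      .choice(list("ACGT"), size=56)),
                              (28,))
            ref = locus.reference_seq
            for read in self._edit_cases(ref, 12):
                aln = align_read(read, locus)
                assert aln.aligned
                expected = oracles.optimal_alignment_score(ref, read)
                assert aln.score == expected
                # the reported indel set reconstructs the read and attains
                # the optimal score on its own
                assert oracles.apply_alignment(ref, aln) == read
                assert oracles.score_of_alignment(aln) == expected

    def test_edge_edits_attain_or_beat_bruteforce_quality(self):
        """For edits near the read ends several representations coexist
        (free end gap vs mismatch vs flush indel). The anchored-rescue
        pass may pick a flush-indel alignment whose raw score is below the
        free-end optimum but whose quality — score with internal deletion
        penalties forgiven — is at least as good, and the reported indel
        set must still reconstruct the read exactly."""
        rng = np.random.default_rng(17)
        ref = "".join(rng.choice(list("ACGT"), size=50))
        locus = LocusSpec("tiny", ref, (25,))
        for read in self._edit_cases(ref, 2):
            aln = align_read(read, locus)
            assert aln.aligned
            optimum = oracles.optimal_alignment_score(ref, read)
            assert aln.score <= optimum
            deletion_penalty = sum(-5 - (i.length - 1) for i in aln.indels
                                   if i.kind == "deletion")
            assert aln.score - deletion_penalty >= optimum
            assert oracles.apply_alignment(ref, aln) == read

    def test_planted_edits_recovered_canonically(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            ref = "".join(rng.choice(list("ACGT"), size=60))
            locus = LocusSpec("tiny", ref, (30,))
            pos = int(rng.integers(8, 40))
            k = int(rng.integers(1, 4))
            read = ref[:pos] + ref[pos + k:]
            aln = align_read(read, locus)
            expected = oracles.left_shift_indels(ref, [("deletion", pos, k, "")])
            got = [(i.kind, i.ref_start, i.length, i.inserted_seq)
                   for i in aln.indels]
            assert got == expected


class TestLeftAlignment:
    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_shift_preserves_implied_read(self, seed):
        rng = np.random.default_rng(seed)
        ref = "".join(rng.choice(list("ACGT"), p=[0.4, 0.1, 0.1, 0.4], size=50))
        pos = int(rng.integers(5, 44))
        k = int(rng.integers(1, 5))
        raw = [Indel("deletion", pos, k)]
        canon = left_align_indels(ref, raw)
        before = ref[:pos] + ref[pos + k:]
        s = canon[0].ref_start
        after = ref[:s] + ref[s + k:]
        assert before == after
        # idempotent
        assert left_align_indels(ref, list(canon)) == canon

    def test_homopolymer_deletion_shifts_fully_left(self):
        ref = "ACGTTTTTTACG"
        canon = left_align_indels(ref, [Indel("deletion", 7, 2)])
        assert canon == (Indel("deletion", 3, 2),)

    def test_insertion_rotates_sequence(self):
        ref = "ACGTTTACG"
        canon = left_align_indels(ref, [Indel("insertion", 6, 1, "T")])
        assert canon == (Indel("insertion", 3, 1, "T"),)


class TestClassifyOutcome:
    def test_flush_no_indels_is_wildtype(self, single_cut_locus):
        call = _call(single_cut_locus.reference_seq, single_cut_locus)
        assert call.category is OutcomeCategory.WILDTYPE
        assert call.outcome_key == "WT"

    def test_small_deletion_at_cut_is_deletion(self, single_cut_locus):
        ref = single_cut_locus.reference_seq
        c = single_cut_locus.cut_sites[0]
        call = _call(ref[:c - 1] + ref[c:], single_cut_locus)
        assert call.category is OutcomeCategory.DELETION

    def test_two_indels_are_multiple_indels(self, triple_cut_locus):
        ref = triple_cut_locus.reference_seq
        c1, _, c3 = triple_cut_locus.cut_sites
        read = ref[:c1 - 1] + ref[c1:c3 - 2] + ref[c3:]
        call = _call(read, triple_cut_locus)
        assert call.category is OutcomeCategory.MULTIPLE_INDELS

    def test_both_boundaries_25bp_from_cuts_is_malformed(self, single_cut_locus):
        ref = single_cut_locus.reference_seq
        c = single_cut_locus.cut_sites[0]
        read = ref[c - 25:c + 25]
        call = _call(read, single_cut_locus)
        assert call.category is OutcomeCategory.MALFORMED_LAYOUT

    def test_one_boundary_45bp_from_cuts_is_malformed(self, single_cut_locus):
        ref = single_cut_locus.reference_seq
        c = single_cut_locus.cut_sites[0]
        read = ref[:c - 45]  # right boundary 45 bp left of the cut, left flush
        call = _call(read, single_cut_locus)
        assert call.category is OutcomeCategory.MALFORMED_LAYOUT

    def test_boundary_within_20bp_of_cut_not_malformed(self, single_cut_locus):
        ref = single_cut_locus.reference_seq
        c = single_cut_locus.cut_sites[0]
        read = ref[c - 15:]  # left boundary 15 bp from the cut, right flush
        aln = align_read(read, single_cut_locus)
        call = classify_outcome(aln, single_cut_locus)
        # truncated-but-near-cut read without indels carries no usable call,
        # but it is never wild type
        assert call.category is not OutcomeCategory.WILDTYPE

    def test_unaligned_read_category(self, single_cut_locus, rng):
        junk = "".join(rng.choice(list("ACGT"), size=70))
        call = _call(junk, single_cut_locus)
        assert call.category is OutcomeCategory.UNALIGNED

    def test_classification_is_total(self, triple_cut_locus, identity_bias):
        from ampscreen import multi_guide_spectrum
        spectrum = multi_guide_spectrum(3, efficiency=0.8, error_rate=0.002)
        reads, _ = simulate_edited_reads(triple_cut_locus, spectrum, 400,
                                         identity_bias, seed=5)
        calls = [_call(seq, triple_cut_locus) for _, seq in reads]
        assert len(calls) == 400
        assert all(isinstance(c.category, OutcomeCategory) for c in calls)


class TestTabulateOutcomes:
    def _wt_calls(self, locus, n):
        call = _call(locus.reference_seq, locus)
        return [call] * n

    def _edited_call(self, locus):
        ref = locus.reference_seq
        c = locus.cut_sites[0]
        return _call(ref[:c - 1] + "G" + ref[c:] if ref[c - 1] != "G"
                     else ref[:c - 1] + "A" + ref[c:], locus)

    def test_all_wildtype_zero_efficiency(self, single_cut_locus, identity_bias):
        table = tabulate_outcomes(self._wt_calls(single_cut_locus, 1000),
                                  single_cut_locus, identity_bias)
        assert table.editing_efficiency_pct == 0.0
        assert table.on_target_total_corrected == 1000
        assert table.passes_filter

    def test_mixture_efficiency_ratio(self, single_cut_locus, identity_bias):
        ref = single_cut_locus.reference_seq
        c = single_cut_locus.cut_sites[0]
        edited = _call(ref[:c] + "T" + ref[c:], single_cut_locus)
        assert edited.category is OutcomeCategory.INSERTION
        calls = self._wt_calls(single_cut_locus, 50) + [edited] * 950
        table = tabulate_outcomes(calls, single_cut_locus, identity_bias)
        # insertion lengthens the amplicon by 1 bp; with the identity model
        # raw and corrected counts coincide
        assert table.editing_efficiency_pct == pytest.approx(95.0)

    def test_filter_requires_over_100_corrected_reads(self, single_cut_locus,
                                                      identity_bias):
        table = tabulate_outcomes(self._wt_calls(single_cut_locus, 90),
                                  single_cut_locus, identity_bias)
        assert not table.passes_filter
        table = tabulate_outcomes(self._wt_calls(single_cut_locus, 101),
                                  single_cut_locus, identity_bias)
        assert table.passes_filter

    def test_empty_call_list(self, single_cut_locus, identity_bias):
        table = tabulate_outcomes([], single_cut_locus, identity_bias)
        assert table.outcomes.empty
        assert not table.passes_filter

    def test_efficiency_scale_invariant(self, single_cut_locus, identity_bias):
        ref = single_cut_locus.reference_seq
        c = single_cut_locus.cut_sites[0]
        edited = _call(ref[:c - 2] + ref[c:], single_cut_locus)
        calls = self._wt_calls(single_cut_locus, 30) + [edited] * 70
        t1 = tabulate_outcomes(calls, single_cut_locus, identity_bias)
        t2 = tabulate_outcomes(calls * 2, single_cut_locus, identity_bias)
        assert t1.editing_efficiency_pct == pytest.approx(
            t2.editing_efficiency_pct)
        assert (t1.outcomes["raw_count"] == t1.outcomes["corrected_count"]).all()

    def test_malformed_excluded_from_denominator(self, single_cut_locus,
                                                 identity_bias):
        ref = single_cut_locus.reference_seq
        c = single_cut_locus.cut_sites[0]
        malformed = _call(ref[c - 25:c + 25], single_cut_locus)
        assert malformed.category is OutcomeCategory.MALFORMED_LAYOUT
        calls = self._wt_calls(single_cut_locus, 200) + [malformed] * 800
        table = tabulate_outcomes(calls, single_cut_locus, identity_bias)
        assert table.editing_efficiency_pct == 0.0
        assert table.on_target_total_corrected == 200


def test_simulation_round_trip_exact(triple_cut_locus, identity_bias):
    """Reads simulated without error classify back to the drawn mixture."""
    from ampscreen import multi_guide_spectrum
    spectrum = multi_guide_spectrum(3, efficiency=0.9, error_rate=0.0)
    reads, truth = simulate_edited_reads(triple_cut_locus, spectrum, 2000,
                                         identity_bias, seed=21)
    calls = [_call(seq, triple_cut_locus) for _, seq in reads]
    observed = {}
    for call in calls:
        observed[call.category.value] = observed.get(call.category.value, 0) + 1
    expected = truth.groupby("category")["drawn_count"].sum().to_dict()
    assert observed == {k: v for k, v in expected.items() if v > 0}
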