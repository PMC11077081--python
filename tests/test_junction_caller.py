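"""Caller contracts: split scoring, toy junctions, oracle equivalence."""

from __future__ import annotations

import numpy as np
import pytest

from switchjx import (
    CallerOpts,
    CohortSpec,
    call_cohort,
    call_junction,
    score_split,
    simulate_cohort,
)

from _oracle import oracle_call, random_instance
from conftest import merge_calls_truth

TOY = CallerOpts(
    min_anchor=2, min_identity=0.5, seed_k=None, try_reverse_complement=False
)


class TestScoreSplit:
    donor = "A" * 40 + "C" * 40
    acceptor = "G" * 40 + "T" * 40

    def test_exact_split_scores_all_matches(self):
        read = self.donor[:40] + self.acceptor[40:]
        assert score_split(read, self.donor, self.acceptor, 40, 41, 40) == 80

    def test_one_substitution_costs_match_plus_penalty(self):
        read = list(self.donor[:40] + self.acceptor[40:])
        read[10] = "G"
        assert score_split("".join(read), self.donor, self.acceptor, 40, 41, 40) == 76

    def test_empty_donor_segment_is_acceptor_only(self):
        read = self.acceptor[40:]
        full = score_split(read, self.donor, self.acceptor, 0, 41, 0)
        assert full == 40

    def test_breakpoint_out_of_read_rejected(self):
        with pytest.raises(ValueError):
            score_split("ACGT", self.donor, self.acceptor, 4, 1, 9)


class TestToyJunctions:
    def test_blunt_unique_exact_split(self):
        from switchjx import SwitchReference

        donor = SwitchReference("d", "AAAACCCC", "donor")
        acceptor = SwitchReference("a", "GGGGTTTT", "acceptor")
        call = call_junction("AAAATTTT", donor, acceptor, TOY)
        assert call.status == "called"
        assert (call.d_end, call.a_start) == (4, 5)
        assert call.mh_length == 0 and call.insertion_seq == ""

    def test_four_nt_microhomology(self):
        from switchjx import SwitchReference

        donor = SwitchReference("d", "AAAACGCG", "donor")
        acceptor = SwitchReference("a", "CGCGTTTT", "acceptor")
        call = call_junction("AAAACGCGTTTT", donor, acceptor, TOY)
        assert call.status == "called"
        assert call.mh_length == 4
        assert call.insertion_seq == ""
        assert call.a_start == call.d_end - 3

    def test_two_nt_insertion(self):
        from switchjx import SwitchReference

        donor = SwitchReference("d", "AAAACCCC", "donor")
        acceptor = SwitchReference("a", "CCCCTTTT", "acceptor")
        call = call_junction("AAAAGGTTTT", donor, acceptor, TOY)
        assert call.status == "called"
        assert call.mh_length == 0
        assert call.insertion_seq == "GG"
        assert call.a_start == call.d_end + 3

    def test_short_read_unalignable(self, donor, acceptor):
        call = call_junction("ACGT" * 7 + "AC", donor, acceptor)  # 30 nt
        assert call.status == "unalignable"


class TestOracleEquivalence:
    def test_random_small_instances_match_exhaustive_enumeration(self):
        """Production caller vs brute-force 2-D DP on 150 random instances."""
        from switchjx import SwitchReference

        rng = np.random.default_rng(2024)
        opts = CallerOpts(
            min_anchor=1, min_identity=0.0, seed_k=None,
            try_reverse_complement=False, max_candidates=10_000,
        )
        for i in range(150):
            dseq, aseq, read = random_instance(rng)
            got = call_junction(
                read,
                SwitchReference("d", dseq, "donor"),
                SwitchReference("a", aseq, "acceptor"),
                opts,
            )
            status, mh, ins = oracle_call(read, dseq, aseq)
            assert got.status == status, (i, read, dseq, aseq, got)
            if status == "called":
                assert (got.mh_length, got.insertion_seq) == (mh, ins), (
                    i, read, dseq, aseq, got, (mh, ins),
                )


class TestCohortCalling:
    def test_noise_free_cohort_fully_called_and_exact(
        self, small_cohort, small_cohort_calls
    ):
        assert len(small_cohort_calls) == len(small_cohort.records)
        assert (small_cohort_calls["status"] == "called").all()
        m = merge_calls_truth(small_cohort_calls, small_cohort)
        assert (m["mh_length_call"] == m["mh_length_truth"]).all()
        assert (
            m["insertion_seq_call"].fillna("")
            == m["insertion_seq_truth"].fillna("")
        ).all()
        assert (m["donor_break_call"] == m["donor_break_truth"]).all()
        assert (m["acceptor_break_call"] == m["acceptor_break_truth"]).all()

    def test_trichotomy_invariant_every_call(self, small_cohort_calls):
        for rec in small_cohort_calls.itertuples(index=False):
            ins = rec.insertion_seq or ""
            if rec.mh_length > 0:
                assert rec.a_start == rec.d_end - rec.mh_length + 1
                assert ins == ""
            elif ins:
                assert rec.a_start == rec.d_end + len(ins) + 1
            else:
                assert rec.a_start == rec.d_end + 1

    def test_mh_segment_matches_both_references(self, small_cohort, small_cohort_calls):
        reads = dict(small_cohort.records)
        d = small_cohort.donor.sequence
        a = small_cohort.acceptor.sequence
        checked = 0
        for rec in small_cohort_calls.itertuples(index=False):
            if rec.mh_length == 0:
                continue
            k = rec.mh_length
            seg = reads[rec.read_id][rec.a_start - 1 : rec.d_end]
            assert len(seg) == k
            assert seg == d[rec.donor_break - k : rec.donor_break]
            assert seg == a[rec.acceptor_break - 1 - k : rec.acceptor_break - 1]
            checked += 1
        assert checked > 20

    def test_input_order_permutation_gives_same_calls(self, small_cohort):
        records = list(small_cohort.records)[:40]
        fwd = call_cohort(records, small_cohort.donor, small_cohort.acceptor)
        rev = call_cohort(records[::-1], small_cohort.donor, small_cohort.acceptor)
        key = ["read_id", "mh_length", "insertion_seq", "donor_break"]
        left = fwd[key].sort_values("read_id").reset_index(drop=True)
        right = rev[key].sort_values("read_id").reset_index(drop=True)
        assert left.equals(right)

    def test_extra_donor_context_does_not_change_call(self, small_cohort):
        """Prepending exact 5' donor context never changes (mh, insertion)."""
        d = small_cohort.donor.sequence
        truths = {t.read_id: t for t in small_cohort.truths}
        n = 0
        for read_id, seq in list(small_cohort.records)[:25]:
            t = truths[read_id]
            s = t.read_start_offset
            if s < 30:
                continue
            extended = d[s - 30 : s] + seq
            base = call_junction(seq, small_cohort.donor, small_cohort.acceptor)
            ext = call_junction(extended, small_cohort.donor, small_cohort.acceptor)
            assert (base.mh_length, base.insertion_seq) == (
                ext.mh_length, ext.insertion_seq,
            )
            n += 1
        assert n > 10

    def test_reverse_complement_reads_recovered(self, small_cohort):
        from switchjx.synthetic_data import _revcomp

        records = [(rid, _revcomp(seq)) for rid, seq in list(small_cohort.records)[:20]]
        calls = call_cohort(records, small_cohort.donor, small_cohort.acceptor)
        assert (calls["status"] == "called").all()
        assert (calls["orientation"] == "-").all()
        m = merge_calls_truth(calls, small_cohort)
        assert (m["mh_length_call"] == m["mh_length_truth"]).all()

    def test_empty_cohort_warns(self, donor, acceptor):
        with pytest.warns(UserWarning, match="empty"):
            table = call_cohort([], donor, acceptor)
        assert table.empty
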