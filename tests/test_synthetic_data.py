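"""Generator contracts: references, junction truth, cohorts, qPCR panels."""

from __future__ import annotations

import math

import numpy as np
import pytest

from switchjx import (
    CohortSpec,
    QpcrPanelSpec,
    SwitchReference,
    make_switch_reference,
    simulate_cohort,
    simulate_junction,
    simulate_qpcr_panel,
)
from switchjx.synthetic_data import (
    GenerationError,
    delta_ct_for_fraction,
    truth_table,
)

from conftest import UNIFORM_MIX


class TestSwitchReference:
    def test_repeat_unit_density_and_length(self):
        ref = make_switch_reference("Smu", "donor", 2000, "GAGCT", 0.6, seed=1)
        assert len(ref.sequence) == 2000
        assert set(ref.sequence) <= set("ACGT")
        # construction interleaves unit/spacer 1:1, so >= length/(4*|unit|)
        assert ref.sequence.count("GAGCT") >= 2000 // (4 * 5) == 100

    def test_deterministic_for_fixed_seed(self):
        a = make_switch_reference("S", "donor", 500, "GGGCT", 0.55, seed=7)
        b = make_switch_reference("S", "donor", 500, "GGGCT", 0.55, seed=7)
        c = make_switch_reference("S", "donor", 500, "GGGCT", 0.55, seed=8)
        assert a.sequence == b.sequence
        assert a.sequence != c.sequence

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"length": 100},
            {"length": 500, "repeat_unit": ""},
            {"length": 500, "gc_bias": 0.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_switch_reference("S", "donor", **kwargs)

    def test_non_acgt_sequence_rejected(self):
        with pytest.raises(ValueError):
            SwitchReference("S", "ACGTN" * 50, "donor")


@pytest.fixture(scope="module")
def params():
    return CohortSpec(
        n_junctions=1, mix={"blunt": 1.0}, mutation_rate=0.0,
        read_length_range=(200, 260),
    )


class TestSimulateJunction:
    def test_blunt_read_is_plain_concatenation(self, donor, acceptor, params):
        sim = simulate_junction(donor, acceptor, "blunt", params, seed=3)
        t = sim.truth
        d, a = sim.donor.sequence, sim.acceptor.sequence
        s = t.read_start_offset
        left = d[s : t.donor_break]
        assert sim.read.startswith(left)
        assert sim.read[len(left) :] == a[
            t.acceptor_break - 1 : t.acceptor_break - 1 + len(sim.read) - len(left)
        ]
        assert t.mh_length == 0 and t.insertion_seq == ""

    @pytest.mark.parametrize("outcome,k", [("mh_short", 2), ("mh_long", 6)])
    def test_mh_flank_is_shared_and_exact(self, donor, acceptor, params, outcome, k):
        sim = simulate_junction(donor, acceptor, outcome, params, seed=5, mh_length=k)
        t = sim.truth
        d, a = sim.donor.sequence, sim.acceptor.sequence
        e, a0 = t.donor_break, t.acceptor_break - 1
        assert t.mh_length == k
        # the k donor bases ending at donor_break equal the k acceptor bases
        # ending at acceptor_break - 1 ...
        assert d[e - k : e] == a[a0 - k : a0]
        # ... and the identity does not extend on either side
        assert d[e - k - 1] != a[a0 - k - 1]
        assert d[e] != a[a0]

    def test_mh_and_insertion_mutually_exclusive(self, donor, acceptor, params):
        sim = simulate_junction(donor, acceptor, "small_insertion", params, seed=9)
        assert sim.truth.mh_length == 0
        assert 1 <= len(sim.truth.insertion_seq) <= 2

    def test_ecs_requires_decoy(self, donor, acceptor, params):
        with pytest.raises(GenerationError, match="ecs"):
            simulate_junction(donor, acceptor, "ecs_insertion", params, seed=1)

    def test_ecs_insertion_copied_from_decoy(self, donor, acceptor, decoy, params):
        sim = simulate_junction(
            donor, acceptor, "ecs_insertion", params, decoy=decoy, seed=2
        )
        t = sim.truth
        contig, start, end, strand = t.ecs_source
        frag = decoy[contig][start - 1 : end]
        if strand == "-":
            frag = frag.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert t.insertion_seq == frag
        assert len(t.insertion_seq) >= 31

    def test_mutations_spare_protected_zone(self, donor, acceptor):
        params = CohortSpec(
            n_junctions=1, mix={"blunt": 1.0}, mutation_rate=0.2,
            read_length_range=(200, 260),
        )
        for seed in range(5):
            sim = simulate_junction(donor, acceptor, "mh_long", params, seed=seed)
            t = sim.truth
            jx = t.donor_break - t.read_start_offset  # first non-donor read idx
            protected = set(range(jx - t.mh_length - 3 + 1, jx + 3 + 1))  # 1-based
            assert t.mutations, "high rate should mutate the halo"
            assert not protected & {pos for pos, _, _ in t.mutations}


class TestSimulateCohort:
    def test_degenerate_mixture_all_blunt(self, donor, acceptor):
        spec = CohortSpec(n_junctions=100, mix={"blunt": 1.0}, seed=1)
        res = simulate_cohort(spec, donor, acceptor)
        assert len(res.records) == 100
        assert all(t.mh_length == 0 and t.insertion_seq == "" for t in res.truths)

    def test_category_counts_near_mixture(self, donor, acceptor, decoy):
        spec = CohortSpec(n_junctions=1000, mix=UNIFORM_MIX, seed=2)
        res = simulate_cohort(spec, donor, acceptor, decoy)
        tt = truth_table(res)
        counts = tt["category"].value_counts()
        sd = math.sqrt(1000 * 0.2 * 0.8)  # binomial SD ~ 12.6
        for cat in UNIFORM_MIX:
            assert abs(counts[cat] - 200) <= 4 * sd

    def test_duplication_re_emits_verbatim(self, donor, acceptor):
        spec = CohortSpec(
            n_junctions=100, mix={"blunt": 0.5, "mh_short": 0.5},
            duplication_rate=0.1, seed=3,
        )
        res = simulate_cohort(spec, donor, acceptor)
        assert len(res.records) == 110
        seqs = [s for _, s in res.records]
        assert len(set(seqs)) == 100
        dups = [t for t in res.truths if t.duplicate_of]
        assert len(dups) == 10
        by_id = dict(res.records)
        assert all(by_id[t.read_id] == by_id[t.duplicate_of] for t in dups)

    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CohortSpec(n_junctions=10, mix={"blunt": 0.5})

    def test_read_lengths_within_range(self, small_cohort):
        lengths = [len(s) for _, s in small_cohort.records]
        assert min(lengths) >= 500
        assert max(lengths) <= 1000


class TestQpcrPanel:
    def spec(self, **over):
        kw = dict(
            amplicons=(("p3", "target"), ("cd3e", "negative_control")),
            true_ssdna_fraction={"p3": 0.03, "cd3e": 0.001},
            baseline_cq={"p3": 24.0, "cd3e": 26.0},
            replicates=3,
            cq_noise_sd=0.0,
            seed=5,
        )
        kw.update(over)
        return QpcrPanelSpec(**kw)

    def test_delta_ct_formula_values(self):
        assert delta_ct_for_fraction(1.0) == 0.0
        assert delta_ct_for_fraction(0.5) == pytest.approx(
            math.log2(1.5) + 1, abs=1e-12
        )

    def test_forward_inverse_round_trip(self):
        for f in np.geomspace(0.001, 1.0, 25):
            dct = delta_ct_for_fraction(float(f))
            ssdna = 100.0 / (2.0 ** (dct - 1.0) + 0.5)
            assert ssdna == pytest.approx(100.0 * f, abs=1e-9)

    def test_noiseless_panel_encodes_exact_shift(self):
        panel = simulate_qpcr_panel(self.spec())
        g = panel.groupby(["amplicon", "digestion"])["cq"].mean()
        dct = g[("p3", "digested")] - g[("p3", "mock")]
        assert dct == pytest.approx(delta_ct_for_fraction(0.03), abs=1e-12)

    def test_ceiling_caps_tiny_fractions(self):
        spec = self.spec(
            true_ssdna_fraction={"p3": 0.03, "cd3e": 1e-6},
            delta_ct_ceiling=15.0,
        )
        panel = simulate_qpcr_panel(spec)
        sub = panel[panel["amplicon"] == "cd3e"]
        assert sub["capped"].all()
        dct = (
            sub[sub["digestion"] == "digested"]["cq"].mean()
            - sub[sub["digestion"] == "mock"]["cq"].mean()
        )
        assert dct == pytest.approx(15.0, abs=1e-12)

    def test_negative_control_fraction_validated(self):
        with pytest.raises(ValueError, match="negative-control"):
            self.spec(true_ssdna_fraction={"p3": 0.03, "cd3e": 0.05})

    def test_replicate_minimum(self):
        with pytest.raises(ValueError, match="replicates"):
            self.spec(replicates=1)
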