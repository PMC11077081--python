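from __future__ import annotations

import pandas as pd
import pytest

from switchjx import (
    CohortSpec,
    call_cohort,
    make_decoy_genome,
    make_switch_reference,
    simulate_cohort,
)
from switchjx.synthetic_data import truth_table

UNIFORM_MIX = {
    "blunt": 0.2,
    "mh_short": 0.2,
    "mh_long": 0.2,
    "small_insertion": 0.2,
    "ecs_insertion": 0.2,
}


@pytest.fixture(scope="session")
def donor():
    return make_switch_reference("Smu", "donor", 2500, "GAGCT", 0.6, seed=11)


@pytest.fixture(scope="session")
def acceptor():
    return make_switch_reference("Salpha", "acceptor", 2500, "TGGGC", 0.6, seed=12)


@pytest.fixture(scope="session")
def decoy():
    return make_decoy_genome(n_contigs=3, contig_length=5000, seed=13)


@pytest.fixture(scope="session")
def small_cohort(donor, acceptor, decoy):
    """300 noise-free junctions, uniform over the five outcome categories."""
    spec = CohortSpec(n_junctions=300, mix=UNIFORM_MIX, mutation_rate=0.0, seed=21)
    return simulate_cohort(spec, donor, acceptor, decoy)


@pytest.fixture(scope="session")
def small_cohort_calls(small_cohort):
    return call_cohort(
        list(small_cohort.records), small_cohort.donor, small_cohort.acceptor
    )


def merge_calls_truth(calls: pd.DataFrame, cohort) -> pd.DataFrame:
    tt = truth_table(cohort)
    return calls.merge(tt, on="read_id", suffixes=("_call", "_truth"))
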