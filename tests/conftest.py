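"""Shared fixtures: the synthetic structure battery and derived objects.

Expensive constructions are session-scoped so the planted-truth tests and
the acceptance suite reuse them.
"""

from __future__ import annotations

import pytest

from cryptosite import pipeline, structio, synthetic_data

BATTERY_SEEDS = (1, 2, 3, 4, 5)


def build_battery(seed: int):
    """One globule with a low-confidence loop, one plain globule, one hinge."""
    return [
        synthetic_data.make_globule_fixture(seed=seed, low_conf_loop=True),
        synthetic_data.make_globule_fixture(seed=seed + 100),
        synthetic_data.make_hinge_fixture(seed=seed),
    ]


def run_battery(seed: int) -> tuple[pipeline.FullResult, dict]:
    battery = build_battery(seed)
    structures = {truth.accession: s for s, truth in battery}
    ptm = synthetic_data.make_ptm_fixture(battery, seed=seed)
    sites = structio.read_ptm_table(ptm)
    result = pipeline.run_full(structures, sites)
    expected = {(truth.accession, pos): label
                for _, truth in battery for pos, label in truth.planted_sites}
    return result, expected


@pytest.fixture(scope="session")
def battery_results() -> dict[int, tuple[pipeline.FullResult, dict]]:
    return {seed: run_battery(seed) for seed in BATTERY_SEEDS}


@pytest.fixture(scope="session")
def globule() -> tuple[structio.Structure, synthetic_data.FixtureTruth]:
    return synthetic_data.make_globule_fixture(seed=1, low_conf_loop=True)


@pytest.fixture(scope="session")
def hinge() -> tuple[structio.Structure, synthetic_data.FixtureTruth]:
    return synthetic_data.make_hinge_fixture(seed=1)


@pytest.fixture(scope="session")
def toy_chain():
    return synthetic_data.make_toy_chain_native(30, seed=0)
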