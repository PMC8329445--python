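"""Shared fixtures: configuration, physiologies and the expensive scenario runs.

Scenario simulations are session-scoped so the infusion/bolus runs are
integrated once and shared across metric, property and acceptance tests.
"""

import copy

import pytest

from nicpbpk import load_config
from nicpbpk.scenarios import BUILTIN_SCENARIOS, build_model


@pytest.fixture(scope="session")
def config():
    return load_config()


@pytest.fixture()
def config_copy(config):
    """A deep copy safe to mutate in schema/growth tests."""
    return copy.deepcopy(config)


def _run(scenario_id, config):
    scenario = BUILTIN_SCENARIOS[scenario_id]
    model = build_model(scenario, config=config)
    result = model.simulate(
        scenario.schedule, scenario.horizon_h,
        output_dt_min=scenario.output_dt_min,
        metadata={"scenario": scenario.id},
    )
    return scenario, model, result


@pytest.fixture(scope="session")
def women_infusion(config):
    """Baseline 70-kg adult, IV nicotine 10 µg/min x 60 min, 72-h horizon."""
    return _run("nic_infusion_10ug_60min", config)


@pytest.fixture(scope="session")
def pregnant_infusion(config):
    """Week-30 pregnant subject (73 kg), same nicotine infusion."""
    return _run("preg_infusion_10ug_60min", config)


@pytest.fixture(scope="session")
def pregnant_bolus(config):
    """Week-30 pregnant subject, single 1 µg/kg IV nicotine bolus, dense grid."""
    return _run("nic_bolus_1ug_kg_week30", config)
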