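"""ODE core: structure, conservation, linearity and analytic limits."""

import copy

import numpy as np
import pytest

from nicpbpk import (
    COTININE, ConfigurationError, DomainError, DoseEvent, DoseSchedule,
    ModelOptions, NumericalError, PBPKModel, PlacentalTransfer,
    build_physiology, table1_defaults,
)
from nicpbpk.compound_params import MW_RATIO_COT_NIC, CompoundParams, MW_NIC
from nicpbpk.pbpk_core import COMPOUNDS


def make_model(config, population="women", week=0.0, weight=70.0, **kwargs):
    maternal, fetal = build_physiology(week, weight, config)
    placenta = (PlacentalTransfer.from_dict(config["placental_transfer"])
                if maternal.is_pregnant else None)
    return PBPKModel(maternal, fetal, table1_defaults(population),
                     placenta=placenta, **kwargs)


def nic_infusion(rate=10.0, duration=60.0):
    return DoseSchedule([DoseEvent(route="iv_infusion", compound="NIC",
                                   rate=rate, duration=duration)])


# -- structure -------------------------------------------------------------

def test_pregnant_state_count_is_32_dynamic_equations(config):
    model = make_model(config, "pregnant", week=30.0, weight=73.0)
    assert model.index.n_dynamic == 32  # 2 compounds x 16 compartments
    assert len(model.index) == 32 + 5   # + urine x2, hepatic sinks x2, formed
    assert "NIC:fetal_brain" in model.index.names
    assert "formed:COT" in model.index.names


def test_nonpregnant_state_count(config):
    model = make_model(config)
    assert model.index.n_dynamic == 22  # no placenta, no fetus
    assert all("fetal" not in name for name in model.index.names)


def test_pregnant_model_requires_fetus_and_placenta(config):
    maternal, fetal = build_physiology(30.0, 73.0, config)
    with pytest.raises(DomainError, match="placental"):
        PBPKModel(maternal, fetal, table1_defaults("pregnant"))
    with pytest.raises(DomainError, match="fetal"):
        PBPKModel(maternal, None, table1_defaults("pregnant"),
                  placenta=PlacentalTransfer(1.0, 1.0, 1.0, 1.0))


def test_placental_transfer_rejects_negative_rates():
    with pytest.raises(DomainError):
        PlacentalTransfer(-1.0, 1.0, 1.0, 1.0)


def test_systemic_clearance_must_stay_below_organ_flow(config_copy):
    # pregnant hepatic nicotine clearance (~116 L/h at 73 kg) cannot be
    # supported by a 60 L/h liver flow under the well-stirred inversion
    config_copy["gestation"]["tissue_growth"]["liver"] = {"flow": {"poly": [0.0]}}
    config_copy["tissues"]["liver"]["flow_L_per_h"] = 60.0
    with pytest.raises(ConfigurationError, match="hepatic_nic"):
        make_model(config_copy, "pregnant", week=30.0, weight=73.0)


# -- right-hand side -------------------------------------------------------

def test_zero_state_zero_input_gives_zero_derivative(config):
    model = make_model(config, "pregnant", week=30.0, weight=73.0)
    deriv = model.rhs(np.zeros(len(model.index)), 0.0)
    assert np.all(deriv == 0.0)


@pytest.mark.parametrize("population,week,weight",
                         [("women", 0.0, 70.0), ("pregnant", 30.0, 73.0)])
def test_rhs_conserves_mass_at_arbitrary_states(config, population, week, weight):
    """Compound-wise mass budgets close exactly for any state.

    Nicotine: compartment derivatives + urine + hepatic sink sum to zero
    without input.  Cotinine: the same sum equals the formation flux.
    """
    model = make_model(config, population, week=week, weight=weight)
    rng = np.random.default_rng(7)
    for _ in range(5):
        state = rng.uniform(0.0, 50.0, len(model.index))
        deriv = model.rhs(state, 0.0)
        for compound in COMPOUNDS:
            total = sum(deriv[model.index.of(compound, c)]
                        for c in model.index.compartments)
            total += deriv[model.index.accumulator(f"urine:{compound}")]
            total += deriv[model.index.accumulator(f"hepatic_sink:{compound}")]
            source = (deriv[model.index.accumulator("formed:COT")]
                      if compound == "COT" else 0.0)
            assert total == pytest.approx(source, abs=1e-9 * max(1.0, abs(source)))


def test_rhs_rejects_nonfinite_state(config):
    model = make_model(config)
    state = np.zeros(len(model.index))
    state[3] = np.nan
    with pytest.raises(NumericalError, match=model.index.names[3]):
        model.rhs(state, 0.0)
    with pytest.raises(DomainError):
        model.rhs(np.zeros(3), 0.0)


def test_cotinine_formation_ratio_at_steady_state(config):
    """At steady state under constant infusion, cotinine forms at
    f_met x (MW ratio) x the hepatic nicotine elimination rate."""
    model = make_model(config)
    schedule = DoseSchedule([DoseEvent(route="iv_infusion", compound="NIC",
                                       rate=10.0, duration=48.0 * 60.0)])
    result = model.simulate(schedule, horizon_h=48.0, output_dt_min=5.0)
    state = result.amounts[:, -1]
    deriv = model.rhs(state, 47.0 * 60.0, schedule)
    formation = deriv[model.index.accumulator("formed:COT")]
    hepatic_nic = deriv[model.index.accumulator("hepatic_sink:NIC")]
    assert formation == pytest.approx(0.8 * MW_RATIO_COT_NIC * hepatic_nic, rel=1e-12)


# -- simulation properties -------------------------------------------------

def test_mass_balance_through_simulation(config):
    schedule = nic_infusion()
    model = make_model(config)
    result = model.simulate(schedule, horizon_h=12.0, output_dt_min=1.0)
    residual = model.mass_balance_residual(result, schedule)
    assert residual.max() <= 1e-6


def test_mass_balance_pregnant_bolus(config):
    schedule = DoseSchedule([DoseEvent(route="iv_bolus", compound="NIC",
                                       amount=73.0, start=0.0)])
    model = make_model(config, "pregnant", week=30.0, weight=73.0)
    result = model.simulate(schedule, horizon_h=8.0, output_dt_min=1.0)
    assert model.mass_balance_residual(result, schedule).max() <= 1e-6


def test_dose_linearity(config):
    """Doubling the dose doubles every trajectory (the system is linear)."""
    options = ModelOptions(rtol=1e-11, atol=1e-13)
    model = make_model(config, options=options)
    r1 = model.simulate(nic_infusion(rate=10.0), 12.0, output_dt_min=1.0)
    r2 = model.simulate(nic_infusion(rate=20.0), 12.0, output_dt_min=1.0)
    mask = r1.amounts > 1e-6
    rel = np.abs(r2.amounts[mask] - 2.0 * r1.amounts[mask]) / (2.0 * r1.amounts[mask])
    assert rel.max() <= 1e-8


def test_non_negativity(pregnant_bolus):
    _, _, result = pregnant_bolus
    assert result.amounts.min() >= 0.0


def test_simulated_systemic_clearance_matches_published_value(config):
    """Dose / arterial AUC recovers the whole-body clearance the model was
    given, confirming the well-stirred back-calculation."""
    model = make_model(config)
    schedule = DoseSchedule([DoseEvent(route="iv_bolus", compound="NIC",
                                       amount=600.0, start=0.0)])
    result = model.simulate(schedule, horizon_h=60.0, output_dt_min=0.5)
    auc_art = np.trapezoid(result.concentration("arterial", "NIC"), result.time_h)
    cl_total = 68.04 + 2.94  # women column at 70 kg, L/h
    assert 600.0 / auc_art == pytest.approx(cl_total, rel=0.02)


def test_one_compartment_analytic_oracle(config_copy):
    """With unit partitions, flows >> clearance and no metabolism the model
    collapses to one well-mixed pool with mono-exponential washout."""
    for name, entry in config_copy["tissues"].items():
        entry["partition_nic"] = entry["partition_cot"] = 1.0
        if entry["flow_L_per_h"] is not None:
            entry["flow_L_per_h"] *= 1000.0
    maternal, _ = build_physiology(0.0, 70.0, config_copy)
    nicotine = CompoundParams("NIC", MW_NIC, metabolic_fraction_to_cotinine=0.0)
    model = PBPKModel(maternal, None, table1_defaults("women"), nicotine=nicotine)
    volume = (maternal.arterial_volume + maternal.venous_volume
              + sum(t.volume for t in maternal.tissues))
    clearance = 68.04 + 2.94
    k = clearance / volume
    dose = 600.0
    schedule = DoseSchedule([DoseEvent(route="iv_bolus", compound="NIC",
                                       amount=dose, start=0.0)])
    half_life_h = np.log(2.0) / k
    result = model.simulate(schedule, horizon_h=5.0 * half_life_h, output_dt_min=0.5)
    analytic = dose / volume * np.exp(-k * result.time_h)
    simulated = result.concentration("venous", "NIC")
    mask = result.time_min >= 1.0  # skip the sub-minute mixing transient
    assert np.abs(simulated[mask] - analytic[mask]).max() <= 0.01 * analytic[mask].max()
    assert np.all(np.abs(simulated[mask] / analytic[mask] - 1.0) <= 0.01)


def test_pregnant_concentrations_below_nonpregnant(women_infusion, pregnant_infusion):
    """Higher pregnancy clearances depress maternal plasma levels.

    Nicotine is lower at every output time.  Cotinine is lower once the
    formation transient has passed (the pregnant liver converts nicotine
    faster, so pregnant cotinine transiently leads during the first few
    minutes); ordering is asserted beyond 60 min.
    """
    _, _, women = women_infusion
    _, _, pregnant = pregnant_infusion
    nic_w = women.concentration("plasma", "NIC")
    nic_p = pregnant.concentration("plasma", "NIC")
    assert np.all(nic_p[1:] <= nic_w[1:] * (1.0 + 1e-9))
    after = women.time_min >= 60.0
    cot_w = women.concentration("plasma", "COT")
    cot_p = pregnant.concentration("plasma", "COT")
    assert np.all(cot_p[after] <= cot_w[after] * (1.0 + 1e-9))


def test_intrinsic_reference_caps_elimination_at_organ_flow(config):
    """With clearance_reference='intrinsic' the published value acts on the
    liver outflow, so the effective clearance is below the systemic one."""
    options = ModelOptions(clearance_reference="intrinsic")
    model = make_model(config, options=options)
    schedule = DoseSchedule([DoseEvent(route="iv_bolus", compound="NIC",
                                       amount=600.0, start=0.0)])
    result = model.simulate(schedule, horizon_h=60.0, output_dt_min=0.5)
    auc_art = np.trapezoid(result.concentration("arterial", "NIC"), result.time_h)
    effective = 600.0 / auc_art
    q_liver = model.maternal.tissue("liver").blood_flow
    assert effective < q_liver
    assert effective < 68.04  # below the systemic (women) column value


def test_metabolism_can_be_switched_off(config):
    nicotine = CompoundParams("NIC", MW_NIC, metabolic_fraction_to_cotinine=0.0)
    model = make_model(config)
    model_off = PBPKModel(model.maternal, None, model.clearances, nicotine=nicotine)
    result = model_off.simulate(nic_infusion(), 4.0, output_dt_min=1.0)
    assert result.cotinine_formed()[-1] == 0.0
    assert np.all(result.concentration("venous", "COT") == 0.0)
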