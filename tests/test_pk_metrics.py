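"""Noncompartmental metrics on synthetic and simulated curves."""

import numpy as np
import pytest

from nicpbpk import DomainError, SimulationResult, auc, cmax_tmax, percent_lower, terminal_half_life, urine_at


def synthetic_result(time_min, venous_conc, volume=1.0, urine=None):
    """Minimal single-compound result with a venous trace (µg/L)."""
    time_min = np.asarray(time_min, dtype=float)
    amounts = [np.asarray(venous_conc, dtype=float) * volume]
    names = ["NIC:venous"]
    if urine is not None:
        amounts.append(np.asarray(urine, dtype=float))
        names.append("urine:NIC")
    return SimulationResult(
        time_min=time_min,
        amounts=np.vstack(amounts),
        state_names=tuple(names),
        volumes={"NIC:venous": volume},
    )


# -- cmax / tmax -----------------------------------------------------------

def test_tmax_of_t_exp_minus_t():
    """C(t) = t e^(-t) (t in hours) peaks at t = 1 h."""
    t_min = np.arange(0.0, 5.0 * 60.0 + 0.1, 0.1)
    t_h = t_min / 60.0
    result = synthetic_result(t_min, t_h * np.exp(-t_h))
    peak = cmax_tmax(result, "venous", "NIC")
    assert peak.tmax_min == pytest.approx(60.0, abs=0.1)
    assert peak.cmax == pytest.approx(np.exp(-1.0), abs=1e-6)


def test_tmax_of_monotone_decay_is_first_point():
    t_min = np.arange(1.0, 100.0, 1.0)
    result = synthetic_result(t_min, np.exp(-t_min / 30.0))
    cmax, tmax = cmax_tmax(result, "venous", "NIC")
    assert tmax == 1.0 and cmax == pytest.approx(np.exp(-1.0 / 30.0))


def test_all_zero_trajectory_is_flagged():
    result = synthetic_result([0.0, 1.0, 2.0], [0.0, 0.0, 0.0])
    peak = cmax_tmax(result, "venous", "NIC")
    assert peak.all_zero and tuple(peak) == (0.0, 0.0)


# -- terminal half-life ----------------------------------------------------

@pytest.mark.parametrize("half_life_h", [0.03, 0.3, 3.0, 30.0])
def test_half_life_recovery_across_three_decades(half_life_h):
    """The log-linear estimator recovers k within 0.1% on mono-exponentials."""
    k = np.log(2.0) / half_life_h
    t_min = np.linspace(0.0, 8.0 * half_life_h * 60.0, 400)
    result = synthetic_result(t_min, 10.0 * np.exp(-k * t_min / 60.0))
    estimate = terminal_half_life(result, "venous", "NIC")
    assert estimate.half_life_h == pytest.approx(half_life_h, rel=1e-3)
    assert not estimate.low_confidence


def test_half_life_exact_on_three_hour_exponential():
    k = np.log(2.0) / 3.0
    t_min = np.linspace(0.0, 24.0 * 60.0, 1000)
    result = synthetic_result(t_min, np.exp(-k * t_min / 60.0))
    assert terminal_half_life(result, "venous", "NIC").half_life_h == pytest.approx(3.0, rel=1e-9)


def test_half_life_flags_non_loglinear_tail():
    t_min = np.linspace(0.0, 600.0, 500)
    wobble = np.exp(-t_min / 120.0) * (1.0 + 0.5 * np.sin(t_min / 20.0))
    estimate = terminal_half_life(synthetic_result(t_min, wobble), "venous", "NIC")
    assert estimate.low_confidence


def test_half_life_requires_enough_tail_points():
    result = synthetic_result([0.0, 1.0, 2.0, 3.0], [4.0, 3.0, 2.0, 1.0])
    with pytest.raises(DomainError, match="5 positive"):
        terminal_half_life(result, "venous", "NIC")


def test_half_life_rejects_rising_tail():
    # early peak, then a tail that climbs again: no decay slope to fit
    t_min = np.linspace(0.0, 100.0, 200)
    conc = 10.0 * np.exp(-t_min / 5.0) + 0.02 * t_min
    with pytest.raises(DomainError, match="not decaying"):
        terminal_half_life(synthetic_result(t_min, conc), "venous", "NIC")


# -- AUC -------------------------------------------------------------------

def test_auc_of_constant_curve():
    t_min = np.linspace(0.0, 120.0, 121)
    result = synthetic_result(t_min, np.full_like(t_min, 5.0))
    assert auc(result, "venous", "NIC", 0.0, 60.0) == pytest.approx(5.0)


def test_auc_of_exponential_approaches_c0_over_k():
    k = 2.0  # 1/h
    t_min = np.linspace(0.0, 10.0 * np.log(2.0) / k * 60.0, 5000)
    result = synthetic_result(t_min, 8.0 * np.exp(-k * t_min / 60.0))
    assert auc(result, "venous", "NIC", 0.0, t_min[-1]) == pytest.approx(8.0 / k, rel=1e-3)


def test_auc_additivity_and_interval_validation():
    t_min = np.linspace(0.0, 180.0, 700)
    result = synthetic_result(t_min, np.exp(-t_min / 60.0))
    whole = auc(result, "venous", "NIC", 0.0, 120.0)
    parts = (auc(result, "venous", "NIC", 0.0, 45.5)
             + auc(result, "venous", "NIC", 45.5, 120.0))
    assert parts == pytest.approx(whole, rel=1e-12)
    with pytest.raises(DomainError):
        auc(result, "venous", "NIC", 60.0, 60.0)
    with pytest.raises(DomainError):
        auc(result, "venous", "NIC", 0.0, 1e6)


# -- percent difference and urine ------------------------------------------

def test_percent_lower_identity_and_antisymmetry():
    t_min = np.linspace(0.0, 100.0, 101)
    a = synthetic_result(t_min, 10.0 * np.exp(-t_min / 50.0))
    b = synthetic_result(t_min, 4.0 * np.exp(-t_min / 50.0))
    assert percent_lower(a, a, "venous", "NIC", 30.0) == 0.0
    ab = percent_lower(a, b, "venous", "NIC", 30.0)
    ba = percent_lower(b, a, "venous", "NIC", 30.0)
    assert ab == pytest.approx(60.0)
    # algebra of the definition: pl(a,b) = -pl(b,a) / (1 - pl(b,a)/100)
    assert ab == pytest.approx(-ba / (1.0 - ba / 100.0))


def test_percent_lower_requires_positive_reference():
    t_min = np.linspace(0.0, 10.0, 11)
    zero = synthetic_result(t_min, np.zeros_like(t_min))
    other = synthetic_result(t_min, np.ones_like(t_min))
    with pytest.raises(DomainError):
        percent_lower(zero, other, "venous", "NIC", 5.0)


def test_urine_interpolation_and_monotonicity(women_infusion):
    _, _, result = women_infusion
    assert urine_at(result, "NIC", 0.0) == 0.0
    series = result.urine("NIC")
    assert np.all(np.diff(series) >= -1e-12)
    midpoint = urine_at(result, "NIC", 123.45)
    lo = urine_at(result, "NIC", 123.0)
    hi = urine_at(result, "NIC", 124.0)
    assert lo <= midpoint <= hi
    with pytest.raises(DomainError):
        urine_at(result, "NIC", -1.0)


def test_result_validates_grid_and_shapes():
    with pytest.raises(DomainError, match="strictly increasing"):
        synthetic_result([0.0, 1.0, 1.0], [1.0, 1.0, 1.0])
    with pytest.raises(DomainError, match="shape"):
        SimulationResult(np.array([0.0, 1.0]), np.zeros((2, 3)),
                         ("NIC:venous", "urine:NIC"), {"NIC:venous": 1.0})


def test_plasma_alias_resolves_to_venous(women_infusion):
    _, _, result = women_infusion
    assert np.array_equal(result.concentration("plasma", "NIC"),
                          result.concentration("venous", "NIC"))
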