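"""Maternal-placental-fetal PBPK right-hand side, simulation and calibration.

Model structure
---------------
Both compounds are simulated simultaneously on a flow-limited (perfusion
limited) compartment system: every tissue equilibrates with its perfusing
blood so that the venous outflow concentration is ``C_tissue / P_tissue``.
Nicotine and cotinine are coupled in the liver, where a fixed molar
fraction (default 80%) of hepatically eliminated nicotine appears as
newly formed cotinine.  During pregnancy the placenta exchanges with fetal
blood through directional influx/efflux transfer clearances, and the fetus
disposes of both compounds through a reduced-capacity fetal liver.

Clearance reference
-------------------
The published hepatic/renal clearances for women and pregnant women are
whole-body *systemic* plasma clearances measured in infusion studies.  By
default the model therefore back-computes the intrinsic organ clearance
through the well-stirred relation ``CL_int = Q * CL / (Q - CL)`` so that
the simulated systemic clearance reproduces the measured value; applying
the published numbers directly as intrinsic terms would cap the effective
clearance at organ blood flow and underestimate elimination (the pregnant
hepatic nicotine clearance approaches hepatic blood flow).  Set
``clearance_reference="intrinsic"`` to use the values verbatim instead.

The system is linear in the state, so the right-hand side is assembled
once as a constant matrix plus the time-dependent dosing input.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import dosing as _dosing
from .compound_params import (
    COT, COTININE, MW_RATIO_COT_NIC, NIC, NICOTINE,
    ClearanceSet, CompoundParams, to_absolute_clearance,
)
from .dosing import DoseSchedule
from .errors import CalibrationError, ConfigurationError, DomainError, NumericalError
from .physiology import FETAL_TISSUES, FetalPhysiology, MaternalPhysiology
from .pk_metrics import SimulationResult

COMPOUNDS = (NIC, COT)

MATERNAL_STATES = (
    "arterial", "venous", "lung", "brain", "liver", "kidney",
    "rapid", "muscle", "fat", "mammary", "uterus", "placenta",
)
FETAL_STATES = tuple(f"fetal_{name}" for name in ("blood",) + FETAL_TISSUES)

#: dosing input compartments (shared with :mod:`nicpbpk.dosing`)
_INPUT_COMPARTMENTS = ("venous", "lung", "liver")

#: fraction of organ blood flow the systemic clearance may not exceed when
#: inverting the well-stirred relation
_WELL_STIRRED_MARGIN = 0.95


@dataclass(frozen=True)
class PlacentalTransfer:
    """Directional placental transfer clearances (L/h) per compound."""

    influx_nic: float   # maternal -> fetal, acts on placenta outflow conc.
    efflux_nic: float   # fetal -> maternal, acts on fetal blood conc.
    influx_cot: float
    efflux_cot: float

    def __post_init__(self) -> None:
        for name in ("influx_nic", "efflux_nic", "influx_cot", "efflux_cot"):
            if getattr(self, name) < 0:
                raise DomainError(f"placental transfer {name} must be >= 0")

    def influx(self, compound: str) -> float:
        return self.influx_nic if compound == NIC else self.influx_cot

    def efflux(self, compound: str) -> float:
        return self.efflux_nic if compound == NIC else self.efflux_cot

    def to_dict(self) -> dict:
        return {
            "influx_nic": self.influx_nic, "efflux_nic": self.efflux_nic,
            "influx_cot": self.influx_cot, "efflux_cot": self.efflux_cot,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PlacentalTransfer":
        return cls(**data)


@dataclass(frozen=True)
class ModelOptions:
    """Numerical and structural switches of the ODE model."""

    #: "systemic": published clearances are whole-body values, converted to
    #: intrinsic organ clearances via the well-stirred relation (default);
    #: "intrinsic": published values are applied verbatim to organ outflow.
    clearance_reference: str = "systemic"
    #: apply the MW_COT/MW_NIC mass ratio to the nicotine->cotinine flux so
    #: the 80% conversion is molar while states are tracked in mass units
    mw_scaling: bool = True
    rtol: float = 1e-8
    atol: float = 1e-10  # µg

    def __post_init__(self) -> None:
        if self.clearance_reference not in ("systemic", "intrinsic"):
            raise DomainError(
                "clearance_reference must be 'systemic' or 'intrinsic', "
                f"got {self.clearance_reference!r}")


class StateIndex:
    """Published index map of the state vector.

    Dynamic states come first — per compound: the maternal compartments,
    then (when a fetus is present) placenta and the fetal compartments —
    followed by the bookkeeping accumulators (urine, cumulative hepatic
    elimination, cumulative cotinine formation).  In the pregnant
    configuration there are 32 dynamic equations (2 compounds x 16
    compartments), matching the published count; the accumulators are
    additional bookkeeping states.
    """

    def __init__(self, pregnant: bool) -> None:
        self.pregnant = pregnant
        compartments = [s for s in MATERNAL_STATES if pregnant or s != "placenta"]
        if pregnant:
            compartments += list(FETAL_STATES)
        self.compartments = tuple(compartments)
        names = [f"{c}:{s}" for c in COMPOUNDS for s in compartments]
        self.n_dynamic = len(names)
        names += [f"urine:{c}" for c in COMPOUNDS]
        names += [f"hepatic_sink:{c}" for c in COMPOUNDS]
        names += ["formed:COT"]
        self.names = tuple(names)
        self._pos = {n: i for i, n in enumerate(names)}

    def __len__(self) -> int:
        return len(self.names)

    def of(self, compound: str, compartment: str) -> int:
        try:
            return self._pos[f"{compound}:{compartment}"]
        except KeyError:
            raise DomainError(
                f"no state for compound {compound!r} in compartment {compartment!r}"
            ) from None

    def accumulator(self, name: str) -> int:
        return self._pos[name]


def _intrinsic_clearance(cl_systemic: float, organ_flow: float, where: str) -> float:
    """Invert the well-stirred relation; the result satisfies
    ``Q * CL_int / (Q + CL_int) == cl_systemic``."""
    if cl_systemic == 0.0:
        return 0.0
    if cl_systemic >= _WELL_STIRRED_MARGIN * organ_flow:
        raise ConfigurationError(
            f"{where}: systemic clearance {cl_systemic:.3g} L/h is not attainable "
            f"with organ blood flow {organ_flow:.3g} L/h (well-stirred limit); "
            "increase the configured organ flow or use clearance_reference='intrinsic'")
    return organ_flow * cl_systemic / (organ_flow - cl_systemic)


class PBPKModel:
    """Assembled linear ODE system for one subject and parameter set."""

    def __init__(
        self,
        maternal: MaternalPhysiology,
        fetal: Optional[FetalPhysiology],
        clearances: ClearanceSet,
        placenta: Optional[PlacentalTransfer] = None,
        nicotine: CompoundParams = NICOTINE,
        cotinine: CompoundParams = COTININE,
        options: ModelOptions = ModelOptions(),
    ) -> None:
        if maternal.is_pregnant and fetal is None:
            raise DomainError("pregnant physiology requires a fetal physiology")
        if not maternal.is_pregnant and fetal is not None:
            raise DomainError("non-pregnant physiology cannot carry a fetus")
        if maternal.is_pregnant and placenta is None:
            raise DomainError("pregnant model requires placental transfer parameters")
        self.maternal = maternal
        self.fetal = fetal
        self.clearances = clearances
        self.placenta = placenta
        self.nicotine = nicotine
        self.cotinine = cotinine
        self.options = options
        self.index = StateIndex(pregnant=maternal.is_pregnant)
        self._build()

    # -- assembly ----------------------------------------------------------
    def _organ_clearance(self, pathway: str, organ_flow: float) -> float:
        cl_abs = to_absolute_clearance(
            getattr(self.clearances, pathway), self.clearances.unit,
            self.maternal.body_weight)
        if self.options.clearance_reference == "systemic":
            return _intrinsic_clearance(cl_abs, organ_flow, f"clearances.{pathway}")
        return cl_abs

    def _fetal_clearance(self, pathway: str, organ_flow: float) -> float:
        assert self.fetal is not None
        cl_abs = self.fetal.hepatic_clearance_fraction * to_absolute_clearance(
            getattr(self.clearances, pathway), self.clearances.unit,
            self.fetal.body_weight)
        if self.options.clearance_reference == "systemic":
            return _intrinsic_clearance(cl_abs, organ_flow, f"fetal {pathway}")
        return cl_abs

    def _build(self) -> None:
        idx = self.index
        n = len(idx)
        M = np.zeros((n, n))
        maternal = self.maternal
        pregnant = maternal.is_pregnant
        f_met = self.nicotine.metabolic_fraction_to_cotinine or 0.0
        mw_factor = MW_RATIO_COT_NIC if self.options.mw_scaling else 1.0

        volumes: dict[str, float] = {}
        for compound in COMPOUNDS:
            volumes[f"{compound}:arterial"] = maternal.arterial_volume
            volumes[f"{compound}:venous"] = maternal.venous_volume
            for t in maternal.tissues:
                volumes[f"{compound}:{t.name}"] = t.volume
            if pregnant:
                volumes[f"{compound}:fetal_blood"] = self.fetal.blood_volume
                for t in self.fetal.tissues:
                    volumes[f"{compound}:fetal_{t.name}"] = t.volume
        self.volumes = volumes

        co = maternal.cardiac_output
        liver = maternal.tissue("liver")
        kidney = maternal.tissue("kidney")
        cl_h = {NIC: self._organ_clearance("hepatic_nic", liver.blood_flow),
                COT: self._organ_clearance("hepatic_cot", liver.blood_flow)}
        cl_r = {NIC: self._organ_clearance("renal_nic", kidney.blood_flow),
                COT: self._organ_clearance("renal_cot", kidney.blood_flow)}
        self.intrinsic_hepatic = dict(cl_h)
        self.intrinsic_renal = dict(cl_r)

        for compound in COMPOUNDS:
            art = idx.of(compound, "arterial")
            ven = idx.of(compound, "venous")
            lung = idx.of(compound, "lung")
            v_art = volumes[f"{compound}:arterial"]
            v_ven = volumes[f"{compound}:venous"]
            lung_spec = maternal.tissue("lung")
            k_lung_out = co / (lung_spec.volume * lung_spec.partition(compound))

            # lung: Q_co * (C_ven - C_lung/P_lung)
            M[lung, ven] += co / v_ven
            M[lung, lung] -= k_lung_out
            # arterial: Q_co * C_lung/P_lung - sum_i Q_i * C_art
            M[art, lung] += k_lung_out
            M[art, art] -= co / v_art
            # venous: sum_i Q_i * C_i/P_i - Q_co * C_ven
            M[ven, ven] -= co / v_ven

            for t in maternal.tissues:
                if t.name == "lung":
                    continue
                i = idx.of(compound, t.name)
                k_out = t.blood_flow / (t.volume * t.partition(compound))
                M[i, art] += t.blood_flow / v_art
                M[i, i] -= k_out
                M[ven, i] += k_out

            # hepatic elimination on liver outflow concentration
            liv = idx.of(compound, "liver")
            k_liv = cl_h[compound] / (liver.volume * liver.partition(compound))
            M[liv, liv] -= k_liv
            M[idx.accumulator(f"hepatic_sink:{compound}"), liv] += k_liv

            # renal elimination on kidney outflow concentration -> urine
            kid = idx.of(compound, "kidney")
            k_kid = cl_r[compound] / (kidney.volume * kidney.partition(compound))
            M[kid, kid] -= k_kid
            M[idx.accumulator(f"urine:{compound}"), kid] += k_kid

        # nicotine -> cotinine biotransformation in the maternal liver
        nic_liv = idx.of(NIC, "liver")
        k_h_nic = cl_h[NIC] / (liver.volume * liver.partition(NIC))
        M[idx.of(COT, "liver"), nic_liv] += f_met * mw_factor * k_h_nic
        M[idx.accumulator("formed:COT"), nic_liv] += f_met * mw_factor * k_h_nic

        if pregnant:
            fetal = self.fetal
            fetal_liver = fetal.tissue("liver")
            cl_f = {NIC: self._fetal_clearance("hepatic_nic", fetal_liver.blood_flow),
                    COT: self._fetal_clearance("hepatic_cot", fetal_liver.blood_flow)}
            self.fetal_hepatic = dict(cl_f)
            placenta_spec = maternal.tissue("placenta")
            v_fb = fetal.blood_volume
            for compound in COMPOUNDS:
                pl = idx.of(compound, "placenta")
                fb = idx.of(compound, "fetal_blood")
                k_pl_out = self.placenta.influx(compound) / (
                    placenta_spec.volume * placenta_spec.partition(compound))
                k_fb_out = self.placenta.efflux(compound) / v_fb
                # placenta <-> fetal blood transfer
                M[pl, pl] -= k_pl_out
                M[pl, fb] += k_fb_out
                M[fb, pl] += k_pl_out
                M[fb, fb] -= k_fb_out
                # fetal circulation
                for t in fetal.tissues:
                    j = idx.of(compound, f"fetal_{t.name}")
                    k_out = t.blood_flow / (t.volume * t.partition(compound))
                    M[j, fb] += t.blood_flow / v_fb
                    M[j, j] -= k_out
                    M[fb, j] += k_out
                    M[fb, fb] -= t.blood_flow / v_fb
                # fetal hepatic elimination (renal assumed absent before birth)
                fl = idx.of(compound, "fetal_liver")
                k_fl = cl_f[compound] / (fetal_liver.volume * fetal_liver.partition(compound))
                M[fl, fl] -= k_fl
                M[idx.accumulator(f"hepatic_sink:{compound}"), fl] += k_fl
            # fetal nicotine -> cotinine coupling, as in the maternal liver
            fl_nic = idx.of(NIC, "fetal_liver")
            k_fl_nic = cl_f[NIC] / (fetal_liver.volume * fetal_liver.partition(NIC))
            M[idx.of(COT, "fetal_liver"), fl_nic] += f_met * mw_factor * k_fl_nic
            M[idx.accumulator("formed:COT"), fl_nic] += f_met * mw_factor * k_fl_nic

        self.matrix = M

    # -- evaluation --------------------------------------------------------
    def _input_vector(self, t_min: float, schedule: DoseSchedule) -> np.ndarray:
        """Continuous dosing input, µg/h per state."""
        u = np.zeros(len(self.index))
        for compound in COMPOUNDS:
            for compartment in _INPUT_COMPARTMENTS:
                rate = _dosing.input_rate(schedule, compound, compartment, t_min)
                if rate:
                    u[self.index.of(compound, compartment)] += rate * 60.0
        return u

    def rhs(self, state: np.ndarray, t_min: float, schedule: Optional[DoseSchedule] = None) -> np.ndarray:
        """Time derivative of the state in µg/min at ``t_min``."""
        state = np.asarray(state, dtype=float)
        if state.shape != (len(self.index),):
            raise DomainError(
                f"state must have length {len(self.index)}, got {state.shape}")
        if not np.all(np.isfinite(state)):
            bad = self.index.names[int(np.argmax(~np.isfinite(state)))]
            raise NumericalError(f"non-finite amount in state {bad!r} at t={t_min} min")
        du = self.matrix @ state
        if schedule is not None:
            du = du + self._input_vector(t_min, schedule)
        return du / 60.0

    # -- simulation --------------------------------------------------------
    def simulate(
        self,
        schedule: DoseSchedule,
        horizon_h: float,
        output_dt_min: float = 0.1,
        initial_state: Optional[np.ndarray] = None,
        metadata: Optional[dict] = None,
    ) -> SimulationResult:
        """Integrate the model and return dense output on a regular grid.

        Integration restarts at every dose-event boundary so that input
        discontinuities and bolus jumps are handled exactly.
        """
        if horizon_h <= 0:
            raise DomainError("horizon must be > 0")
        horizon_min = horizon_h * 60.0
        n = len(self.index)
        grid = np.arange(0.0, horizon_min + 0.5 * output_dt_min, output_dt_min)
        grid[-1] = min(grid[-1], horizon_min)

        bolus_times = sorted({
            e.start for c in COMPOUNDS for e in schedule.bolus_events(c)
            if e.start <= horizon_min})
        boundaries = sorted(set(schedule.breakpoints_min(horizon_min)) | set(bolus_times))
        segments = [0.0] + [b for b in boundaries if 0.0 < b < horizon_min] + [horizon_min]

        y = np.zeros(n) if initial_state is None else np.asarray(initial_state, dtype=float).copy()
        times = [0.0]
        states = [None]  # placeholder, filled after t=0 boluses

        def jac(_t: float, _y: np.ndarray) -> np.ndarray:
            return self.matrix / 60.0

        def f(t: float, x: np.ndarray) -> np.ndarray:
            return (self.matrix @ x + self._input_vector(t, schedule)) / 60.0

        for t0, t1 in zip(segments[:-1], segments[1:]):
            for compound in COMPOUNDS:
                for compartment, amount in _dosing.bolus_state_increment(
                        schedule, compound, t0).items():
                    y[self.index.of(compound, compartment)] += amount
            if t0 == 0.0:
                states[0] = y.copy()
            if t1 <= t0:
                continue
            t_eval = grid[(grid > t0) & (grid <= t1)]
            if len(t_eval) == 0 or t_eval[-1] < t1:
                t_eval = np.append(t_eval, t1)
            sol = solve_ivp(
                f, (t0, t1), y, method="LSODA", t_eval=t_eval,
                rtol=self.options.rtol, atol=self.options.atol, jac=jac)
            if not sol.success:
                raise NumericalError(
                    f"ODE solver failed on [{t0}, {t1}] min: {sol.message}")
            keep = np.isin(sol.t, grid)
            times.extend(sol.t[keep].tolist())
            for col in sol.y[:, keep].T:
                states.append(col)
            y = sol.y[:, -1].copy()

        amounts = np.column_stack(states)
        # zero out solver-scale negative amounts; anything larger is an error
        floor = amounts.min()
        if floor < -1e-9:
            bad = self.index.names[int(np.argmin(amounts.min(axis=1)))]
            raise NumericalError(
                f"negative amount {floor:.3e} µg in state {bad!r}; tighten tolerances")
        np.clip(amounts, 0.0, None, out=amounts)

        meta = {
            "gestation_week": self.maternal.gestation_week,
            "body_weight_kg": self.maternal.body_weight,
            "clearance_population": self.clearances.population,
            "clearance_reference": self.options.clearance_reference,
            "solver": {"method": "LSODA", "rtol": self.options.rtol,
                       "atol": self.options.atol, "output_dt_min": output_dt_min},
            "n_dynamic_equations": self.index.n_dynamic,
        }
        if metadata:
            meta.update(metadata)
        return SimulationResult(
            time_min=np.asarray(times),
            amounts=amounts,
            state_names=self.index.names,
            volumes=self.volumes,
            metadata=meta,
        )

    # -- audits ------------------------------------------------------------
    def mass_balance_residual(self, result: SimulationResult, schedule: DoseSchedule) -> np.ndarray:
        """Relative mass-balance residual at every output time.

        For each compound: delivered(t) (+ formed, for cotinine) must equal
        the sum of all compartment amounts plus urine plus the cumulative
        hepatic sink.  Returns the worse of the two compounds' relative
        residuals (normalized by total delivered mass).
        """
        worst = np.zeros(len(result.time_min))
        for compound in COMPOUNDS:
            delivered = np.array([
                _delivered_mass(schedule, compound, t) for t in result.time_min])
            in_body = np.zeros(len(result.time_min))
            for compartment in self.index.compartments:
                in_body += result.amount(compartment, compound)
            total = (in_body + result.urine(compound)
                     + result.hepatic_eliminated(compound))
            source = delivered + (result.cotinine_formed() if compound == COT else 0.0)
            scale = max(source[-1], 1.0)
            worst = np.maximum(worst, np.abs(total - source) / scale)
        return worst


def _delivered_mass(schedule: DoseSchedule, compound: str, t_min: float) -> float:
    """Cumulative mass (µg) delivered into the system by time ``t_min``."""
    total = 0.0
    for e in schedule.events:
        if e.compound != compound or e.start > t_min:
            continue
        if e.route == "iv_bolus":
            total += e.amount
        elif e.route == "oral":
            ka_min = e.ka_per_h / 60.0
            total += e.bioavailability * e.amount * (1.0 - np.exp(-ka_min * (t_min - e.start)))
        else:
            window = min(t_min - e.start, e.duration)
            rate = e.rate if e.route == "iv_infusion" else e.amount / e.duration
            total += rate * window
    return total


# ---------------------------------------------------------------------------
# placental transfer calibration


def calibrate_placenta(
    maternal: MaternalPhysiology,
    fetal: FetalPhysiology,
    clearances: ClearanceSet,
    target_nic_ratio: float = 1.15,
    target_cot_ratio: float = 0.9,
    tolerance: float = 0.02,
    influx_nic: float = 20.0,
    influx_cot: float = 5.0,
    infusion_rate_ug_min: float = 10.0,
    settle_h: float = 48.0,
    options: ModelOptions = ModelOptions(),
) -> PlacentalTransfer:
    """Calibrate placental efflux constants against quasi-steady-state ratios.

    The influx scales are held fixed (the fetal/maternal ratio depends on
    the efflux/influx balance, not the absolute scale) and the efflux
    constants are found by deterministic 1-D root searches so that, under a
    sustained maternal nicotine infusion, the fetal-blood / maternal-venous
    concentration ratio reaches ``target_nic_ratio`` for nicotine and
    ``target_cot_ratio`` (< 1) for cotinine.  The returned constants are
    verified by simulation; failure to bracket a target raises
    :class:`CalibrationError` reporting the achievable range.
    """
    if not maternal.is_pregnant:
        raise DomainError("placental calibration requires a pregnant physiology")
    if not (0 < target_cot_ratio < 1):
        raise DomainError("target cotinine ratio must lie in (0, 1)")

    schedule = DoseSchedule([
        _dosing.DoseEvent(route="iv_infusion", compound=NIC,
                          rate=infusion_rate_ug_min, start=0.0,
                          duration=settle_h * 60.0)])

    def ratios(transfer: PlacentalTransfer) -> tuple[float, float]:
        model = PBPKModel(maternal, fetal, clearances, placenta=transfer,
                          options=options)
        result = model.simulate(schedule, horizon_h=settle_h, output_dt_min=5.0)
        nic = (result.concentration("fetal_blood", NIC)[-1]
               / result.concentration("venous", NIC)[-1])
        cot = (result.concentration("fetal_blood", COT)[-1]
               / result.concentration("venous", COT)[-1])
        return float(nic), float(cot)

    def solve(which: str, target: float, base: PlacentalTransfer) -> float:
        lo, hi = 1e-3, 1e3  # efflux/influx ratio bracket
        influx = base.influx(NIC if which == "nic" else COT)

        def objective(log_ratio: float) -> float:
            efflux = influx * 10.0 ** log_ratio
            transfer = replace(base, **{f"efflux_{which}": efflux})
            value = ratios(transfer)[0 if which == "nic" else 1]
            return value - target

        f_lo, f_hi = objective(np.log10(lo)), objective(np.log10(hi))
        if f_lo * f_hi > 0:
            raise CalibrationError(
                f"{which.upper()} fetal/maternal ratio target {target} is outside the "
                f"achievable range [{f_hi + target:.3f}, {f_lo + target:.3f}] "
                "with non-negative transfer constants")
        log_ratio = brentq(objective, np.log10(lo), np.log10(hi), xtol=1e-6)
        return influx * 10.0 ** log_ratio

    transfer = PlacentalTransfer(
        influx_nic=influx_nic, efflux_nic=influx_nic,
        influx_cot=influx_cot, efflux_cot=influx_cot)
    transfer = replace(transfer, efflux_nic=solve("nic", target_nic_ratio, transfer))
    transfer = replace(transfer, efflux_cot=solve("cot", target_cot_ratio, transfer))

    nic_ratio, cot_ratio = ratios(transfer)
    if abs(nic_ratio - target_nic_ratio) > tolerance or not cot_ratio < 1.0:
        raise CalibrationError(
            f"calibration verification failed: NIC ratio {nic_ratio:.4f} "
            f"(target {target_nic_ratio} ± {tolerance}), COT ratio {cot_ratio:.4f}")
    return transfer
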