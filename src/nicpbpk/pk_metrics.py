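"""Noncompartmental post-processing of simulated concentration-time courses.

Provides the container for simulation output (:class:`SimulationResult`)
and the standard NCA quantities: Cmax/Tmax, terminal half-life by
log-linear regression, trapezoidal AUC, cumulative urinary amounts and
percent differences between paired runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError

#: aliases accepted wherever a compartment name is expected; "plasma" means
#: venous blood (the clinically sampled pool)
COMPARTMENT_ALIASES = {
    "plasma": "venous",
    "fetal_plasma": "fetal_blood",
}


def resolve_compartment(name: str) -> str:
    return COMPARTMENT_ALIASES.get(name, name)


@dataclass
class SimulationResult:
    """Dense simulated time courses for both compounds.

    ``amounts`` holds µg per state on the output grid; concentrations are
    derived as amount / compartment volume (µg/L).  Bookkeeping
    accumulators (urine, cumulative hepatic elimination, cumulative
    cotinine formation) are carried alongside the dynamic states so that
    mass balance can be audited at every output time.
    """

    time_min: np.ndarray                       # strictly increasing, min
    amounts: np.ndarray                        # n_states x n_times, µg
    state_names: tuple[str, ...]               # e.g. "NIC:liver", "urine:COT"
    volumes: Mapping[str, float]               # dynamic state name -> L
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.amounts = np.asarray(self.amounts, dtype=float)
        if np.any(np.diff(self.time_min) <= 0):
            raise DomainError("time grid must be strictly increasing")
        if self.amounts.shape != (len(self.state_names), len(self.time_min)):
            raise DomainError("amounts shape inconsistent with state names / time grid")
        self._index = {name: i for i, name in enumerate(self.state_names)}

    # -- accessors ---------------------------------------------------------
    @property
    def time_h(self) -> np.ndarray:
        return self.time_min / 60.0

    def _state(self, name: str) -> np.ndarray:
        try:
            return self.amounts[self._index[name]]
        except KeyError:
            raise DomainError(f"no state named {name!r} in this simulation") from None

    def amount(self, compartment: str, compound: str) -> np.ndarray:
        """Amount (µg) in a compartment over time."""
        return self._state(f"{compound}:{resolve_compartment(compartment)}")

    def concentration(self, compartment: str, compound: str) -> np.ndarray:
        """Concentration (µg/L) in a compartment over time."""
        name = f"{compound}:{resolve_compartment(compartment)}"
        return self._state(name) / self.volumes[name]

    def urine(self, compound: str) -> np.ndarray:
        """Cumulative amount excreted unchanged in urine (µg)."""
        return self._state(f"urine:{compound}")

    def hepatic_eliminated(self, compound: str) -> np.ndarray:
        """Cumulative hepatically eliminated mass (µg of the compound)."""
        return self._state(f"hepatic_sink:{compound}")

    def cotinine_formed(self) -> np.ndarray:
        """Cumulative cotinine mass formed from nicotine (µg of cotinine)."""
        return self._state("formed:COT")

    def compartments(self, compound: str) -> list[str]:
        prefix = f"{compound}:"
        return [n[len(prefix):] for n in self.state_names
                if n.startswith(prefix) and n in self.volumes]

    def at(self, series: np.ndarray, t_min: float) -> float:
        """Interpolate a stored series at ``t_min`` (grid-internal only)."""
        if not (self.time_min[0] <= t_min <= self.time_min[-1]):
            raise DomainError(
                f"t={t_min} min outside simulated grid "
                f"[{self.time_min[0]}, {self.time_min[-1]}]")
        return float(np.interp(t_min, self.time_min, series))

    def to_frame(self, compartments: Optional[list[str]] = None) -> pd.DataFrame:
        """Long-format table (time_min, compartment, compound, concentration_ug_per_L)."""
        rows = []
        for compound in ("NIC", "COT"):
            for compartment in self.compartments(compound):
                if compartments is not None and compartment not in compartments:
                    continue
                rows.append(pd.DataFrame({
                    "time_min": self.time_min,
                    "compartment": compartment,
                    "compound": compound,
                    "concentration_ug_per_L": self.concentration(compartment, compound),
                }))
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class CmaxTmax:
    cmax: float      # µg/L
    tmax_min: float  # min
    all_zero: bool = False

    def __iter__(self) -> Iterator[float]:
        return iter((self.cmax, self.tmax_min))


@dataclass(frozen=True)
class HalfLifeEstimate:
    half_life_h: float
    r_squared: float
    n_points: int
    low_confidence: bool

    def __float__(self) -> float:
        return self.half_life_h


@dataclass(frozen=True)
class PKMetrics:
    """Summary metrics for one (compartment, compound) trajectory."""

    compartment: str
    compound: str
    cmax: float                      # µg/L
    tmax_min: float
    half_life_h: Optional[float]
    half_life_r_squared: Optional[float]
    auc_ug_h_per_L: float
    urine_cumulative_ug: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "compartment": self.compartment,
            "compound": self.compound,
            "cmax_ug_per_L": self.cmax,
            "tmax_min": self.tmax_min,
            "half_life_h": self.half_life_h,
            "half_life_r_squared": self.half_life_r_squared,
            "auc_ug_h_per_L": self.auc_ug_h_per_L,
            "urine_cumulative_ug": self.urine_cumulative_ug,
        }


def cmax_tmax(result: SimulationResult, compartment: str, compound: str) -> CmaxTmax:
    """Maximum concentration and its time; ties broken by earliest time."""
    conc = result.concentration(compartment, compound)
    if np.all(conc == 0.0):
        return CmaxTmax(0.0, 0.0, all_zero=True)
    i = int(np.argmax(conc))  # argmax returns the first maximizer
    return CmaxTmax(float(conc[i]), float(result.time_min[i]))


def terminal_half_life(
    result: SimulationResult,
    compartment: str,
    compound: str,
    window: float = 0.3,
    r_squared_threshold: float = 0.95,
) -> HalfLifeEstimate:
    """Terminal half-life from a log-linear fit over the trailing window.

    ``window`` is the trailing fraction of the simulated span used for the
    fit (default: last 30%).  Requires at least five strictly positive
    post-Tmax samples in the window.  A fit with R² below the threshold is
    returned flagged rather than rejected.
    """
    if not (0.0 < window <= 1.0):
        raise DomainError(f"window must be in (0, 1], got {window}")
    conc = result.concentration(compartment, compound)
    t_h = result.time_h
    t_start = t_h[-1] - window * (t_h[-1] - t_h[0])
    i_tmax = int(np.argmax(conc))
    mask = (t_h >= t_start) & (conc > 0.0) & (t_h > t_h[i_tmax])
    if mask.sum() < 5:
        raise DomainError(
            "terminal window holds fewer than 5 positive post-Tmax samples; "
            "extend the horizon or widen the window")
    fit = stats.linregress(t_h[mask], np.log(conc[mask]))
    if fit.slope >= 0:
        raise DomainError("terminal concentrations are not decaying; no half-life estimable")
    r2 = float(fit.rvalue ** 2)
    return HalfLifeEstimate(
        half_life_h=float(np.log(2.0) / -fit.slope),
        r_squared=r2,
        n_points=int(mask.sum()),
        low_confidence=r2 < r_squared_threshold,
    )


def percent_lower(
    reference: SimulationResult,
    test: SimulationResult,
    compartment: str,
    compound: str,
    t_min: float,
) -> float:
    """Percent by which ``test`` is below ``reference`` at ``t_min``.

    ``100 * (C_ref - C_test) / C_ref``; negative if the test run is higher.
    """
    c_ref = reference.at(reference.concentration(compartment, compound), t_min)
    c_test = test.at(test.concentration(compartment, compound), t_min)
    if c_ref <= 0:
        raise DomainError(f"reference concentration at t={t_min} min is not positive")
    return 100.0 * (c_ref - c_test) / c_ref


def urine_at(result: SimulationResult, compound: str, t_min: float) -> float:
    """Cumulative urinary amount (µg) at ``t_min`` (interpolated)."""
    return result.at(result.urine(compound), t_min)


def auc(
    result: SimulationResult, compartment: str, compound: str,
    t0_min: float, t1_min: float,
) -> float:
    """Trapezoidal AUC (µg·h/L) of a concentration curve over [t0, t1]."""
    if t1_min <= t0_min:
        raise DomainError(f"AUC interval requires t1 > t0, got [{t0_min}, {t1_min}]")
    conc = result.concentration(compartment, compound)
    t = result.time_min
    if not (t[0] <= t0_min and t1_min <= t[-1]):
        raise DomainError("AUC interval outside the simulated grid")
    # refine endpoints by interpolation so the integral is exact on the grid
    inner = (t > t0_min) & (t < t1_min)
    ts = np.concatenate(([t0_min], t[inner], [t1_min]))
    cs = np.concatenate((
        [np.interp(t0_min, t, conc)], conc[inner], [np.interp(t1_min, t, conc)]))
    return float(np.trapezoid(cs, ts / 60.0))


def summarize(
    result: SimulationResult,
    compartment: str,
    compound: str,
    half_life_window: float = 0.3,
    urine_time_min: Optional[float] = None,
) -> PKMetrics:
    """Assemble the standard metric set for one trajectory."""
    peak = cmax_tmax(result, compartment, compound)
    try:
        hl = terminal_half_life(result, compartment, compound, window=half_life_window)
        half_life, r2 = hl.half_life_h, hl.r_squared
    except DomainError:
        half_life, r2 = None, None
    urine = None
    if urine_time_min is not None:
        urine = urine_at(result, compound, urine_time_min)
    return PKMetrics(
        compartment=compartment,
        compound=compound,
        cmax=peak.cmax,
        tmax_min=peak.tmax_min,
        half_life_h=half_life,
        half_life_r_squared=r2,
        auc_ug_h_per_L=auc(result, compartment, compound,
                           result.time_min[0], result.time_min[-1]),
        urine_cumulative_ug=urine,
    )
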