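"""Administration schedules for the intravenous, inhalation and oral routes.

Doses are expressed at the interface in minutes and µg (matching how the
regimens are reported clinically); the ODE core converts to hours
internally.  Routes map to input compartments as follows:

* ``iv_bolus`` / ``iv_infusion`` -> venous blood
* ``inhalation``                 -> lung (zero-order over a short puff train)
* ``oral``                       -> liver inflow (portal), first-order
  absorption with rate constant ``ka_per_h`` and bioavailability ``F``;
  both are required on the event because no validated defaults exist.

The oral depot is handled analytically (the absorption rate is a closed
form exponential), so it adds no state variables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

from .compound_params import COT, NIC
from .errors import DomainError

ROUTES = ("iv_bolus", "iv_infusion", "inhalation", "oral")

_ROUTE_COMPARTMENT = {
    "iv_bolus": "venous",
    "iv_infusion": "venous",
    "inhalation": "lung",
    "oral": "liver",
}

DEFAULT_INHALATION_DURATION_MIN = 5.0

#: absorption tail length (in multiples of 1/ka) beyond which an oral event
#: no longer contributes to the input rate; exp(-36) underflows tolerance.
_ORAL_TAIL = 36.0


@dataclass(frozen=True)
class DoseEvent:
    route: str
    compound: str
    amount: Optional[float] = None      # µg (bolus / oral / inhalation total)
    rate: Optional[float] = None        # µg/min (infusion)
    start: float = 0.0                  # min
    duration: float = 0.0               # min (infusion / inhalation)
    ka_per_h: Optional[float] = None    # oral absorption rate constant, 1/h
    bioavailability: Optional[float] = None  # oral F

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise DomainError(f"unknown route {self.route!r}; expected one of {ROUTES}")
        if self.compound not in (NIC, COT):
            raise DomainError(f"compound must be NIC or COT, got {self.compound!r}")
        if self.start < 0:
            raise DomainError("start must be >= 0")
        if self.duration < 0:
            raise DomainError("duration must be >= 0")
        if self.route == "iv_bolus":
            self._require_amount()
            if self.duration != 0:
                raise DomainError("iv_bolus must have duration 0")
        elif self.route == "iv_infusion":
            if self.rate is None or self.rate < 0:
                raise DomainError("iv_infusion requires rate >= 0 (µg/min)")
            if self.duration <= 0:
                raise DomainError("iv_infusion requires duration > 0")
            if self.amount is not None:
                raise DomainError("iv_infusion takes a rate, not an amount")
        elif self.route == "inhalation":
            self._require_amount()
            if self.duration <= 0:
                object.__setattr__(self, "duration", DEFAULT_INHALATION_DURATION_MIN)
        elif self.route == "oral":
            self._require_amount()
            if self.ka_per_h is None or self.ka_per_h <= 0:
                raise DomainError("oral dosing requires ka_per_h > 0 (no default is provided)")
            if self.bioavailability is None or not (0.0 <= self.bioavailability <= 1.0):
                raise DomainError("oral dosing requires bioavailability in [0,1]")

    def _require_amount(self) -> None:
        if self.amount is None or self.amount < 0:
            raise DomainError(f"{self.route} requires amount >= 0 (µg)")

    @property
    def target_compartment(self) -> str:
        return _ROUTE_COMPARTMENT[self.route]

    @property
    def delivered_amount(self) -> float:
        """Total mass entering the system, µg (oral scaled by bioavailability)."""
        if self.route == "iv_infusion":
            return self.rate * self.duration
        if self.route == "oral":
            return self.amount * self.bioavailability
        return self.amount

    def continuous_rate(self, t_min: float) -> float:
        """Continuous input rate contribution at time ``t_min``, µg/min."""
        if self.route == "iv_bolus":
            return 0.0
        if self.route == "oral":
            ka_min = self.ka_per_h / 60.0
            dt = t_min - self.start
            if dt < 0 or ka_min * dt > _ORAL_TAIL:
                return 0.0
            return self.bioavailability * self.amount * ka_min * math.exp(-ka_min * dt)
        # zero-order window (infusion or puff train)
        if self.start <= t_min < self.start + self.duration:
            return self.rate if self.route == "iv_infusion" else self.amount / self.duration
        return 0.0


@dataclass(frozen=True)
class DoseSchedule:
    events: tuple[DoseEvent, ...]

    def __init__(self, events: Iterable[DoseEvent] = ()) -> None:
        object.__setattr__(
            self, "events", tuple(sorted(events, key=lambda e: e.start)))

    def total_delivered(self, compound: str) -> float:
        return sum(e.delivered_amount for e in self.events if e.compound == compound)

    def bolus_events(self, compound: str) -> list[DoseEvent]:
        return [e for e in self.events
                if e.compound == compound and e.route == "iv_bolus"]

    def breakpoints_min(self, horizon_min: float) -> list[float]:
        """Event boundaries in (0, horizon) at which integration restarts."""
        times = set()
        for e in self.events:
            times.add(e.start)
            if e.route in ("iv_infusion", "inhalation"):
                times.add(e.start + e.duration)
        return sorted(t for t in times if 0.0 < t < horizon_min)

    @classmethod
    def from_dicts(cls, entries: Iterable[dict]) -> "DoseSchedule":
        """Build from scenario-file entries.

        Each entry: ``{route, compound, amount_ug | rate_ug_per_min,
        start_min, duration_min, [ka_per_h, bioavailability]}``.
        """
        events = []
        for entry in entries:
            events.append(DoseEvent(
                route=entry["route"],
                compound=entry["compound"],
                amount=entry.get("amount_ug"),
                rate=entry.get("rate_ug_per_min"),
                start=entry.get("start_min", 0.0),
                duration=entry.get("duration_min", 0.0),
                ka_per_h=entry.get("ka_per_h"),
                bioavailability=entry.get("bioavailability"),
            ))
        return cls(events)


def input_rate(schedule: DoseSchedule, compound: str, compartment: str, t_min: float) -> float:
    """Continuous dosing rate into ``compartment`` at ``t_min``, µg/min.

    Overlapping events are additive.  Bolus doses do not appear here; they
    are instantaneous state increments (see :func:`bolus_state_increment`).
    """
    if t_min < 0:
        raise DomainError("t must be >= 0")
    if compartment not in ("venous", "lung", "liver"):
        raise DomainError(
            f"no route delivers into compartment {compartment!r} "
            "(expected venous, lung or liver)")
    return sum(
        e.continuous_rate(t_min)
        for e in schedule.events
        if e.compound == compound and e.target_compartment == compartment
    )


def bolus_state_increment(schedule: DoseSchedule, compound: str, t_min: float) -> dict[str, float]:
    """Instantaneous amount increments (µg per compartment) applied at ``t_min``."""
    increments: dict[str, float] = {}
    for e in schedule.bolus_events(compound):
        if e.start == t_min:
            increments[e.target_compartment] = (
                increments.get(e.target_compartment, 0.0) + e.amount)
    return increments
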