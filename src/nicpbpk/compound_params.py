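"""Nicotine/cotinine compound constants and clearance parameter sets.

Clearance values are carried per kilogram of body weight together with an
explicit unit tag, because the published men column is reported in mL/h/kg
while the women and pregnant columns are reported in mL/min/kg.  No silent
unit reconciliation is performed; arithmetic across sets requires explicit
normalization to a common unit.

The women/pregnant clearances are whole-body (systemic) plasma clearances
measured in infusion studies.  How they are mapped onto organ-level
elimination terms (systemic vs. intrinsic reference) is decided in
:mod:`nicpbpk.pbpk_core`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from .errors import DomainError

NIC = "NIC"
COT = "COT"

MW_NIC = 162.23  # g/mol
MW_COT = 176.22  # g/mol
#: mass conversion factor applied when 1 mol of nicotine becomes 1 mol of cotinine
MW_RATIO_COT_NIC = MW_COT / MW_NIC

UNIT_ML_PER_H_PER_KG = "mL/h/kg"
UNIT_ML_PER_MIN_PER_KG = "mL/min/kg"
_VALID_UNITS = (UNIT_ML_PER_H_PER_KG, UNIT_ML_PER_MIN_PER_KG)

#: conversion factors unit -> L/h per kg
_TO_L_PER_H = {
    UNIT_ML_PER_H_PER_KG: 1e-3,
    UNIT_ML_PER_MIN_PER_KG: 60e-3,
}

POPULATIONS = ("men", "women", "pregnant")
CLEARANCE_PATHWAYS = ("hepatic_nic", "renal_nic", "hepatic_cot", "renal_cot")


@dataclass(frozen=True)
class ClearanceSet:
    """Hepatic and renal clearances for one population, per kg body weight."""

    hepatic_nic: float
    renal_nic: float
    hepatic_cot: float
    renal_cot: float
    unit: str
    population: str

    def __post_init__(self) -> None:
        for pathway in CLEARANCE_PATHWAYS:
            value = getattr(self, pathway)
            if value < 0:
                raise DomainError(f"clearance {pathway} must be >= 0, got {value}")
        if self.unit not in _VALID_UNITS:
            raise DomainError(f"unknown clearance unit {self.unit!r}; expected one of {_VALID_UNITS}")

    def normalized(self, unit: str = UNIT_ML_PER_MIN_PER_KG) -> "ClearanceSet":
        """Return an equivalent set expressed in ``unit``."""
        if unit not in _VALID_UNITS:
            raise DomainError(f"unknown clearance unit {unit!r}")
        if unit == self.unit:
            return self
        factor = _TO_L_PER_H[self.unit] / _TO_L_PER_H[unit]
        return replace(
            self,
            hepatic_nic=self.hepatic_nic * factor,
            renal_nic=self.renal_nic * factor,
            hepatic_cot=self.hepatic_cot * factor,
            renal_cot=self.renal_cot * factor,
            unit=unit,
        )

    def to_dict(self) -> dict:
        return {
            "hepatic_nic": self.hepatic_nic,
            "renal_nic": self.renal_nic,
            "hepatic_cot": self.hepatic_cot,
            "renal_cot": self.renal_cot,
            "unit": self.unit,
            "population": self.population,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ClearanceSet":
        return cls(**data)


# Published hepatic/renal clearance columns.  Note the men column is reported
# in mL/h/kg while the female columns are in mL/min/kg; both are exposed
# verbatim with their stated units.
_TABLE1 = {
    "men": ClearanceSet(
        hepatic_nic=277.14, renal_nic=0.6198, hepatic_cot=6.3635, renal_cot=0.0248,
        unit=UNIT_ML_PER_H_PER_KG, population="men",
    ),
    "women": ClearanceSet(
        hepatic_nic=16.2, renal_nic=0.7, hepatic_cot=0.5, renal_cot=0.2,
        unit=UNIT_ML_PER_MIN_PER_KG, population="women",
    ),
    "pregnant": ClearanceSet(
        hepatic_nic=26.6, renal_nic=0.3, hepatic_cot=1.2, renal_cot=0.3,
        unit=UNIT_ML_PER_MIN_PER_KG, population="pregnant",
    ),
}


def table1_defaults(population: str) -> ClearanceSet:
    """Return the published clearance column for ``population``.

    Parameters
    ----------
    population:
        One of ``"men"``, ``"women"``, ``"pregnant"``.
    """
    try:
        return _TABLE1[population]
    except KeyError:
        raise DomainError(
            f"unknown population {population!r}; expected one of {POPULATIONS}"
        ) from None


def to_absolute_clearance(value: float, unit: str, body_weight_kg: float) -> float:
    """Convert a per-kg clearance to an absolute clearance in L/h."""
    if value < 0:
        raise DomainError(f"clearance must be >= 0, got {value}")
    if body_weight_kg <= 0:
        raise DomainError(f"body weight must be > 0, got {body_weight_kg}")
    try:
        factor = _TO_L_PER_H[unit]
    except KeyError:
        raise DomainError(f"unknown clearance unit {unit!r}") from None
    return value * body_weight_kg * factor


def from_absolute_clearance(value_L_per_h: float, unit: str, body_weight_kg: float) -> float:
    """Inverse of :func:`to_absolute_clearance` (L/h back to per-kg units)."""
    if body_weight_kg <= 0:
        raise DomainError(f"body weight must be > 0, got {body_weight_kg}")
    try:
        factor = _TO_L_PER_H[unit]
    except KeyError:
        raise DomainError(f"unknown clearance unit {unit!r}") from None
    return value_L_per_h / (body_weight_kg * factor)


def pregnancy_increase_percent(
    pregnant: ClearanceSet, nonpregnant: ClearanceSet, pathway: str
) -> float:
    """Percent increase of a clearance pathway in pregnancy.

    Returns ``100 * (pregnant / nonpregnant - 1)`` after normalizing both
    sets to a common unit.
    """
    if pathway not in CLEARANCE_PATHWAYS:
        raise DomainError(f"unknown pathway {pathway!r}; expected one of {CLEARANCE_PATHWAYS}")
    preg = pregnant.normalized()
    nonpreg = nonpregnant.normalized()
    base = getattr(nonpreg, pathway)
    if base == 0:
        raise DomainError(f"non-pregnant {pathway} clearance is zero; percent increase undefined")
    return 100.0 * (getattr(preg, pathway) / base - 1.0)


@dataclass(frozen=True)
class CompoundParams:
    """Compound-level constants for nicotine or cotinine."""

    name: str
    molecular_weight: float
    #: molar fraction of hepatically eliminated nicotine converted to
    #: cotinine (CYP2A6 C-oxidation); only defined for nicotine.
    metabolic_fraction_to_cotinine: Optional[float] = None

    def __post_init__(self) -> None:
        if self.name not in (NIC, COT):
            raise DomainError(f"compound name must be NIC or COT, got {self.name!r}")
        if self.molecular_weight <= 0:
            raise DomainError("molecular weight must be > 0")
        f = self.metabolic_fraction_to_cotinine
        if self.name == COT and f is not None:
            raise DomainError("metabolic_fraction_to_cotinine is defined only for NIC")
        if f is not None and not (0.0 <= f <= 1.0):
            raise DomainError(f"metabolic_fraction_to_cotinine must be in [0,1], got {f}")


NICOTINE = CompoundParams(NIC, MW_NIC, metabolic_fraction_to_cotinine=0.8)
COTININE = CompoundParams(COT, MW_COT)
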