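"""Compartmental anatomy and its body-weight / gestational-age scaling.

The maternal body is represented by arterial and venous blood plus ten
perfused tissue compartments (lung, brain, liver, kidney, vessel-rich
"rapid" group, muscle, fat, mammary gland, uterus and — during pregnancy —
placenta).  The fetus is a four-compartment sub-model (blood, liver, brain,
rest of body) exchanging with the mother exclusively through the placenta.

Scaling model
-------------
A physiology is built from a configuration table holding baseline volumes,
blood flows and tissue:blood partition coefficients for a reference
non-pregnant adult (70 kg), together with gestational growth functions.
For a subject of body weight ``BW`` at gestational week ``w``:

* the pre-pregnancy equivalent weight is ``BW - weight_gain(w)``;
* baseline volumes and flows scale linearly with the pre-pregnancy weight
  relative to the reference weight;
* gestational increments (uterus, placenta, mammary, blood expansion,
  extracellular water, organ blood-flow increases) are added on top.

Growth functions are supplied either as polynomial coefficients or as
piecewise-linear point tables keyed by week; both must be non-negative and
non-decreasing over weeks 0-40 and vanish at week 0.

Internal units: volumes L, flows L/h, time h, body weight kg.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError, DomainError

WEEKS_PER_MONTH = 4.348

MATERNAL_TISSUES = (
    "lung", "brain", "liver", "kidney", "rapid",
    "muscle", "fat", "mammary", "uterus", "placenta",
)
#: tissues perfused from the arterial pool (lung is in series, fed by venous return)
PERFUSED_TISSUES = tuple(t for t in MATERNAL_TISSUES if t != "lung")
FETAL_TISSUES = ("liver", "brain", "rest")

_FLOW_BALANCE_RTOL = 1e-9


def months_to_weeks(months: float) -> float:
    """Convenience conversion for gestational age given in months."""
    if months < 0:
        raise DomainError(f"gestation months must be >= 0, got {months}")
    return months * WEEKS_PER_MONTH


@dataclass(frozen=True)
class TissueSpec:
    """Volume, perfusion and partitioning of one compartment."""

    name: str
    volume: float          # L
    blood_flow: float      # L/h
    partition_nic: float   # tissue:blood, dimensionless
    partition_cot: float

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise DomainError(f"tissue {self.name}: volume must be > 0, got {self.volume}")
        if self.blood_flow < 0:
            raise DomainError(f"tissue {self.name}: blood flow must be >= 0")
        if self.partition_nic <= 0 or self.partition_cot <= 0:
            raise DomainError(f"tissue {self.name}: partition coefficients must be > 0")

    def partition(self, compound: str) -> float:
        return self.partition_nic if compound == "NIC" else self.partition_cot


@dataclass(frozen=True)
class MaternalPhysiology:
    body_weight: float
    gestation_week: float
    arterial_volume: float
    venous_volume: float
    tissues: tuple[TissueSpec, ...]

    def __post_init__(self) -> None:
        names = [t.name for t in self.tissues]
        if len(set(names)) != len(names):
            raise ConfigurationError("tissues: duplicate compartment names")
        qsum = sum(t.blood_flow for t in self.tissues if t.name != "lung")
        co = self.cardiac_output
        if co <= 0:
            raise ConfigurationError("tissues: total perfusion must be > 0")
        if abs(qsum - co) > _FLOW_BALANCE_RTOL * co:
            raise ConfigurationError("tissues: perfused flows do not sum to cardiac output")
        total_volume = self.arterial_volume + self.venous_volume + sum(t.volume for t in self.tissues)
        if total_volume > self.body_weight * 1.0:
            raise ConfigurationError(
                f"tissues: total volume {total_volume:.2f} L exceeds body weight "
                f"{self.body_weight} kg at 1 L/kg"
            )

    @property
    def cardiac_output(self) -> float:
        """Total blood flow L/h (carried by the lung, in series)."""
        return self.tissue("lung").blood_flow

    def tissue(self, name: str) -> TissueSpec:
        for t in self.tissues:
            if t.name == name:
                return t
        raise DomainError(f"no tissue named {name!r}")

    @property
    def is_pregnant(self) -> bool:
        return self.gestation_week > 0

    def to_dict(self) -> dict:
        return {
            "body_weight": self.body_weight,
            "gestation_week": self.gestation_week,
            "arterial_volume": self.arterial_volume,
            "venous_volume": self.venous_volume,
            "tissues": [
                {
                    "name": t.name, "volume": t.volume, "blood_flow": t.blood_flow,
                    "partition_nic": t.partition_nic, "partition_cot": t.partition_cot,
                }
                for t in self.tissues
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "MaternalPhysiology":
        tissues = tuple(TissueSpec(**t) for t in data["tissues"])
        return cls(
            body_weight=data["body_weight"],
            gestation_week=data["gestation_week"],
            arterial_volume=data["arterial_volume"],
            venous_volume=data["venous_volume"],
            tissues=tissues,
        )


@dataclass(frozen=True)
class FetalPhysiology:
    body_weight: float
    blood_volume: float
    tissues: tuple[TissueSpec, ...]
    hepatic_clearance_fraction: float = 0.20

    def __post_init__(self) -> None:
        if self.body_weight <= 0 or self.blood_volume <= 0:
            raise DomainError("fetal body weight and blood volume must be > 0")
        if not (0.0 <= self.hepatic_clearance_fraction <= 1.0):
            raise DomainError("hepatic_clearance_fraction must be in [0,1]")

    def tissue(self, name: str) -> TissueSpec:
        for t in self.tissues:
            if t.name == name:
                return t
        raise DomainError(f"no fetal tissue named {name!r}")

    def to_dict(self) -> dict:
        return {
            "body_weight": self.body_weight,
            "blood_volume": self.blood_volume,
            "hepatic_clearance_fraction": self.hepatic_clearance_fraction,
            "tissues": [
                {
                    "name": t.name, "volume": t.volume, "blood_flow": t.blood_flow,
                    "partition_nic": t.partition_nic, "partition_cot": t.partition_cot,
                }
                for t in self.tissues
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "FetalPhysiology":
        return cls(
            body_weight=data["body_weight"],
            blood_volume=data["blood_volume"],
            hepatic_clearance_fraction=data["hepatic_clearance_fraction"],
            tissues=tuple(TissueSpec(**t) for t in data["tissues"]),
        )


# ---------------------------------------------------------------------------
# growth functions

def _make_growth(spec, field: str) -> Callable[[float], float]:
    """Compile a growth spec ({'poly': [...]} or {'points': [[w, v], ...]})."""
    if not isinstance(spec, Mapping) or not ({"poly", "points"} & set(spec)):
        raise ConfigurationError(f"{field}: expected a mapping with a 'poly' or 'points' key")
    if "poly" in spec:
        coeffs = list(spec["poly"])
        if not coeffs or not all(isinstance(c, (int, float)) for c in coeffs):
            raise ConfigurationError(f"{field}.poly: expected a non-empty list of numbers")

        def fn(w: float, _c=np.asarray(coeffs, dtype=float)) -> float:
            return float(np.polyval(_c[::-1], w))
    else:
        pts = spec["points"]
        try:
            ws = np.asarray([p[0] for p in pts], dtype=float)
            vs = np.asarray([p[1] for p in pts], dtype=float)
        except (TypeError, IndexError):
            raise ConfigurationError(f"{field}.points: expected a list of [week, value] pairs") from None
        if len(ws) < 2 or np.any(np.diff(ws) <= 0):
            raise ConfigurationError(f"{field}.points: weeks must be strictly increasing (>= 2 points)")

        def fn(w: float, _ws=ws, _vs=vs) -> float:
            return float(np.interp(w, _ws, _vs))

    grid = np.linspace(0.0, 40.0, 161)
    vals = np.array([fn(w) for w in grid])
    if np.any(vals < -1e-12):
        raise ConfigurationError(f"{field}: growth function must be non-negative on [0, 40]")
    if np.any(np.diff(vals) < -1e-12):
        raise ConfigurationError(f"{field}: growth function must be non-decreasing on [0, 40]")
    return fn


class GestationModel:
    """Gestational growth of maternal body weight, blood, tissues and fetus."""

    def __init__(self, config: Mapping) -> None:
        gest = config.get("gestation", {})
        self.weight_gain = _make_growth(
            gest.get("weight_gain", {"poly": [0.0]}), "gestation.weight_gain")
        if abs(self.weight_gain(0.0)) > 1e-12:
            raise ConfigurationError("gestation.weight_gain: must be 0 at week 0")

        self.blood_growth = {}
        for pool, spec in gest.get("blood_growth", {}).items():
            if pool not in ("arterial", "venous"):
                raise ConfigurationError(f"gestation.blood_growth.{pool}: unknown blood pool")
            self.blood_growth[pool] = _make_growth(spec, f"gestation.blood_growth.{pool}")

        self.volume_growth: dict[str, Callable[[float], float]] = {}
        self.flow_growth: dict[str, Callable[[float], float]] = {}
        for tissue, spec in gest.get("tissue_growth", {}).items():
            if tissue not in MATERNAL_TISSUES:
                raise ConfigurationError(f"gestation.tissue_growth.{tissue}: unknown tissue")
            if "volume" in spec:
                self.volume_growth[tissue] = _make_growth(
                    spec["volume"], f"gestation.tissue_growth.{tissue}.volume")
            if "flow" in spec:
                self.flow_growth[tissue] = _make_growth(
                    spec["flow"], f"gestation.tissue_growth.{tissue}.flow")

    def volume_increment(self, tissue: str, week: float) -> float:
        fn = self.volume_growth.get(tissue)
        return fn(week) if fn else 0.0

    def flow_increment(self, tissue: str, week: float) -> float:
        fn = self.flow_growth.get(tissue)
        return fn(week) if fn else 0.0


# ---------------------------------------------------------------------------
# configuration handling

_TISSUE_FIELDS = ("volume_L", "flow_L_per_h", "partition_nic", "partition_cot")


def default_config_path() -> str:
    """Path of the packaged default physiology configuration."""
    return str(importlib.resources.files("nicpbpk.data") / "physiology_default.yaml")


def load_config(path: Optional[str] = None) -> dict:
    """Load and validate a physiology configuration (YAML or JSON-as-YAML)."""
    if path is None:
        path = default_config_path()
    with open(path) as fh:
        config = yaml.safe_load(fh)
    validate_config(config)
    return config


def validate_config(config: Mapping) -> None:
    """Schema-validate a physiology configuration, naming offending fields."""
    if not isinstance(config, Mapping):
        raise ConfigurationError("configuration root must be a mapping")
    for key in ("reference", "blood", "tissues", "fetus"):
        if key not in config:
            raise ConfigurationError(f"{key}: missing required section")
    ref = config["reference"]
    if not isinstance(ref.get("body_weight_kg"), (int, float)) or ref["body_weight_kg"] <= 0:
        raise ConfigurationError("reference.body_weight_kg: must be a positive number")
    blood = config["blood"]
    for pool in ("arterial_L", "venous_L"):
        if not isinstance(blood.get(pool), (int, float)) or blood[pool] <= 0:
            raise ConfigurationError(f"blood.{pool}: must be a positive number")
    tissues = config["tissues"]
    for name in MATERNAL_TISSUES:
        if name not in tissues:
            raise ConfigurationError(f"tissues.{name}: missing compartment")
        entry = tissues[name]
        for field in _TISSUE_FIELDS:
            value = entry.get(field)
            if field == "flow_L_per_h" and name == "lung":
                if value is not None:
                    raise ConfigurationError(
                        "tissues.lung.flow_L_per_h: must be null (lung carries cardiac output)")
                continue
            if not isinstance(value, (int, float)) or value < 0:
                raise ConfigurationError(f"tissues.{name}.{field}: must be a non-negative number")
        if name not in ("placenta",) and entry["volume_L"] <= 0:
            raise ConfigurationError(f"tissues.{name}.volume_L: must be > 0")
        if entry["partition_nic"] <= 0 or entry["partition_cot"] <= 0:
            raise ConfigurationError(f"tissues.{name}: partition coefficients must be > 0")
    fetus = config["fetus"]
    for field in ("body_weight", "blood_volume_frac", "tissues", "hepatic_clearance_fraction"):
        if field not in fetus:
            raise ConfigurationError(f"fetus.{field}: missing required field")
    if not (0.0 <= fetus["hepatic_clearance_fraction"] <= 1.0):
        raise ConfigurationError("fetus.hepatic_clearance_fraction: must be in [0,1]")
    for name in FETAL_TISSUES:
        if name not in fetus["tissues"]:
            raise ConfigurationError(f"fetus.tissues.{name}: missing compartment")
        entry = fetus["tissues"][name]
        for field in ("volume_frac", "flow_L_per_h_per_kg", "partition_nic", "partition_cot"):
            if not isinstance(entry.get(field), (int, float)) or entry[field] <= 0:
                raise ConfigurationError(f"fetus.tissues.{name}.{field}: must be a positive number")
    # growth functions are validated on compilation
    GestationModel(config)


def weight_from_gestation(
    pre_pregnancy_weight: float, gestation_week: float, config: Optional[Mapping] = None
) -> float:
    """Maternal body weight at ``gestation_week`` given the pre-pregnancy weight."""
    if pre_pregnancy_weight <= 0:
        raise DomainError(f"pre-pregnancy weight must be > 0, got {pre_pregnancy_weight}")
    if not (0.0 <= gestation_week <= 40.0):
        raise DomainError(f"gestation week must be in [0, 40], got {gestation_week}")
    if config is None:
        config = load_config()
    return pre_pregnancy_weight + GestationModel(config).weight_gain(gestation_week)


def build_physiology(
    gestation_week: float,
    body_weight: float,
    config: Optional[Mapping] = None,
) -> tuple[MaternalPhysiology, Optional[FetalPhysiology]]:
    """Construct maternal (and, if pregnant, fetal) physiology.

    ``body_weight`` is the actual weight at ``gestation_week`` (the
    pre-pregnancy equivalent used for baseline scaling is recovered by
    subtracting the configured gestational weight gain).  Returns
    ``(maternal, fetal)``; ``fetal`` is ``None`` for ``gestation_week == 0``,
    in which case the placenta compartment is excluded from the physiology.
    """
    if not (0.0 <= gestation_week <= 40.0):
        raise DomainError(f"gestation week must be in [0, 40], got {gestation_week}")
    if body_weight <= 0:
        raise DomainError(f"body weight must be > 0, got {body_weight}")
    if config is None:
        config = load_config()
    else:
        validate_config(config)

    gest = GestationModel(config)
    ref_bw = config["reference"]["body_weight_kg"]
    pre_bw = body_weight - gest.weight_gain(gestation_week)
    if pre_bw <= 0:
        raise DomainError(
            f"body weight {body_weight} kg is below the configured gestational "
            f"weight gain at week {gestation_week}")
    scale = pre_bw / ref_bw

    pregnant = gestation_week > 0
    tissues = []
    perfused_total = 0.0
    for name in MATERNAL_TISSUES:
        if name == "lung":
            continue
        entry = config["tissues"][name]
        volume = entry["volume_L"] * scale + gest.volume_increment(name, gestation_week)
        flow = entry["flow_L_per_h"] * scale + gest.flow_increment(name, gestation_week)
        if name == "placenta" and not pregnant:
            continue  # excluded from the non-pregnant state entirely
        if volume <= 0:
            raise ConfigurationError(
                f"tissues.{name}: volume is not positive at week {gestation_week}; "
                "provide a gestational volume growth entry")
        tissues.append(TissueSpec(
            name=name, volume=volume, blood_flow=flow,
            partition_nic=entry["partition_nic"], partition_cot=entry["partition_cot"],
        ))
        perfused_total += flow

    lung_entry = config["tissues"]["lung"]
    tissues.insert(0, TissueSpec(
        name="lung",
        volume=lung_entry["volume_L"] * scale,
        blood_flow=perfused_total,  # lung is in series with the whole circulation
        partition_nic=lung_entry["partition_nic"],
        partition_cot=lung_entry["partition_cot"],
    ))

    blood = config["blood"]
    arterial = blood["arterial_L"] * scale
    venous = blood["venous_L"] * scale
    if pregnant:
        for pool, fn in gest.blood_growth.items():
            if pool == "arterial":
                arterial += fn(gestation_week)
            else:
                venous += fn(gestation_week)

    maternal = MaternalPhysiology(
        body_weight=body_weight,
        gestation_week=gestation_week,
        arterial_volume=arterial,
        venous_volume=venous,
        tissues=tuple(tissues),
    )

    fetal = None
    if pregnant:
        fconf = config["fetus"]
        fetal_bw = _make_growth(fconf["body_weight"], "fetus.body_weight")(gestation_week)
        if fetal_bw <= 0:
            raise ConfigurationError(
                f"fetus.body_weight: not positive at week {gestation_week}")
        ftissues = tuple(
            TissueSpec(
                name=name,
                volume=fconf["tissues"][name]["volume_frac"] * fetal_bw,
                blood_flow=fconf["tissues"][name]["flow_L_per_h_per_kg"] * fetal_bw,
                partition_nic=fconf["tissues"][name]["partition_nic"],
                partition_cot=fconf["tissues"][name]["partition_cot"],
            )
            for name in FETAL_TISSUES
        )
        fetal = FetalPhysiology(
            body_weight=fetal_bw,
            blood_volume=fconf["blood_volume_frac"] * fetal_bw,
            tissues=ftissues,
            hepatic_clearance_fraction=fconf["hepatic_clearance_fraction"],
        )

    return maternal, fetal
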