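"""Named simulation scenarios and tabular/JSON output writers.

The built-in scenarios encode the regimens used to exercise the model:
a 60-min 10 µg/min intravenous nicotine infusion and a 30-min 0.67 mg/min
cotinine infusion in a 70-kg non-pregnant adult, the same nicotine
infusion in a week-30 pregnant subject (73 kg), and a single 1 µg/kg
intravenous nicotine bolus in the pregnant subject for brain and fetal
kinetics.  (The cotinine infusion rate is reported inconsistently in the
source material — 0.67 vs 0.65 mg/min; the scenario uses 0.67.)
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import yaml

from .compound_params import COT, NIC, table1_defaults
from .dosing import DoseEvent, DoseSchedule
from .errors import DomainError
from .pbpk_core import ModelOptions, PBPKModel, PlacentalTransfer
from .physiology import build_physiology, load_config
from .pk_metrics import SimulationResult, percent_lower, summarize

METRICS_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class Scenario:
    id: str
    population: str                    # men | women | pregnant
    body_weight: float                 # kg
    schedule: DoseSchedule
    horizon_h: float
    gestation_week: float = 0.0
    output_dt_min: float = 0.5
    #: (compartment, compound) trajectories written to the time-course CSV
    outputs: tuple[tuple[str, str], ...] = (("venous", NIC), ("venous", COT))
    urine_time_min: Optional[float] = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.population not in ("men", "women", "pregnant"):
            raise DomainError(f"unknown population {self.population!r}")
        if self.population == "pregnant" and not (0 < self.gestation_week <= 40):
            raise DomainError("pregnant scenarios require gestation_week in (0, 40]")
        if self.population != "pregnant" and self.gestation_week != 0:
            raise DomainError("non-pregnant scenarios must have gestation_week 0")


def _builtin_scenarios() -> dict[str, Scenario]:
    nic_infusion = DoseSchedule([DoseEvent(
        route="iv_infusion", compound=NIC, rate=10.0, start=0.0, duration=60.0)])
    scenarios = [
        Scenario(
            id="nic_infusion_10ug_60min",
            population="women", body_weight=70.0,
            schedule=nic_infusion, horizon_h=72.0,
            urine_time_min=300.0,
            outputs=(("venous", NIC), ("venous", COT), ("brain", NIC)),
            description="IV nicotine 10 µg/min for 60 min, 70-kg non-pregnant adult "
                        "(baseline validation regimen)",
        ),
        Scenario(
            id="men_infusion_10ug_60min",
            population="men", body_weight=70.0,
            schedule=nic_infusion, horizon_h=72.0,
            urine_time_min=300.0,
            description="Same infusion with the adult-men clearance column "
                        "(baseline-calibration mirror)",
        ),
        Scenario(
            id="cot_infusion_0p67mg_30min",
            population="women", body_weight=70.0,
            schedule=DoseSchedule([DoseEvent(
                route="iv_infusion", compound=COT, rate=670.0, start=0.0, duration=30.0)]),
            horizon_h=72.0,
            outputs=(("venous", COT),),
            description="IV cotinine 0.67 mg/min for 30 min, 70-kg non-pregnant adult",
        ),
        Scenario(
            id="preg_infusion_10ug_60min",
            population="pregnant", gestation_week=30.0, body_weight=73.0,
            schedule=nic_infusion, horizon_h=72.0,
            urine_time_min=300.0,
            outputs=(("venous", NIC), ("venous", COT),
                     ("fetal_blood", NIC), ("fetal_blood", COT)),
            description="Same nicotine infusion, week-30 pregnant subject (73 kg)",
        ),
        Scenario(
            id="nic_bolus_1ug_kg_week30",
            population="pregnant", gestation_week=30.0, body_weight=73.0,
            schedule=DoseSchedule([DoseEvent(
                route="iv_bolus", compound=NIC, amount=73.0, start=0.0)]),
            horizon_h=8.0, output_dt_min=0.1,
            outputs=(("venous", NIC), ("venous", COT), ("brain", NIC),
                     ("fetal_blood", NIC), ("fetal_blood", COT)),
            description="Single IV nicotine bolus 1 µg/kg, week-30 pregnant subject "
                        "(brain uptake and fetal/maternal kinetics)",
        ),
    ]
    return {s.id: s for s in scenarios}


BUILTIN_SCENARIOS = _builtin_scenarios()


def list_scenarios() -> list[str]:
    return sorted(BUILTIN_SCENARIOS)


def scenario_from_file(path: str) -> Scenario:
    """Load a scenario document (YAML/JSON) from disk."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    try:
        return Scenario(
            id=data["id"],
            population=data["population"],
            gestation_week=data.get("gestation_week", 0.0),
            body_weight=data["body_weight_kg"],
            schedule=DoseSchedule.from_dicts(data["schedule"]),
            horizon_h=data["horizon_h"],
            output_dt_min=data.get("output_dt_min", 0.5),
            outputs=tuple((c, x) for c, x in data.get(
                "outputs", [["venous", NIC], ["venous", COT]])),
            urine_time_min=data.get("urine_time_min"),
            description=data.get("description", ""),
        )
    except KeyError as exc:
        raise DomainError(f"scenario file {path}: missing field {exc}") from None


def get_scenario(scenario: "str | Scenario") -> Scenario:
    if isinstance(scenario, Scenario):
        return scenario
    if scenario in BUILTIN_SCENARIOS:
        return BUILTIN_SCENARIOS[scenario]
    if Path(scenario).exists():
        return scenario_from_file(scenario)
    raise DomainError(
        f"unknown scenario {scenario!r}; available ids: {', '.join(list_scenarios())}")


def build_model(
    scenario: Scenario,
    config: Optional[Mapping] = None,
    placenta: Optional[PlacentalTransfer] = None,
    options: ModelOptions = ModelOptions(),
) -> PBPKModel:
    """Assemble the PBPK model for a scenario.

    The clearance column follows the scenario population; men and women
    share the female anatomy template (only the clearance column differs).
    """
    if config is None:
        config = load_config()
    maternal, fetal = build_physiology(
        scenario.gestation_week, scenario.body_weight, config)
    if maternal.is_pregnant and placenta is None:
        placenta = PlacentalTransfer.from_dict(config["placental_transfer"])
    return PBPKModel(
        maternal, fetal, table1_defaults(scenario.population),
        placenta=placenta if maternal.is_pregnant else None,
        options=options,
    )


def _parameter_hash(scenario: Scenario, model: PBPKModel) -> str:
    payload = {
        "scenario": scenario.id,
        "population": scenario.population,
        "gestation_week": scenario.gestation_week,
        "body_weight": scenario.body_weight,
        "schedule": [
            {"route": e.route, "compound": e.compound, "amount": e.amount,
             "rate": e.rate, "start": e.start, "duration": e.duration}
            for e in scenario.schedule.events],
        "physiology": model.maternal.to_dict(),
        "fetal": model.fetal.to_dict() if model.fetal else None,
        "clearances": model.clearances.to_dict(),
        "placenta": model.placenta.to_dict() if model.placenta else None,
        "options": {"clearance_reference": model.options.clearance_reference,
                    "rtol": model.options.rtol, "atol": model.options.atol},
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()


def run_scenario(
    scenario: "str | Scenario",
    config: Optional[Mapping] = None,
    out_dir: Optional[str] = None,
    placenta: Optional[PlacentalTransfer] = None,
    options: ModelOptions = ModelOptions(),
) -> tuple[SimulationResult, dict]:
    """Simulate a scenario; optionally write time-course CSV + metrics JSON.

    Deterministic: identical scenario and configuration produce
    byte-identical output files.
    """
    scenario = get_scenario(scenario)
    model = build_model(scenario, config=config, placenta=placenta, options=options)
    result = model.simulate(
        scenario.schedule, scenario.horizon_h,
        output_dt_min=scenario.output_dt_min,
        metadata={"scenario": scenario.id,
                  "parameter_hash": _parameter_hash(scenario, model)},
    )
    metrics = {
        "schema_version": METRICS_SCHEMA_VERSION,
        "scenario": scenario.id,
        "description": scenario.description,
        "metadata": result.metadata,
        "metrics": [
            summarize(result, compartment, compound,
                      urine_time_min=scenario.urine_time_min).to_dict()
            for compartment, compound in scenario.outputs
        ],
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame = result.to_frame(
            compartments=sorted({c for c, _ in scenario.outputs}))
        frame.to_csv(out / f"{scenario.id}_timecourse.csv",
                     index=False, float_format="%.10g")
        with open(out / f"{scenario.id}_metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return result, metrics


def compare_scenarios(
    id_a: "str | Scenario",
    id_b: "str | Scenario",
    t_min: float,
    config: Optional[Mapping] = None,
) -> dict:
    """Percent by which scenario B plasma levels are below scenario A at ``t_min``.

    Both scenarios must share the same dose schedule.
    """
    a, b = get_scenario(id_a), get_scenario(id_b)
    if a.schedule != b.schedule:
        raise DomainError(
            f"scenarios {a.id!r} and {b.id!r} have different dose schedules; "
            "percent comparison requires identical dosing")
    result_a, _ = run_scenario(a, config=config)
    result_b, _ = run_scenario(b, config=config)
    table = {"t_min": t_min, "reference": a.id, "test": b.id, "percent_lower": {}}
    for compound in (NIC, COT):
        table["percent_lower"][compound] = percent_lower(
            result_a, result_b, "plasma", compound, t_min)
    return table
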