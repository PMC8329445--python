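# nicpbpk

A physiologically based pharmacokinetic (PBPK) simulator for **nicotine
(NIC) and its principal metabolite cotinine (COT)** in non-pregnant adults
and in pregnancy, including placental transfer and fetal disposition.

Nicotine clearance rises substantially during pregnancy (hepatic CYP2A6
C-oxidation is induced and renal handling changes), which matters for
interpreting cotinine biomonitoring in pregnant smokers and for dosing
nicotine replacement therapy. Direct fetal measurements are essentially
unavailable outside delivery, so a mechanistic maternal–placental–fetal
model is the practical way to ask how much nicotine the fetal circulation
and fetal brain actually see. This package is aimed at pharmacokineticists
and public-health modellers who want a small, transparent, fully scriptable
implementation of that model.

## Model

Both compounds are simulated simultaneously on a flow-limited compartment
system. Every tissue `i` with volume `V_i`, blood flow `Q_i` and
tissue:blood partition coefficient `P_i` obeys

    dA_i/dt = Q_i (C_art − C_i / P_i),        C_i = A_i / V_i

with the lung in series carrying the cardiac output `Q_co`, and arterial /
venous blood pools closing the loop. Elimination is linear:

* **liver** — intrinsic clearance acting on liver outflow,
  `− CL_int,h · C_liv / P_liv`; a fixed molar fraction `f_met = 0.8` of
  hepatically eliminated nicotine re-enters the cotinine system as newly
  formed metabolite (mass-scaled by `MW_COT / MW_NIC`);
* **kidney** — `− CL_int,r · C_kid / P_kid`, accumulated in a urine state.

The published hepatic/renal clearances (men, women, pregnant women columns,
exposed verbatim with their units by `table1_defaults`) are whole-body
*systemic* clearances; the model back-computes the intrinsic organ
clearance through the well-stirred relation `CL_int = Q·CL/(Q − CL)` so the
simulated systemic clearance reproduces the measured value.

In pregnancy (gestational week `w > 0`) the mammary gland, uterus and
placenta grow according to configurable gestation tables, blood volume and
organ perfusions expand, and a four-compartment fetus (blood, liver, brain,
rest) exchanges with the placenta through directional transfer clearances

    placenta:     … − k_mf · C_pl / P_pl + k_fm · C_fb
    fetal blood:  … + k_mf · C_pl / P_pl − k_fm · C_fb

whose influx/efflux asymmetry is calibrated (`calibrate_placenta`) so the
quasi-steady fetal/maternal plasma nicotine ratio is 1.15 while the
cotinine ratio stays below 1. The fetal liver clears both compounds at 20%
of the maternal per-kg capacity. The pregnant configuration integrates 32
dynamic ODEs (2 compounds × 16 compartments) plus bookkeeping accumulators
for urine, cumulative hepatic elimination and cotinine formation, so mass
balance is auditable at every output time.

Dosing routes: intravenous bolus and infusion (venous blood), cigarette
smoking as a short zero-order lung input, and oral dosing as first-order
portal absorption (`ka`, `F` required, handled analytically).

## Worked example

```python
from nicpbpk import run_scenario

result, metrics = run_scenario("nic_infusion_10ug_60min", out_dir="out")
for m in metrics["metrics"]:
    if m["compartment"] == "venous":
        print(m["compound"], round(m["cmax_ug_per_L"], 2), "µg/L at",
              m["tmax_min"], "min; t½ =", round(m["half_life_h"], 2),
              "h; urine(5 h) =", round(m["urine_cumulative_ug"], 1), "µg")
```

prints, with the shipped default physiology:

```
NIC 6.25 µg/L at 60.0 min; t½ = 3.53 h; urine(5 h) = 23.3 µg
COT 5.89 µg/L at 63.5 min; t½ = 18.7 h; urine(5 h) = 19.9 µg
```

i.e. after a 60-min 10 µg/min intravenous nicotine infusion into a 70-kg
adult, plasma nicotine peaks at the end of the infusion and decays with a
terminal half-life of ~3.5 h, while the cotinine formed from it persists
with a ~19 h half-life; 23 µg of unchanged nicotine and 20 µg of cotinine
have reached urine five hours after the start.

The same infusion in the week-30 pregnant model shows the accelerated
pregnancy clearance:

```bash
$ nicpbpk compare nic_infusion_10ug_60min preg_infusion_10ug_60min --t-min 150
{
  "percent_lower": {"COT": 18.7, "NIC": 58.2},
  ...
}
```

— pregnant plasma nicotine is ~58% and cotinine ~19% below the
non-pregnant curves 150 min after the start of dosing.

Other built-in scenarios (`nicpbpk list-scenarios`): the 0.67 mg/min × 30
min cotinine infusion, the adult-men clearance mirror, and a 1 µg/kg IV
nicotine bolus in the week-30 model for brain uptake (peak within 2 min)
and fetal kinetics.

## Layout

| module | contents |
| --- | --- |
| `nicpbpk.physiology` | anatomy, body-weight and gestational scaling, config schema |
| `nicpbpk.compound_params` | molecular constants, published clearance columns, unit handling |
| `nicpbpk.dosing` | dose events/schedules for the three intake routes |
| `nicpbpk.pbpk_core` | ODE assembly, simulation, mass-balance audit, placental calibration |
| `nicpbpk.pk_metrics` | Cmax/Tmax, terminal half-life, AUC, urine, percent differences |
| `nicpbpk.scenarios` / `nicpbpk.cli` | named regimens, CSV/JSON writers, `nicpbpk` command |

The default physiology ships as editable YAML
(`src/nicpbpk/data/physiology_default.yaml`); see `docs/methods.md` for the
model assumptions, parameter provenance and known limitations.
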