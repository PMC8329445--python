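# Methods

## Model structure and assumptions

The simulator couples two linear compartmental systems — one for nicotine,
one for cotinine — over a shared anatomy. Disposition is **flow-limited**:
each tissue is a well-mixed pool that equilibrates instantaneously with its
perfusing blood, so the venous outflow concentration is `C_i / P_i` with
`P_i` the tissue:blood partition coefficient. The lung sits in series with
the circulation and carries the whole cardiac output; arterial and venous
blood are explicit pools. Consequences of these assumptions:

* kinetics are linear in dose (no saturable metabolism or binding), so
  trajectories scale exactly with the administered amount;
* "plasma" is identified with venous blood concentration (blood:plasma
  partitioning is absorbed into the partition coefficients);
* membrane-limited uptake is not represented; the only transfer resistance
  in the model is the placental influx/efflux step.

The maternal body comprises arterial and venous blood plus lung, brain,
liver, kidney, a vessel-rich "rapid" group, a muscle group (skeletal muscle
lumped with skin), fat, mammary gland, uterus and — during pregnancy —
placenta. The fetus is a four-compartment sub-model (blood, liver, brain,
rest of body) reached only through the placenta. The pregnant state vector
holds 32 dynamic equations (2 compounds × 16 compartments); urine,
cumulative hepatic elimination and cumulative cotinine formation are
integrated alongside as bookkeeping states so that the mass balance can be
audited at every output time (`PBPKModel.mass_balance_residual`, which
closes to ~1e-15 relative under default tolerances).

## Elimination and the clearance reference

Hepatic and renal elimination are linear intrinsic clearances acting on the
eliminating organ's outflow concentration (`−CL_int · C/P`). The shipped
clearance sets are per-kg *systemic* (whole-body) plasma clearances as
measured in infusion studies; applying such values directly as intrinsic
terms would cap the effective clearance at organ blood flow and
systematically under-predict elimination — the pregnant hepatic nicotine
clearance (26.6 mL/min/kg ≈ 116 L/h at 73 kg) approaches hepatic blood
flow, where the well-stirred model is strongly nonlinear. The model
therefore inverts the well-stirred relation,

    CL_int = Q · CL_sys / (Q − CL_sys),

per eliminating organ at build time, so that the simulated systemic
clearance equals the configured value (verified in the test suite via
dose/AUC). A configuration whose systemic clearance exceeds 95% of the
organ's blood flow is rejected with a clear message rather than silently
capped. `ModelOptions(clearance_reference="intrinsic")` applies the values
verbatim instead, for users whose parameter sets are genuinely intrinsic.

## Nicotine → cotinine coupling

A fixed molar fraction `f_met` (default 0.8, the CYP2A6 C-oxidation share)
of every microgram-equivalent of hepatically eliminated nicotine appears
as newly formed cotinine in the liver of the same body (maternal or
fetal). States are tracked in mass units, so the formation flux carries
the molecular-weight ratio `MW_COT / MW_NIC = 176.22 / 162.23 ≈ 1.086`;
this scaling can be disabled (`mw_scaling=False`) for molar bookkeeping.
The remaining 20% goes to the hepatic sink (glucuronides and other
oxidative products are not tracked as species).

Because the pregnant liver clears nicotine ~1.7× faster, it also *forms*
cotinine faster: during roughly the first hour after the start of dosing
the pregnant plasma cotinine transiently exceeds the non-pregnant curve
before the higher pregnant cotinine clearance and larger distribution
volume pull it below. This early crossover is a structural property of any
parameterization with these clearance ratios, not a tuning artifact; the
ordering tests therefore assert the pregnant-below-non-pregnant relation
for nicotine at all times and for cotinine beyond a 60-min formation
transient.

## Pregnancy scaling

`build_physiology(week, weight, config)` scales the reference 70-kg
baseline linearly with the pre-pregnancy-equivalent weight
(`weight − weight_gain(week)`) and adds gestational increments on top.
Growth functions are additive increments per gestational week, configured
as polynomials or piecewise-linear tables, validated to be non-negative and
non-decreasing on weeks 0–40 and zero at week 0. Shipped choices
(editable, marked in the config as defaults not asserted by any single
measured subject):

* weight gain `0.0075·w²` kg (≈ 12 kg at term);
* blood volume +1.5 L at week 30 (venous-weighted), uterus → 2.3 L,
  placenta → 0.5 L, mammary +0.7 L, fat +2.3 L, lean (muscle+skin) +5 L;
* perfusion: liver +45, kidney +20, muscle+skin +60, vessel-rich +24,
  uteroplacental +39 L/h at week 30. The large muscle+skin term carries
  the thermoregulatory skin-flow rise of pregnancy and is what lets the
  faster pregnant clearance actually express itself in plasma within the
  first hours (with unchanged perfusion the extra clearance is masked by
  redistribution from slowly equilibrating tissue).
* fetus: weight `3.5·(w/40)³` kg; blood 10%, brain 13%, liver 4%, rest 60%
  of fetal weight; perfusion 20 L/h per kg across fetal tissues; hepatic
  clearance 20% of the maternal per-kg value; no fetal renal excretion
  (amniotic recycling is not modelled), so fetal elimination is hepatic
  only.

At week 0 the placenta and fetus are removed from the state vector
entirely rather than simulated at zero volume, which keeps the system
non-singular; mammary and uterus remain at their small baselines.

## Partition coefficients and their calibration

No tissue-by-tissue partition measurements exist for this exact model
lineage, so the shipped coefficients are plausible literature-range values
calibrated **once** so that the default configuration reproduces the
reported whole-model outputs (plasma half-lives ~3 h / ~16 h, 5-h urinary
amounts, the pregnant percent differences at 150 min, brain peak ≤ 2 min).
The structurally meaningful choices:

* muscle `P_NIC = 1` — muscle nicotine tracks plasma;
* fat is a small-perfusion depot (`Q` 9 L/h, `P_NIC` 2) whose washout rate
  `Q/(V·P) ≈ 0.2 h⁻¹` supplies the ~3-h terminal nicotine phase, while the
  bulk of the dose is eliminated from the faster pool;
* pregnancy-specific tissues (mammary, uterus, placenta) carry `P_NIC = 1`
  so they do not become late depots feeding maternal plasma after the
  infusion;
* cotinine partitions are near 1 (total distribution volume ≈ 0.9 L/kg)
  with the muscle group at 1.9, giving the long cotinine half-life with
  the small published cotinine clearances.

The nicotine/cotinine half-life and urine outputs move in opposite
directions under the admissible volume knobs (half-life ∝ V, early urinary
metabolite ∝ 1/V), so the shipped values are the balanced point of that
trade-off; both sit within the reported ranges but nearer their edges than
the other outputs.

## Placental transfer and its calibration

Transfer is a directional influx–efflux pair per compound: influx `k_mf`
(L/h) acts on placental outflow concentration, efflux `k_fm` on fetal
blood. A symmetric passive-diffusion term cannot produce a fetal nicotine
level *above* maternal together with a fetal cotinine level *below*
maternal, which is why the asymmetric form is used.
`calibrate_placenta` fixes the influx scales (20 and 5 L/h; the
fetal/maternal ratio depends on the efflux/influx balance, not the
absolute scale, which only sets equilibration speed) and solves two
deterministic 1-D root problems (Brent's method on log efflux/influx) so
that under a sustained maternal nicotine infusion, at quasi-steady state
(48 h settle), fetal blood / maternal venous nicotine = 1.15 ± 0.02 and
the cotinine ratio hits a default target of 0.9 — the cotinine target is a
package default expressing "below maternal"; no measured value exists.
Unreachable targets raise a calibration error reporting the achievable
range. The shipped config contains the calibrated constants rounded to
four significant figures.

## Dosing

* `iv_bolus` — instantaneous venous increment; the integrator restarts at
  the event time.
* `iv_infusion` — zero-order venous input (µg/min over a stated window).
* `inhalation` — zero-order lung input over a short puff train (default
  5 min); total absorbed amount must be stated by the scenario, as no
  validated smoking parameters are shipped.
* `oral` — first-order portal absorption into the liver inflow with
  event-supplied `ka` (1/h) and bioavailability `F` (no defaults are
  provided); the depot is handled analytically as an exponential input, so
  it adds no state.

## Numerics

LSODA with the exact (constant) Jacobian, `rtol = 1e-8`, `atol = 1e-10` µg
by default; integration restarts at every dose-event boundary so input
discontinuities are never smoothed across. Output is a regular dense grid
(0.1 min for time-to-peak scenarios, 0.5 min otherwise). Solver-scale
negative amounts (more negative than −1e-9 µg is treated as an error) are
clipped to zero in the returned result. Tmax ties break to the earliest
grid point; its resolution is the output step. The terminal half-life is
the log-linear least-squares slope over the trailing 30% of the simulated
span (≥ 5 positive post-peak samples required; fits with R² < 0.95 are
returned flagged rather than rejected). The dose-linearity property is
asserted at `rtol = 1e-11` because at the default tolerances the solver's
own step error (~4e-8 relative) exceeds the 1e-8 property bound; the
system itself is exactly linear.

Scenario horizons are chosen per output: 72 h for the infusion scenarios
(≥ 4 cotinine half-lives for the terminal fit, with the nicotine fit taken
on the 24-h prefix), 8 h for the bolus/brain scenario, 48 h of sustained
infusion for the calibration quasi-steady state.

## What the defaults do and do not represent

The shipped physiology is one plausible reference adult female (and her
week-30 pregnant counterpart), sufficient to reproduce the reported
aggregate outputs; it is not a validated organ-level parameter set, and
passing tests demonstrate internal consistency plus agreement with those
aggregate outputs only. Individual tissue curves (other than plasma,
urine, brain timing and the fetal ratios) are unconstrained predictions.

Known limitations: no enzyme-level (CYP2A6/UGT) saturation — clearances
are fixed at their stated per-kg values and, in pregnancy, at the week-30
level regardless of the configured week; no plasma-protein binding; no
trophoblast transporter kinetics beyond the lumped influx/efflux pair; no
amniotic fluid or fetal urine recycling; no inter-individual variability
(the configuration is a single subject; population sampling hooks would
sit naturally on top of the config dict but are not provided).
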