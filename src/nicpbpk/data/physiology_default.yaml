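# Default physiology for the nicotine/cotinine pregnancy PBPK model.
#
# DEFAULTS — these volumes, flows, partition coefficients and gestational
# growth functions are not asserted by the source publication (which does
# not print them); they are plausible adult-female values assembled from
# the standard PBPK literature lineage (ICRP-style reference anatomy,
# flow-limited nicotine models) and calibrated once so that the shipped
# model reproduces the published simulation outputs (plasma half-lives,
# 5-h urinary amounts, pregnant vs non-pregnant differences, brain uptake
# time).  Edit freely for other subjects; entries are in L, L/h and
# dimensionless tissue:blood partition coefficients.
#
# Notes on the compartment grouping: "rapid" is the vessel-rich group
# (viscera, glands); "muscle" lumps skeletal muscle with skin, which is
# why its perfusion rises substantially with gestation (thermoregulatory
# skin flow); "fat" is the slowly perfused adipose depot whose washout
# sets the terminal nicotine phase.
#
# Growth functions map gestational week w -> additive increment, either as
#   {poly: [c0, c1, c2, ...]}  meaning c0 + c1*w + c2*w^2 + ...
# or {points: [[w0, v0], [w1, v1], ...]} (piecewise linear).

reference:
  body_weight_kg: 70.0

blood:
  arterial_L: 1.5
  venous_L: 3.5

tissues:
  # lung flow is null: the lung is in series and carries the whole cardiac
  # output (sum of all perfused-tissue flows).
  lung:     {volume_L: 0.5,  flow_L_per_h: null, partition_nic: 4.0, partition_cot: 1.0}
  brain:    {volume_L: 1.3,  flow_L_per_h: 50.0, partition_nic: 1.5, partition_cot: 0.8}
  liver:    {volume_L: 1.7,  flow_L_per_h: 90.0, partition_nic: 6.0, partition_cot: 1.2}
  kidney:   {volume_L: 0.30, flow_L_per_h: 54.0, partition_nic: 3.0, partition_cot: 3.0}
  rapid:    {volume_L: 4.0,  flow_L_per_h: 55.0, partition_nic: 1.8, partition_cot: 3.0}
  muscle:   {volume_L: 24.0, flow_L_per_h: 60.0, partition_nic: 1.0, partition_cot: 1.9}
  fat:      {volume_L: 20.0, flow_L_per_h: 9.0,  partition_nic: 2.0, partition_cot: 0.5}
  mammary:  {volume_L: 0.4,  flow_L_per_h: 1.5,  partition_nic: 1.0, partition_cot: 1.0}
  uterus:   {volume_L: 0.08, flow_L_per_h: 4.5,  partition_nic: 1.0, partition_cot: 1.0}
  # placenta baseline is zero; it exists only through gestational growth and
  # is excluded from the non-pregnant state.
  placenta: {volume_L: 0.0,  flow_L_per_h: 0.0,  partition_nic: 1.0, partition_cot: 1.0}

gestation:
  # maternal weight gain, kg (≈ 12 kg at term, quadratic in week)
  weight_gain: {poly: [0.0, 0.0, 0.0075]}
  # plasma/blood volume expansion, L
  blood_growth:
    arterial: {poly: [0.0, 0.01125]}
    venous:   {poly: [0.0, 0.039375]}
  # additive organ growth, volumes in L, flows in L/h
  tissue_growth:
    uterus:   {volume: {poly: [0.0, 0.0, 0.0025]},     flow: {poly: [0.0, 0.0, 0.01875]}}
    placenta: {volume: {poly: [0.0, 0.0, 0.00053125]}, flow: {poly: [0.0, 0.0, 0.025]}}
    mammary:  {volume: {poly: [0.0, 0.0, 0.00075]},    flow: {poly: [0.0, 0.05625]}}
    fat:      {volume: {poly: [0.0, 0.075]}}
    muscle:   {volume: {poly: [0.0, 0.1667]},          flow: {poly: [0.0, 2.0]}}
    rapid:    {volume: {poly: [0.0, 0.05]},            flow: {poly: [0.0, 0.8]}}
    liver:    {flow: {poly: [0.0, 1.5]}}
    kidney:   {flow: {poly: [0.0, 0.675]}}

fetus:
  # fetal weight ≈ 3.5 kg at term, cubic in gestational week
  body_weight: {poly: [0.0, 0.0, 0.0, 5.46875e-5]}
  blood_volume_frac: 0.10
  hepatic_clearance_fraction: 0.20
  tissues:
    brain: {volume_frac: 0.13, flow_L_per_h_per_kg: 4.0,  partition_nic: 3.0, partition_cot: 0.8}
    liver: {volume_frac: 0.04, flow_L_per_h_per_kg: 2.7,  partition_nic: 3.5, partition_cot: 1.2}
    rest:  {volume_frac: 0.60, flow_L_per_h_per_kg: 13.3, partition_nic: 1.0, partition_cot: 1.0}

# Placental influx (maternal->fetal) and efflux (fetal->maternal) transfer
# clearances, L/h.  The shipped values are the output of
# calibrate_placenta() with the default targets (fetal/maternal nicotine
# ratio 1.15, cotinine ratio 0.9; the latter is a package default — the
# source only states that the fetal cotinine level is below the maternal
# one).
placental_transfer:
  influx_nic: 20.0
  efflux_nic: 16.501
  influx_cot: 5.0
  efflux_cot: 5.5695

dosing_defaults:
  inhalation_duration_min: 5.0
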