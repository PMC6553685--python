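# Baseline parameter table for the coupled socio-climate model.
# Triangular distributions (lower / mode / upper) drive ensembles and the
# tornado sensitivity analysis; modes are the baseline values.
social:
  kappa: 0.05      # social learning rate, 1/yr
  beta: 1.0        # net cost to mitigate, utility units
  delta: 1.0       # strength of social norms, utility units
  fmax: 5.0        # ceiling of perceived climate cost, utility units
  omega: 3.0       # cost-sigmoid steepness, 1/degC
  Tc: 2.5          # cost-sigmoid midpoint, degC anomaly
  tf: 25.0         # forward extrapolation horizon, yr
  tp: 10.0         # backward extrapolation window, yr
  x0: 0.05         # initial mitigator fraction in 2014

climate:
  solar_flux: 1368.0            # W/m^2
  solar_flux_ref: 1368.0        # W/m^2 (calibration reference; do not sample)
  albedo: 0.30
  heat_capacity: 1.4e9          # J/K/m^2 effective areal heat capacity
  T_preind: 287.0               # K
  ghg_coeff: 5.35               # W/m^2 per ln(CO2 ratio)
  feedback_amp: 4.13            # W/m^2/K fast-feedback amplification
  atm_preind: 596.4             # GtC (280 ppm)
  veg_preind: 550.0             # GtC
  soil_preind: 1500.0           # GtC
  ocean_preind: 38000.0         # GtC
  photo_preind: 120.0           # GtC/yr
  veg_resp_preind: 60.0         # GtC/yr
  k_half: 300.0                 # ppm
  veg_capacity: 1300.0          # GtC
  q10_veg: 2.0
  q10_soil: 2.2
  photo_temp_coeff: 0.015       # 1/degC
  ocean_exchange: 0.035         # GtC/yr/ppm
  revelle: 12.5
  solubility_temp_coeff: 0.035  # 1/degC

forcing:
  eps_max: 15.0    # saturating post-2014 increment, GtC/yr
  s: 50.0          # half-saturation constant, yr
  source: stylised # stylised | synthetic | csv path supplied at load time

simulation:
  start_year: 1800
  behaviour_start_year: 2014
  horizon_end: 2200
  rtol: 1.0e-8
  atol: 1.0e-10

distributions:
  - {name: kappa,          lower: 0.02,    mode: 0.05,   upper: 0.2}
  - {name: beta,           lower: 0.5,     mode: 1.0,    upper: 1.5}
  - {name: delta,          lower: 0.5,     mode: 1.0,    upper: 1.5}
  - {name: fmax,           lower: 4.0,     mode: 5.0,    upper: 6.0}
  - {name: omega,          lower: 1.0,     mode: 3.0,    upper: 5.0}
  - {name: Tc,             lower: 2.0,     mode: 2.5,    upper: 3.0}
  - {name: tf,             lower: 15.0,    mode: 25.0,   upper: 35.0}
  - {name: tp,             lower: 5.0,     mode: 10.0,   upper: 15.0}
  - {name: x0,             lower: 0.01,    mode: 0.05,   upper: 0.1}
  - {name: eps_max,        lower: 10.0,    mode: 15.0,   upper: 20.0}
  - {name: s,              lower: 30.0,    mode: 50.0,   upper: 70.0}
  - {name: solar_flux,     lower: 1361.16, mode: 1368.0, upper: 1374.84}
  - {name: k_half,         lower: 240.0,   mode: 300.0,  upper: 360.0}
  - {name: ocean_exchange, lower: 0.028,   mode: 0.035,  upper: 0.042}
  - {name: q10_soil,       lower: 1.8,     mode: 2.2,    upper: 2.6}
  - {name: feedback_amp,   lower: 3.5,     mode: 4.13,   upper: 4.6}
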