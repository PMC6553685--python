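"""Reduced Earth-system model: four carbon pools plus an energy balance.

State variables are *deviations* from pre-industrial values: atmospheric
(C_at), vegetation (C_veg), soil (C_so) and ocean (C_oc) carbon in GtC, and
the global mean surface temperature anomaly T in degC.  Atmospheric carbon
obeys

    dC_at/dt = eps(t) * (1 - x) - P + R_veg + R_so - F_oc

with photosynthesis P (Michaelis-Menten CO2 fertilisation with a weak
linear temperature modifier), Q10 vegetation and soil respiration R_veg,
R_so, litterfall closing the land loop, and a Revelle-buffered,
solubility-limited air-sea exchange F_oc into an explicit ocean pool, so
that emission is the only exogenous carbon source.  The energy balance is
run on the absolute surface temperature,

    c dT_abs/dt = F_d - sigma * T_abs^4      (per unit area),

with the net downward flux F_d = (S/4)(1 - albedo) + A0 + B ln(pCO2/pCO2_0)
+ w * T: shortwave absorption, a calibrated pre-industrial greenhouse
offset A0, logarithmic CO2 radiative forcing, and a linear amplification
term w*T standing for fast feedbacks (water vapour, lapse rate) that sets
the equilibrium climate sensitivity (~3 degC per CO2 doubling at the
defaults).  A0 is calibrated against a reference solar flux so the
pre-industrial state is an exact radiative equilibrium; varying
``solar_flux`` away from the reference then acts as a genuine forcing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np

__all__ = [
    "ClimateParams",
    "ClimateState",
    "photosynthesis_rate",
    "vegetation_respiration",
    "litterfall",
    "soil_respiration",
    "ocean_uptake",
    "downward_flux",
    "carbon_rhs",
    "temperature_rhs",
]

SECONDS_PER_YEAR = 3.155695e7


@dataclass(frozen=True)
class ClimateParams:
    """Physical constants and calibrated coefficients of the reduced model.

    Flux coefficients are derived from the pre-industrial flux values
    (``photo_preind`` etc.) so that the all-zero deviation state is an exact
    fixed point.  ``solar_flux_ref`` is the calibration value of the solar
    parameter; setting ``solar_flux`` away from it imposes a radiative
    forcing.
    """

    solar_flux: float = 1368.0            # W/m^2, incident solar parameter
    solar_flux_ref: float = 1368.0        # W/m^2, calibration reference
    albedo: float = 0.30                  # planetary shortwave albedo
    sigma_SB: float = 5.670374419e-8      # W m^-2 K^-4
    a_E: float = 5.101e14                 # m^2, Earth surface area
    heat_capacity: float = 1.4e9          # J K^-1 m^-2, effective areal heat capacity
    T_preind: float = 287.0               # K, pre-industrial absolute GMST
    ghg_coeff: float = 5.35               # W/m^2 per ln(CO2 ratio)
    feedback_amp: float = 4.13            # W/m^2/K, fast-feedback amplification
    atm_preind: float = 596.4             # GtC (280 ppm)
    veg_preind: float = 550.0             # GtC
    soil_preind: float = 1500.0           # GtC
    ocean_preind: float = 38000.0         # GtC
    photo_preind: float = 120.0           # GtC/yr, pre-industrial photosynthesis
    veg_resp_preind: float = 60.0         # GtC/yr, pre-industrial plant respiration
    k_half: float = 300.0                 # ppm, CO2 fertilisation half-saturation
    veg_capacity: float = 1300.0          # GtC, vegetation carrying capacity
    q10_veg: float = 2.0                  # respiration Q10, vegetation
    q10_soil: float = 2.2                 # respiration Q10, soil
    photo_temp_coeff: float = 0.015       # 1/degC, linear T modifier on P
    ocean_exchange: float = 0.035         # GtC/yr per ppm air-sea pCO2 difference
    revelle: float = 12.5                 # ocean carbonate buffer factor
    solubility_temp_coeff: float = 0.035  # 1/degC, warming raises ocean pCO2
    gtc_per_ppm: float = 2.13             # GtC per ppm CO2

    def __post_init__(self) -> None:
        for name in (
            "solar_flux", "solar_flux_ref", "sigma_SB", "a_E", "heat_capacity",
            "T_preind", "atm_preind", "veg_preind", "soil_preind", "ocean_preind",
            "photo_preind", "veg_resp_preind", "k_half", "q10_veg", "q10_soil",
            "ocean_exchange", "gtc_per_ppm",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.albedo < 1.0:
            raise ValueError("albedo must lie in (0, 1)")
        if self.veg_resp_preind >= self.photo_preind:
            raise ValueError("need photo_preind > veg_resp_preind (litterfall > 0)")
        if self.veg_capacity <= self.veg_preind:
            raise ValueError("veg_capacity must exceed veg_preind")

    # -- derived calibration constants ------------------------------------
    @property
    def litter_preind(self) -> float:
        """Pre-industrial litterfall, closing the vegetation balance (GtC/yr)."""
        return self.photo_preind - self.veg_resp_preind

    @property
    def soil_resp_preind(self) -> float:
        """Pre-industrial soil respiration; equals litterfall at equilibrium."""
        return self.litter_preind

    @property
    def ppm_preind(self) -> float:
        return self.atm_preind / self.gtc_per_ppm

    @property
    def ghg_offset(self) -> float:
        """Pre-industrial greenhouse trapping A0 (W/m^2), calibrated so the
        reference solar flux balances sigma*T_preind^4 at zero deviation."""
        return (
            self.sigma_SB * self.T_preind**4
            - 0.25 * self.solar_flux_ref * (1.0 - self.albedo)
        )

    def replace(self, **changes) -> "ClimateParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class ClimateState:
    """Deviations from pre-industrial values: carbon pools (GtC) and T (degC)."""

    c_at: float = 0.0
    c_veg: float = 0.0
    c_so: float = 0.0
    c_oc: float = 0.0
    T: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.c_at, self.c_veg, self.c_so, self.c_oc, self.T])

    @classmethod
    def from_array(cls, y) -> "ClimateState":
        return cls(*(float(v) for v in y))


def _ppm(state: ClimateState, p: ClimateParams) -> float:
    return (p.atm_preind + state.c_at) / p.gtc_per_ppm


def photosynthesis_rate(state: ClimateState, p: ClimateParams) -> float:
    """Carbon uptake by photosynthesis P, GtC/yr.

    Scales with vegetation carbon up to a carrying capacity (the
    self-limiting land sink), saturating (Michaelis-Menten) CO2
    fertilisation normalised to 1 at pre-industrial, and a weak linear
    temperature modifier (floored at zero).
    """
    conc = _ppm(state, p)
    fert = (conc / (conc + p.k_half)) / (p.ppm_preind / (p.ppm_preind + p.k_half))
    veg_abs = p.veg_preind + state.c_veg
    veg = veg_abs / p.veg_preind
    cap = max(0.0, (p.veg_capacity - veg_abs) / (p.veg_capacity - p.veg_preind))
    temp = max(0.0, 1.0 + p.photo_temp_coeff * state.T)
    return p.photo_preind * max(veg, 0.0) * cap * fert * temp


def vegetation_respiration(state: ClimateState, p: ClimateParams) -> float:
    """Plant (autotrophic) respiration R_veg, GtC/yr, with Q10 temperature response."""
    veg = max((p.veg_preind + state.c_veg) / p.veg_preind, 0.0)
    return p.veg_resp_preind * veg * p.q10_veg ** (state.T / 10.0)


def litterfall(state: ClimateState, p: ClimateParams) -> float:
    """Vegetation-to-soil carbon transfer L, GtC/yr (first order in vegetation)."""
    veg = max((p.veg_preind + state.c_veg) / p.veg_preind, 0.0)
    return p.litter_preind * veg


def soil_respiration(state: ClimateState, p: ClimateParams) -> float:
    """Soil (heterotrophic) respiration R_so, GtC/yr, with Q10 temperature response."""
    soil = max((p.soil_preind + state.c_so) / p.soil_preind, 0.0)
    return p.soil_resp_preind * soil * p.q10_soil ** (state.T / 10.0)


def ocean_uptake(state: ClimateState, p: ClimateParams) -> float:
    """Net air-to-ocean carbon flux F_oc, GtC/yr (signed; negative = outgassing).

    Driven by the pCO2 difference between atmosphere and surface ocean; the
    ocean pCO2 rises with ocean carbon content (Revelle buffering) and with
    temperature (solubility loss).
    """
    p_atm = _ppm(state, p)
    p_oc = (
        p.ppm_preind
        * (1.0 + p.revelle * state.c_oc / p.ocean_preind)
        * (1.0 + p.solubility_temp_coeff * state.T)
    )
    return p.ocean_exchange * (p_atm - p_oc)


def downward_flux(state: ClimateState, p: ClimateParams) -> float:
    """Net downward radiative flux absorbed at the surface F_d, W/m^2.

    Shortwave absorption (S/4)(1 - albedo) plus the calibrated
    pre-industrial greenhouse offset, logarithmic CO2 forcing, and the
    linear fast-feedback amplification w*T.  Increasing in both C_at and
    the solar parameter.
    """
    conc = _ppm(state, p)
    return (
        0.25 * p.solar_flux * (1.0 - p.albedo)
        + p.ghg_offset
        + p.ghg_coeff * np.log(conc / p.ppm_preind)
        + p.feedback_amp * state.T
    )


def carbon_rhs(
    state: ClimateState, emission_rate: float, x: float, p: ClimateParams
) -> np.ndarray:
    """Time derivatives of the four carbon pools (GtC/yr).

    Returns [dC_at, dC_veg, dC_so, dC_oc]/dt.  The anthropogenic term
    eps*(1 - x) vanishes at full mitigation (x = 1); all pool-to-pool
    fluxes cancel in the sum, so total modelled carbon changes only by the
    emission term.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"x must lie in [0, 1], got {x}")
    if emission_rate < 0:
        raise ValueError(f"emission_rate must be >= 0, got {emission_rate}")
    P = photosynthesis_rate(state, p)
    Rv = vegetation_respiration(state, p)
    L = litterfall(state, p)
    Rs = soil_respiration(state, p)
    Foc = ocean_uptake(state, p)
    return np.array(
        [
            emission_rate * (1.0 - x) - P + Rv + Rs - Foc,
            P - Rv - L,
            L - Rs,
            Foc,
        ]
    )


def temperature_rhs(state: ClimateState, p: ClimateParams) -> float:
    """dT/dt in degC/yr from the per-area energy balance on absolute temperature."""
    T_abs = p.T_preind + state.T
    imbalance = downward_flux(state, p) - p.sigma_SB * T_abs**4
    return imbalance * SECONDS_PER_YEAR / p.heat_capacity
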