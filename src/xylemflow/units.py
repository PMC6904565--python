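"""Unit conventions and fluid constants.

Internally the package works in the units the quantities of interest are
naturally reported in: pressures in kPa, mass flow in µg s⁻¹, lengths in µm,
areas in mm² and axial gradients in MPa m⁻¹.  Hydraulic resistances are
therefore carried in kPa/(µg s⁻¹).  All conversions to and from SI happen in
this module so the rest of the code can stay unit-naive.
"""

from __future__ import annotations

# Water at 20 °C.
ETA_WATER_MPA_S = 1.002e-9
"""Dynamic viscosity of water, MPa·s (1.002e-3 Pa·s)."""

RHO_WATER_KG_M3 = 998.0
"""Density of water, kg m⁻³."""

# Area-specific inter-vessel pit resistance for grapevine.  The constant is
# used as resistance = R_PIT_GRAPEVINE / pit_area; see pit_connection_resistance
# for the unit discussion.
R_PIT_GRAPEVINE = 168.0

#: 1 kPa/µm expressed in MPa/m.
KPA_PER_UM_TO_MPA_PER_M = 1.0e3


def pressure_gradient_mpa_m(delta_p_kpa: float, length_um: float) -> float:
    """Axial pressure gradient in MPa m⁻¹ from a drop in kPa over a length in µm."""
    return delta_p_kpa / length_um * KPA_PER_UM_TO_MPA_PER_M


def mass_flow_kg_s(flow_ug_s: float) -> float:
    return flow_ug_s * 1.0e-12 * 1.0e3


def specific_conductivity_si(flow_ug_s: float, gradient_mpa_m: float,
                             area_mm2: float) -> float:
    """Specific conductivity in kg m⁻¹ MPa⁻¹ s⁻¹.

    flow / (gradient × area) with flow in µg s⁻¹ → kg s⁻¹ (×1e-9) and area in
    mm² → m² (×1e-6).
    """
    return flow_ug_s * 1.0e-9 / (gradient_mpa_m * area_mm2 * 1.0e-6)
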