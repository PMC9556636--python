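"""Coolant energy balance: heat absorbed by the perfused vessel.

The energy extracted by the coolant over one ablation is

    dQ = m * c_aqua * dT,

with m the coolant mass passed during the ablation (flow x duration x
density), c_aqua the specific heat of water (4.186 kJ/(kg K)) and dT the
inlet-to-outlet temperature rise measured end-to-end. The absorbed
fraction relates dQ to the applied microwave energy (power x duration).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError

__all__ = ["EnergyBalance", "coolant_mass", "energy_loss", "absorbed_fraction"]

SPECIFIC_HEAT_WATER_KJ_KGK = 4.186
COOLANT_DENSITY_G_ML = 1.0


def coolant_mass(flow_ml_min: float, duration_s: float, density_g_ml: float = COOLANT_DENSITY_G_ML) -> float:
    """Coolant mass (kg) passed through the vessel during the ablation."""
    if flow_ml_min < 0 or duration_s < 0 or density_g_ml < 0:
        raise ParameterError("coolant_mass: inputs must be >= 0")
    return flow_ml_min * (duration_s / 60.0) * density_g_ml / 1000.0


def energy_loss(mass_kg: float, c_kJ_kgK: float, delta_T_K: float) -> float:
    """dQ = m * c * dT, in kJ."""
    if mass_kg < 0 or c_kJ_kgK < 0:
        raise ParameterError("energy_loss: mass and specific heat must be >= 0")
    if delta_T_K < 0:
        raise ParameterError("energy_loss: negative dT (coolant cannot cool below inlet)")
    return mass_kg * c_kJ_kgK * delta_T_K


def absorbed_fraction(delta_Q_kJ: float, power_W: float, duration_s: float) -> float:
    """dQ as a percentage of the applied microwave energy."""
    if power_W <= 0 or duration_s <= 0:
        raise ParameterError("absorbed_fraction: applied energy must be > 0")
    return 100.0 * delta_Q_kJ / (power_W * duration_s / 1000.0)


@dataclass
class EnergyBalance:
    """Full energy bookkeeping for one perfused run."""

    flow_ml_min: float
    duration_s: float
    delta_T_K: float
    coolant_density_g_ml: float
    mass_kg: float
    specific_heat_kJ_kgK: float
    delta_Q_kJ: float
    applied_energy_kJ: float
    absorbed_fraction_pct: float

    @classmethod
    def compute(
        cls,
        flow_ml_min: float,
        duration_s: float,
        delta_T_K: float,
        power_W: float,
        density_g_ml: float = COOLANT_DENSITY_G_ML,
        c_kJ_kgK: float = SPECIFIC_HEAT_WATER_KJ_KGK,
    ) -> "EnergyBalance":
        m = coolant_mass(flow_ml_min, duration_s, density_g_ml)
        dq = energy_loss(m, c_kJ_kgK, delta_T_K)
        return cls(
            flow_ml_min=flow_ml_min,
            duration_s=duration_s,
            delta_T_K=delta_T_K,
            coolant_density_g_ml=density_g_ml,
            mass_kg=m,
            specific_heat_kJ_kgK=c_kJ_kgK,
            delta_Q_kJ=dq,
            applied_energy_kJ=power_W * duration_s / 1000.0,
            absorbed_fraction_pct=absorbed_fraction(dq, power_W, duration_s),
        )
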