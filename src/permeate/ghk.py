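"""Nernst and Goldman-Hodgkin-Katz (GHK) voltage models for sperm membranes.

The membrane potential of a cell permeable to K+, Na+ and Cl- is described by
the GHK voltage equation,

    Em = (RT/F) * ln[(P_K*[K]_o + P_Na*[Na]_o + P_Cl*[Cl]_i) /
                     (P_K*[K]_i + P_Na*[Na]_i + P_Cl*[Cl]_o)],

with the anion's internal/external concentrations swapped relative to the
cations. Only permeability *ratios* are identifiable from voltage data, so
permeabilities are carried as dimensionless numbers relative to a reference
(the residual K+ permeability of SLO3-mutant sperm, assigned 1.0).

This module also provides the passive chloride redistribution fixed point:
if Cl- is not actively pumped, a sustained hyperpolarization drives Cl-
out of the cell until E_Cl equals the membrane potential, at which point the
chloride terms drop out of the GHK expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "CONCENTRATION_FLOOR",
    "BathComposition",
    "PermeabilitySet",
    "EquilibriumPotentials",
    "PassiveChlorideSolution",
    "thermal_voltage_mv",
    "nernst_potential",
    "ghk_voltage",
    "equilibrium_potentials",
    "solve_passive_chloride",
]

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.314462618  # J/(mol K)

#: Nominally 0 mM substitutions (e.g. "1 mM Na" media made with NMDG+) are
#: floored at this value so the GHK logarithms stay defined.
CONCENTRATION_FLOOR = 1e-3  # mM


def thermal_voltage_mv(temperature_c: float = 37.0) -> float:
    """RT/F in millivolts at the given temperature (~26.73 mV at 37 degC)."""
    return 1e3 * GAS_CONSTANT * (temperature_c + 273.15) / FARADAY


def _check_concentration(value: float, name: str, floor: bool = False) -> float:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if value < 0:
        raise ValueError(f"{name} must be positive (mM), got {value!r}")
    if value == 0 and not floor:
        raise ValueError(f"{name} must be positive (mM), got 0")
    return max(value, CONCENTRATION_FLOOR)


@dataclass(frozen=True)
class BathComposition:
    """Ion concentrations (mM) and temperature defining one recording solution.

    Defaults are the HS-based recording medium: 5 K+/151 Na+/143 Cl- outside
    (135 NaCl + 1 Na-pyruvate + 15 NaHCO3), with internal concentrations
    K_in = 120 mM, Na_in = 14 mM, Cl_in = 40 mM chosen so the forward model
    reproduces the measured resting potentials. All overridable.

    Concentrations at a nominal 0 mM (impermeant-ion substitutions) are
    floored at :data:`CONCENTRATION_FLOOR`.
    """

    K_out: float = 5.0
    Na_out: float = 151.0
    Cl_out: float = 143.0
    K_in: float = 120.0
    Na_in: float = 14.0
    Cl_in: float = 40.0
    temperature_C: float = 37.0

    def __post_init__(self) -> None:
        for name in ("K_out", "Na_out", "Cl_out", "K_in", "Na_in", "Cl_in"):
            value = _check_concentration(getattr(self, name), name, floor=True)
            object.__setattr__(self, name, value)
        if not 0.0 <= self.temperature_C <= 50.0:
            raise ValueError(
                f"temperature_C must lie in [0, 50], got {self.temperature_C!r}"
            )

    def with_k_out(self, k_out: float) -> "BathComposition":
        """Same bath with a different external K+ (the assay's swept variable)."""
        return replace(self, K_out=k_out)

    def with_cl_in(self, cl_in: float) -> "BathComposition":
        return replace(self, Cl_in=cl_in)

    def to_dict(self) -> dict:
        return {
            "K_out": self.K_out,
            "Na_out": self.Na_out,
            "Cl_out": self.Cl_out,
            "K_in": self.K_in,
            "Na_in": self.Na_in,
            "Cl_in": self.Cl_in,
            "temperature_C": self.temperature_C,
        }


@dataclass(frozen=True)
class PermeabilitySet:
    """Relative membrane permeabilities to K+, Na+ and Cl-.

    Dimensionless and meaningful only as ratios: the GHK voltage is invariant
    under uniform scaling of all three. Convention here normalizes to the
    SLO3-mutant non-capacitated P_K = 1.0.
    """

    p_k: float
    p_na: float
    p_cl: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_k", "p_na", "p_cl"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")

    @property
    def total(self) -> float:
        return self.p_k + self.p_na + self.p_cl

    def scaled(self, factor: float) -> "PermeabilitySet":
        if factor <= 0:
            raise ValueError("scaling factor must be > 0")
        return PermeabilitySet(self.p_k * factor, self.p_na * factor, self.p_cl * factor)

    def normalized(self, reference_p_k: float = 1.0) -> "PermeabilitySet":
        """Rescale so p_k equals ``reference_p_k`` (requires p_k > 0)."""
        if self.p_k <= 0:
            raise ValueError("cannot normalize a permeability set with p_k = 0")
        return self.scaled(reference_p_k / self.p_k)

    def to_dict(self) -> dict:
        return {"p_k": self.p_k, "p_na": self.p_na, "p_cl": self.p_cl}


class EquilibriumPotentials(NamedTuple):
    E_K: float
    E_Na: float
    E_Cl: float


class PassiveChlorideSolution(NamedTuple):
    Em: float
    Cl_in: float


def nernst_potential(
    c_in: float, c_out: float, valence: int = 1, temperature_c: float = 37.0
) -> float:
    """Equilibrium (Nernst) potential in mV, inside relative to outside.

    Em = (RT/zF) * ln(C_out/C_in). With [K+]_i = 120 mM and [K+]_e = 5 mM at
    37 degC this gives the −84.9 mV calibration anchor.
    """
    c_in = _check_concentration(c_in, "c_in")
    c_out = _check_concentration(c_out, "c_out")
    if valence == 0:
        raise ValueError("valence must be a nonzero integer")
    return thermal_voltage_mv(temperature_c) / valence * math.log(c_out / c_in)


def ghk_voltage(perms: PermeabilitySet, bath: BathComposition) -> float:
    """Goldman-Hodgkin-Katz membrane voltage (mV) for K+, Na+ and Cl-.

    Monovalent ions only; the chloride concentrations enter with inside and
    outside swapped. Raises if all three permeabilities are zero (the voltage
    is then undefined).
    """
    if perms.total <= 0:
        raise ValueError("GHK voltage undefined: all permeabilities are zero")
    num = perms.p_k * bath.K_out + perms.p_na * bath.Na_out + perms.p_cl * bath.Cl_in
    den = perms.p_k * bath.K_in + perms.p_na * bath.Na_in + perms.p_cl * bath.Cl_out
    return thermal_voltage_mv(bath.temperature_C) * math.log(num / den)


def equilibrium_potentials(bath: BathComposition) -> EquilibriumPotentials:
    """Per-ion Nernst potentials (E_K, E_Na, E_Cl) in mV; Cl- has valence −1."""
    t = bath.temperature_C
    return EquilibriumPotentials(
        E_K=nernst_potential(bath.K_in, bath.K_out, +1, t),
        E_Na=nernst_potential(bath.Na_in, bath.Na_out, +1, t),
        E_Cl=nernst_potential(bath.Cl_in, bath.Cl_out, -1, t),
    )


def solve_passive_chloride(
    perms: PermeabilitySet, bath: BathComposition
) -> PassiveChlorideSolution:
    """Fixed point where Cl- is passively distributed across the membrane.

    At equilibrium Cl- carries no net flux, so the membrane potential is set
    by the cation terms alone,

        Em = (RT/F) * ln[(P_K*K_o + P_Na*Na_o) / (P_K*K_i + P_Na*Na_i)],

    and the internal chloride relaxes to Cl_in = Cl_out * exp(Em*F/RT), i.e.
    E_Cl(Cl_in) = Em. The pair is a closed-form fixed point of the full GHK
    expression: substituting this Cl_in back in leaves Em unchanged.
    """
    if perms.p_k + perms.p_na <= 0:
        raise ValueError("passive chloride solution requires p_k + p_na > 0")
    vt = thermal_voltage_mv(bath.temperature_C)
    num = perms.p_k * bath.K_out + perms.p_na * bath.Na_out
    den = perms.p_k * bath.K_in + perms.p_na * bath.Na_in
    em = vt * math.log(num / den)
    cl_in = bath.Cl_out * math.exp(em / vt)
    return PassiveChlorideSolution(Em=em, Cl_in=cl_in)
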