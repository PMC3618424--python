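"""Condition preset registry: permeability ground truths and bath recipes.

Presets are shipped as a YAML registry (``data/presets.yaml``) keyed by
genotype, capacitation state and external pH, with multiplicative modifiers
for channel blockers. All permeabilities are relative to the SLO3-mutant
non-capacitated P_K at pH 7.4, assigned 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Optional, Tuple

import yaml

from .ghk import BathComposition, PermeabilitySet

__all__ = [
    "ConditionSpec",
    "GENOTYPES",
    "STATES",
    "PH_LABELS",
    "BLOCKERS",
    "MEDIA",
    "load_registry",
    "known_conditions",
    "preset_permeabilities",
    "preset_bath",
    "chloride_is_passive",
]

GENOTYPES = ("wild-type", "slo3-mutant")
STATES = ("non-capacitated", "capacitated")
PH_LABELS = ("7", "7.4", "8")
BLOCKERS = ("none", "amiloride", "barium", "clofilium")
MEDIA = ("normal", "low-na", "low-cl-44", "low-cl-5")


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition of the membrane-potential assay.

    ``mixed_fraction``/``subpop_offsets`` optionally emulate a heterogeneous
    sperm population (only a fraction achieves the capacitated, hyperpolarized
    state); the measured voltage is then the population-weighted mean of the
    two subpopulation voltages (true Em plus each offset, in mV).
    """

    genotype: str = "wild-type"
    state: str = "non-capacitated"
    ph: str = "7.4"
    blocker: str = "none"
    media: str = "normal"
    mixed_fraction: Optional[float] = None
    subpop_offsets: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        _require(self.genotype, GENOTYPES, "genotype")
        _require(self.state, STATES, "state")
        _require(str(self.ph), PH_LABELS, "ph")
        object.__setattr__(self, "ph", str(self.ph))
        _require(self.blocker, BLOCKERS, "blocker")
        _require(self.media, MEDIA, "media")
        if self.mixed_fraction is not None and not 0.0 <= self.mixed_fraction <= 1.0:
            raise ValueError(f"mixed_fraction must lie in [0, 1], got {self.mixed_fraction!r}")

    @property
    def label(self) -> str:
        """Canonical condition slug, e.g. ``wt_noncap_ph7.4_amiloride``."""
        parts = [
            "wt" if self.genotype == "wild-type" else "mut",
            "noncap" if self.state == "non-capacitated" else "cap",
            f"ph{self.ph}",
        ]
        if self.blocker != "none":
            parts.append(self.blocker)
        if self.media != "normal":
            parts.append(self.media.replace("-", ""))
        return "_".join(parts)

    def to_dict(self) -> dict:
        return {
            "genotype": self.genotype,
            "state": self.state,
            "ph": self.ph,
            "blocker": self.blocker,
            "media": self.media,
            "mixed_fraction": self.mixed_fraction,
            "subpop_offsets": list(self.subpop_offsets),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionSpec":
        d = dict(d)
        if "subpop_offsets" in d and d["subpop_offsets"] is not None:
            d["subpop_offsets"] = tuple(d["subpop_offsets"])
        return cls(**d)


def _require(value, allowed, name: str) -> None:
    if str(value) not in allowed:
        raise KeyError(f"unknown {name} {value!r}; known values: {', '.join(allowed)}")


@lru_cache(maxsize=1)
def load_registry() -> dict:
    """Load and cache the YAML preset registry shipped with the package."""
    text = resources.files("permeate").joinpath("data/presets.yaml").read_text()
    return yaml.safe_load(text)


def known_conditions() -> list[str]:
    """Labels of every pure-registry condition (no blocker/media modifier)."""
    reg = load_registry()["permeabilities"]
    labels = []
    for genotype, states in reg.items():
        for state, phs in states.items():
            for ph in phs:
                labels.append(ConditionSpec(genotype=genotype, state=state, ph=ph).label)
    return labels


def preset_permeabilities(spec: ConditionSpec) -> PermeabilitySet:
    """Ground-truth relative permeabilities for a condition.

    Base values come from the (genotype, state, pH) registry entry; amiloride
    divides P_Na by 6.5, and SLO3 blockers (Ba2+, clofilium) replace the
    wild-type P_K by the mutant residual value for the same state/pH.
    """
    reg = load_registry()
    try:
        entry = reg["permeabilities"][spec.genotype][spec.state][spec.ph]
    except KeyError as exc:
        raise KeyError(
            f"no permeability preset for {spec.label!r}; known conditions: "
            f"{', '.join(known_conditions())}"
        ) from exc
    p_k, p_na, p_cl = entry["p_k"], entry["p_na"], entry["p_cl"]
    mods = reg["modifiers"]
    if spec.blocker == "amiloride":
        p_na /= mods["amiloride_p_na_factor"]
    elif spec.blocker in mods["slo3_blockers"]:
        residual = reg["permeabilities"]["slo3-mutant"][spec.state][spec.ph]
        p_k = residual["p_k"]
    return PermeabilitySet(p_k=p_k, p_na=p_na, p_cl=p_cl)


def preset_bath(spec: ConditionSpec) -> BathComposition:
    """Recording-bath composition for a condition (media overrides applied)."""
    baths = load_registry()["baths"]
    recipe = dict(baths["normal"])
    if spec.media != "normal":
        recipe.update(baths[spec.media])
    return BathComposition(**recipe)


def chloride_is_passive(spec: ConditionSpec) -> bool:
    """Whether the generator treats internal Cl- as passively redistributed.

    True for the strongly hyperpolarizing or Cl-substituted conditions whose
    voltage curves are well described without an explicit chloride term
    (amiloride, low-Na and low-Cl media); False otherwise, keeping Cl_in at
    its fixed default.
    """
    return spec.blocker == "amiloride" or spec.media != "normal"
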