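"""Synthetic membrane-potential tables and dye traces for the assay conditions.

The generator reproduces the statistical structure the analysis assumes: per
condition, the true membrane potential at each external K+ concentration
comes from the GHK forward model with the preset ground-truth permeabilities;
replicate experiments add Gaussian noise (default sigma = 2 mV, matching the
few-mV SEM scale of population recordings) and are summarized as mean/SEM/n.
Fluorescence traces follow an affine dye-response model (fluorescence rising
with depolarization) with the valinomycin/KCl calibration ladder appended.

Conditions whose curves the analysis treats without an explicit chloride term
(amiloride, low-Na and low-Cl media) are simulated with internal Cl- at its
passive equilibrium for each K_out; all other conditions keep Cl_in fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calibration import (
    DEFAULT_KCL_STEPS,
    VALINOMYCIN_LABEL,
    FluorescenceTrace,
    TraceEvent,
)
from .fitting import EmTable
from .ghk import ghk_voltage, nernst_potential, solve_passive_chloride
from .presets import ConditionSpec, chloride_is_passive, preset_bath, preset_permeabilities

__all__ = [
    "GeneratorConfig",
    "true_em",
    "simulate_em_table",
    "simulate_fluorescence_trace",
    "simulate_condition_suite",
    "DEFAULT_SUITE",
]

#: The condition comparisons the default pipeline runs: baseline genotypes,
#: capacitation, pH 8, SLO3 blockers and amiloride.
DEFAULT_SUITE = (
    ConditionSpec(genotype="slo3-mutant", state="non-capacitated"),
    ConditionSpec(genotype="wild-type", state="non-capacitated"),
    ConditionSpec(genotype="wild-type", state="capacitated"),
    ConditionSpec(genotype="slo3-mutant", state="capacitated"),
    ConditionSpec(genotype="wild-type", state="non-capacitated", ph="8"),
    ConditionSpec(genotype="slo3-mutant", state="non-capacitated", ph="8"),
    ConditionSpec(genotype="wild-type", state="capacitated", blocker="clofilium"),
    ConditionSpec(genotype="wild-type", state="non-capacitated", blocker="amiloride"),
    ConditionSpec(genotype="slo3-mutant", state="non-capacitated", blocker="amiloride"),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic experiment.

    Defaults mirror the assay design: K+ grid 5/10/20/30 mM, n = 11 replicate
    experiments, replicate noise sigma = 2 mV. The dye model maps Em to
    arbitrary units as F = gain*Em + offset with additive Gaussian noise;
    the positive gain makes fluorescence fall upon hyperpolarization.
    """

    k_grid: Tuple[float, ...] = (5.0, 10.0, 20.0, 30.0)
    n_replicates: int = 11
    sigma_mV: float = 2.0
    seed: int = 0
    dye_gain_au_per_mV: float = 2.0
    dye_offset_au: float = 400.0
    dye_sigma_au: float = 3.0
    sample_interval_s: float = 1.0
    baseline_duration_s: float = 120.0
    step_duration_s: float = 90.0
    kcl_steps: Tuple[float, ...] = DEFAULT_KCL_STEPS

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.sigma_mV < 0 or self.dye_sigma_au < 0:
            raise ValueError("noise levels must be >= 0")

    def to_dict(self) -> dict:
        return {
            "k_grid": list(self.k_grid),
            "n_replicates": self.n_replicates,
            "sigma_mV": self.sigma_mV,
            "seed": self.seed,
            "dye_gain_au_per_mV": self.dye_gain_au_per_mV,
            "dye_offset_au": self.dye_offset_au,
            "dye_sigma_au": self.dye_sigma_au,
        }


def true_em(spec: ConditionSpec, k_out: float) -> float:
    """Noise-free membrane potential (mV) of a condition at one [K+]_e.

    Applies the preset permeabilities and bath, passive chloride
    redistribution where the condition calls for it, and the mixed-population
    average when the spec defines one.
    """
    perms = preset_permeabilities(spec)
    bath = preset_bath(spec).with_k_out(k_out)
    if chloride_is_passive(spec):
        em = solve_passive_chloride(perms, bath).Em
    else:
        em = ghk_voltage(perms, bath)
    if spec.mixed_fraction is not None:
        f = spec.mixed_fraction
        off1, off2 = spec.subpop_offsets
        em = f * (em + off1) + (1.0 - f) * (em + off2)
    return em


def simulate_em_table(spec: ConditionSpec, cfg: GeneratorConfig) -> EmTable:
    """Simulate one mean/SEM/n membrane-potential table for a condition.

    Deterministic given ``cfg.seed``: the same seed and config reproduce the
    table bit for bit.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for k in cfg.k_grid:
        em0 = true_em(spec, k)
        reps = em0 + rng.normal(0.0, cfg.sigma_mV, size=cfg.n_replicates)
        mean = float(np.mean(reps))
        if cfg.n_replicates > 1:
            sem = float(np.std(reps, ddof=1) / np.sqrt(cfg.n_replicates))
        else:
            sem = np.nan
        rows.append({"K_out_mM": k, "Em_mV": mean, "sem_mV": sem, "n": cfg.n_replicates})
    return EmTable(
        pd.DataFrame(rows), label=spec.label, condition=spec, bath=preset_bath(spec)
    )


def simulate_fluorescence_trace(spec: ConditionSpec, cfg: GeneratorConfig) -> FluorescenceTrace:
    """Simulate a dye recording with the valinomycin/KCl calibration ladder.

    Timeline: a steady-state segment at the condition's true Em in the 5 mM
    K+ bath, a valinomycin clamp to E_K, then sequential KCl steps with
    plateaus at the corresponding K+ Nernst potentials. Em is mapped to
    arbitrary units through the affine dye model plus Gaussian noise.
    """
    rng = np.random.default_rng(cfg.seed)
    bath = preset_bath(spec)
    k_in, temp = bath.K_in, bath.temperature_C
    k0 = bath.K_out

    segments = [(cfg.baseline_duration_s, true_em(spec, k0))]
    events = []
    t_cursor = cfg.baseline_duration_s
    events.append(TraceEvent(t_cursor, VALINOMYCIN_LABEL, k0))
    segments.append((cfg.step_duration_s, nernst_potential(k_in, k0, 1, temp)))
    t_cursor += cfg.step_duration_s
    for k in cfg.kcl_steps:
        events.append(TraceEvent(t_cursor, f"KCl to {k} mM", k))
        segments.append((cfg.step_duration_s, nernst_potential(k_in, k, 1, temp)))
        t_cursor += cfg.step_duration_s

    em_samples = np.concatenate(
        [
            np.full(max(int(round(dur / cfg.sample_interval_s)), 1), em)
            for dur, em in segments
        ]
    )
    time = np.arange(em_samples.size) * cfg.sample_interval_s
    fluor = cfg.dye_gain_au_per_mV * em_samples + cfg.dye_offset_au
    if cfg.dye_sigma_au > 0:
        fluor = fluor + rng.normal(0.0, cfg.dye_sigma_au, size=fluor.size)
    return FluorescenceTrace(
        time_s=time, fluorescence_au=fluor, events=events, label=spec.label
    )


def simulate_condition_suite(
    conditions: Iterable[ConditionSpec] = DEFAULT_SUITE,
    cfg: Optional[GeneratorConfig] = None,
) -> Dict[str, EmTable]:
    """Simulate one table per condition with independent per-condition seeds.

    Child seeds are spawned deterministically from ``cfg.seed`` in condition
    order, so the whole suite is reproducible while tables stay statistically
    independent.
    """
    conditions = tuple(conditions)
    cfg = cfg or GeneratorConfig()
    ss = np.random.SeedSequence(cfg.seed)
    out = {}
    for spec, child in zip(conditions, ss.spawn(len(conditions))):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        out[spec.label] = simulate_em_table(spec, replace(cfg, seed=child_seed))
    return out
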