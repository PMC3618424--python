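"""Simulate -> calibrate -> fit -> compare -> report, as one reproducible run.

The pipeline mirrors the condition-comparison structure of the voltage assay:
a baseline pair of non-capacitated SLO3-mutant and wild-type tables anchors
the staged fit, every other condition is fitted with condition-appropriate
constraints, the baseline curves are compared with the SEM-weighted
chi-square statistic, and a permeability summary table (one row per
condition) is written alongside per-condition fit reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import (
    EmTable,
    FitResult,
    compare_curves_chisq,
    fit_ghk,
    fit_ghk_no_chloride,
    permeability_p_values,
    staged_fit,
)
from .io import write_em_table, write_fit_result
from .presets import ConditionSpec
from .synthetic import DEFAULT_SUITE, GeneratorConfig, simulate_condition_suite

__all__ = ["RunConfig", "PipelineReport", "run_pipeline", "report_permeability_table"]

logger = logging.getLogger("permeate")

_BASELINE_MUTANT = ConditionSpec(genotype="slo3-mutant", state="non-capacitated").label
_BASELINE_WILDTYPE = ConditionSpec(genotype="wild-type", state="non-capacitated").label


@dataclass
class RunConfig:
    """One pipeline run: conditions, generator settings, fit options, outputs."""

    conditions: Tuple[ConditionSpec, ...] = DEFAULT_SUITE
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    out_dir: Path = Path("permeate-run")
    seed: Optional[int] = None  # overrides generator.seed when set
    all_free_check: bool = False
    no_chloride_comparison: bool = True
    p_values: bool = True
    plots: bool = False
    overwrite: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "conditions" in raw:
            kwargs["conditions"] = tuple(
                ConditionSpec.from_dict(c) for c in raw["conditions"]
            )
        if "generator" in raw:
            kwargs["generator"] = GeneratorConfig(**raw["generator"])
        for key in (
            "seed",
            "all_free_check",
            "no_chloride_comparison",
            "p_values",
            "plots",
            "overwrite",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "out_dir" in raw:
            kwargs["out_dir"] = Path(raw["out_dir"])
        return cls(**kwargs)


@dataclass
class PipelineReport:
    out_dir: Path
    summary: pd.DataFrame
    fits: List[FitResult]
    comparisons: pd.DataFrame
    run_log: dict


def report_permeability_table(results: Sequence[FitResult]) -> pd.DataFrame:
    """Permeability summary in the condition x (P_K, P_Na, P_Cl) layout.

    Includes the selectivity ratios P_K/P_Na and P_K/P_Cl, goodness of fit,
    and nested-fit p-values where computed. All values are relative to the
    mutant non-capacitated P_K = 1.0 normalization.
    """
    if not results:
        raise ValueError("no fit results to report")
    rows = []
    for r in results:
        p = r.permeabilities
        row = {
            "condition": r.label,
            "P_K": p.p_k,
            "P_Na": p.p_na,
            "P_Cl": p.p_cl,
            "P_K/P_Na": p.p_k / p.p_na if p.p_na > 0 else np.inf,
            "P_K/P_Cl": p.p_k / p.p_cl if p.p_cl > 0 else np.inf,
            "weighted_SSE": r.weighted_sse,
            "dof": r.dof,
            "converged": r.converged,
        }
        for name, key in (("p_K", "p_k"), ("p_Na", "p_na"), ("p_Cl", "p_cl")):
            row[f"pvalue_{name}"] = (r.p_values or {}).get(key, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def _prepare_out_dir(out_dir: Path, overwrite: bool) -> Path:
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{out_dir} is not empty; pass overwrite=True (--overwrite) to reuse it"
        )
    (out_dir / "fits").mkdir(parents=True, exist_ok=True)
    (out_dir / "tables").mkdir(parents=True, exist_ok=True)
    return out_dir


def run_pipeline(
    config: RunConfig, tables: Optional[Dict[str, EmTable]] = None
) -> PipelineReport:
    """Execute the full analysis and write the report bundle.

    ``tables`` may supply measured Em tables keyed by condition label;
    otherwise the synthetic suite for ``config.conditions`` is generated.
    The baseline non-capacitated mutant and wild-type tables are required.
    Outputs under ``config.out_dir``: ``tables/*.csv``, ``fits/*.json``,
    ``summary.csv``, ``comparisons.csv`` and ``run_log.json`` (optional
    predicted-vs-observed plots with ``plots=True``).
    """
    cfg = config.generator
    if config.seed is not None:
        cfg = replace(cfg, seed=config.seed)
    out_dir = _prepare_out_dir(config.out_dir, config.overwrite)

    if tables is None:
        logger.info("simulating %d conditions (seed %d)", len(config.conditions), cfg.seed)
        tables = simulate_condition_suite(config.conditions, cfg)
    for label in (_BASELINE_MUTANT, _BASELINE_WILDTYPE):
        if label not in tables:
            raise ValueError(
                f"missing baseline table {label!r}; the staged fit needs both "
                "non-capacitated baselines"
            )
    for label, table in tables.items():
        write_em_table(table, out_dir / "tables" / f"{label}.csv")

    mutant = tables[_BASELINE_MUTANT]
    wildtype = tables[_BASELINE_WILDTYPE]
    others = [t for k, t in tables.items() if k not in (_BASELINE_MUTANT, _BASELINE_WILDTYPE)]

    logger.info("stage 1/2: baseline fits; stage 3: %d conditions", len(others))
    fits = staged_fit(
        mutant, wildtype, others, all_free_check=config.all_free_check
    )

    if config.p_values:
        for result, table in zip(fits, [mutant, wildtype, *others]):
            result.p_values = permeability_p_values(
                table, result.bath, result.constraints
            )

    comparisons = []
    chisq = compare_curves_chisq(wildtype, mutant)
    comparisons.append(
        {
            "comparison": f"{_BASELINE_WILDTYPE} vs {_BASELINE_MUTANT}",
            "statistic": chisq.statistic,
            "dof": chisq.dof,
            "p_value": chisq.p_value,
        }
    )
    if config.no_chloride_comparison:
        for table, full in zip([mutant, wildtype], fits[:2]):
            no_cl = fit_ghk_no_chloride(table, full.bath, full.constraints)
            comparisons.append(
                {
                    "comparison": f"{table.label}: no-chloride vs full fit",
                    "statistic": no_cl.weighted_sse / max(full.weighted_sse, 1e-300),
                    "dof": no_cl.dof,
                    "p_value": np.nan,
                }
            )
            write_fit_result(no_cl, out_dir / "fits" / f"{table.label}_no_cl.json")

    for result in fits:
        write_fit_result(result, out_dir / "fits" / f"{result.label}.json")

    summary = report_permeability_table(fits)
    summary.to_csv(out_dir / "summary.csv", index=False)
    comparisons_df = pd.DataFrame(comparisons)
    comparisons_df.to_csv(out_dir / "comparisons.csv", index=False)

    if config.plots:
        _write_plots(tables, fits, out_dir)

    run_log = {
        "version": __version__,
        "seed": cfg.seed,
        "generator": cfg.to_dict(),
        "conditions": [t for t in tables],
        "normalization": "slo3-mutant non-capacitated p_k = 1.0",
    }
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=2))
    logger.info("report written to %s", out_dir)
    return PipelineReport(out_dir, summary, fits, comparisons_df, run_log)


def _write_plots(tables: Dict[str, EmTable], fits: Sequence[FitResult], out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .fitting import ghk_em_curve

    fig, ax = plt.subplots(figsize=(6, 4.5))
    k_fine = np.linspace(4, 40, 200)
    for result in fits:
        table = tables[result.label]
        ax.errorbar(
            table.k_out, table.em, yerr=table.sem, fmt="o", capsize=3, label=result.label
        )
        ax.plot(
            k_fine,
            ghk_em_curve(result.permeabilities, result.bath, k_fine, result.redistribute_cl),
            lw=1,
        )
    ax.set_xscale("log")
    ax.set_xlabel("external [K+] (mM)")
    ax.set_ylabel("Em (mV)")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(out_dir / "em_vs_k.png", dpi=150)
    plt.close(fig)
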