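"""Constrained GHK least-squares estimation of relative ion permeabilities.

Given a table of mean membrane potentials measured at several external K+
concentrations, the relative permeabilities (P_K, P_Na, P_Cl) are estimated
by weighted nonlinear least squares against the GHK voltage equation. Because
only permeability ratios are identifiable, every fit carries a constraint set
in which at least one parameter is fixed; the staged procedure anchors the
whole analysis to the SLO3-mutant non-capacitated curve:

  stage 1: fix mutant P_K = 1.0, fit P_Na and P_Cl;
  stage 2: fix P_Na/P_Cl at stage-1 values, fit wild-type P_K;
  stage 3: fit each remaining condition with condition-appropriate
           constraints (blocker fits drop P_Cl, see ``staged_fit``).

A chi-square statistic weighted by the per-point SEMs compares two measured
voltage curves, and nested-fit (likelihood-ratio-style) comparisons attach a
p-value to each permeability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .ghk import BathComposition, PermeabilitySet, thermal_voltage_mv
from .presets import ConditionSpec

__all__ = [
    "EmTable",
    "ConstraintSet",
    "FitResult",
    "CurveComparison",
    "GHKPermeabilityFitter",
    "ghk_em_curve",
    "fit_ghk",
    "fit_ghk_no_chloride",
    "staged_fit",
    "compare_curves_chisq",
    "permeability_p_values",
]

FREE = "free"
_PARAM_NAMES = ("p_k", "p_na", "p_cl")


@dataclass
class EmTable:
    """Per-condition membrane potentials (mean, SEM, n) vs external K+.

    ``data`` columns: ``K_out_mM``, ``Em_mV``, ``sem_mV``, ``n``. A fit needs
    at least three distinct K_out values (the assay uses four: 5/10/20/30 mM).
    """

    data: pd.DataFrame
    label: str = ""
    condition: Optional[ConditionSpec] = None
    bath: Optional[BathComposition] = None

    REQUIRED_COLUMNS = ("K_out_mM", "Em_mV", "sem_mV", "n")

    def __post_init__(self) -> None:
        missing = [c for c in ("K_out_mM", "Em_mV") if c not in self.data.columns]
        if missing:
            raise ValueError(f"EmTable missing required columns: {missing}")
        if "sem_mV" not in self.data.columns:
            self.data = self.data.assign(sem_mV=np.nan)
        if "n" not in self.data.columns:
            self.data = self.data.assign(n=1)
        if self.data["K_out_mM"].nunique() < 3:
            raise ValueError(
                "EmTable needs >= 3 distinct K_out values for a permeability fit"
            )
        bad_sem = (self.data["n"] > 1) & ~(self.data["sem_mV"] > 0)
        if bad_sem.any() and self.data["sem_mV"].notna().any():
            raise ValueError("sem_mV must be > 0 wherever n > 1")
        if not self.label and self.condition is not None:
            self.label = self.condition.label

    @classmethod
    def from_arrays(
        cls,
        k_out: Sequence[float],
        em: Sequence[float],
        sem: Optional[Sequence[float]] = None,
        n: Union[int, Sequence[int]] = 1,
        **kwargs,
    ) -> "EmTable":
        df = pd.DataFrame({"K_out_mM": k_out, "Em_mV": em})
        df["sem_mV"] = np.nan if sem is None else np.asarray(sem, dtype=float)
        df["n"] = n
        return cls(df, **kwargs)

    @property
    def k_out(self) -> np.ndarray:
        return self.data["K_out_mM"].to_numpy(dtype=float)

    @property
    def em(self) -> np.ndarray:
        return self.data["Em_mV"].to_numpy(dtype=float)

    @property
    def sem(self) -> Optional[np.ndarray]:
        s = self.data["sem_mV"].to_numpy(dtype=float)
        return s if np.isfinite(s).all() else None

    def weights(self) -> np.ndarray:
        """1/SEM^2 weights, or unit weights when SEMs are absent."""
        s = self.sem
        if s is None:
            return np.ones_like(self.em)
        return 1.0 / s**2


@dataclass(frozen=True)
class ConstraintSet:
    """Per-parameter status for a GHK fit: a fixed value or ``"free"``.

    At least one parameter must be fixed — the GHK voltage only identifies
    permeability ratios, so an all-free fit is scale-degenerate.
    """

    p_k: Union[float, str] = 1.0
    p_na: Union[float, str] = FREE
    p_cl: Union[float, str] = FREE
    reference: str = "slo3-mutant non-capacitated p_k = 1.0"

    def __post_init__(self) -> None:
        statuses = [getattr(self, name) for name in _PARAM_NAMES]
        for value in statuses:
            if isinstance(value, str):
                if value != FREE:
                    raise ValueError(f"constraint must be a number or {FREE!r}, got {value!r}")
            elif not (math.isfinite(value) and value >= 0):
                raise ValueError(f"fixed permeability must be finite and >= 0, got {value!r}")
        if all(v == FREE for v in statuses):
            raise ValueError(
                "under-determined constraint set: at least one permeability must be "
                "fixed (only ratios are identifiable from voltage data)"
            )

    @property
    def free_names(self) -> tuple:
        return tuple(n for n in _PARAM_NAMES if getattr(self, n) == FREE)

    def assemble(self, free_values: Sequence[float]) -> PermeabilitySet:
        values = {}
        it = iter(free_values)
        for name in _PARAM_NAMES:
            v = getattr(self, name)
            values[name] = float(next(it)) if v == FREE else float(v)
        return PermeabilitySet(**values)

    def to_dict(self) -> dict:
        return {
            "p_k": self.p_k,
            "p_na": self.p_na,
            "p_cl": self.p_cl,
            "reference": self.reference,
        }


@dataclass
class FitResult:
    """Outcome of one constrained GHK fit."""

    permeabilities: PermeabilitySet
    residuals_mV: np.ndarray
    weighted_sse: float
    dof: int
    constraints: ConstraintSet
    converged: bool
    message: str = ""
    label: str = ""
    bath: Optional[BathComposition] = None
    redistribute_cl: bool = False
    p_values: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.weighted_sse < 0:
            raise ValueError("weighted SSE cannot be negative")

    @property
    def n_points(self) -> int:
        return len(self.residuals_mV)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "permeabilities": self.permeabilities.to_dict(),
            "residuals_mV": [float(r) for r in self.residuals_mV],
            "weighted_sse": float(self.weighted_sse),
            "dof": int(self.dof),
            "constraints": self.constraints.to_dict(),
            "converged": bool(self.converged),
            "message": self.message,
            "bath": self.bath.to_dict() if self.bath is not None else None,
            "redistribute_cl": self.redistribute_cl,
            "p_values": self.p_values,
        }


class CurveComparison(NamedTuple):
    statistic: float
    dof: int
    p_value: float


def ghk_em_curve(
    perms: PermeabilitySet,
    bath: BathComposition,
    k_out: Sequence[float],
    redistribute_cl: bool = False,
) -> np.ndarray:
    """GHK voltages (mV) across a grid of external K+ concentrations.

    With ``redistribute_cl`` the internal Cl- is taken at its passive
    equilibrium for each K_out, in which case the chloride terms cancel and
    the voltage is set by the cation terms alone.
    """
    k = np.asarray(k_out, dtype=float)
    vt = thermal_voltage_mv(bath.temperature_C)
    if redistribute_cl:
        num = perms.p_k * k + perms.p_na * bath.Na_out
        den = perms.p_k * bath.K_in + perms.p_na * bath.Na_in
    else:
        num = perms.p_k * k + perms.p_na * bath.Na_out + perms.p_cl * bath.Cl_in
        den = perms.p_k * bath.K_in + perms.p_na * bath.Na_in + perms.p_cl * bath.Cl_out
    num = np.maximum(num, 1e-300)
    den = max(den, 1e-300)
    return vt * np.log(num / den)


class GHKPermeabilityFitter(RegressorMixin, BaseEstimator):
    """Weighted least-squares GHK permeability estimator.

    Parameters
    ----------
    bath : BathComposition, optional
        Bath template; K_out is taken per sample from ``X``. Defaults to the
        standard recording medium.
    p_k, p_na, p_cl : float or "free"
        Constraint for each relative permeability: a fixed value or ``"free"``.
        At least one must be fixed. Default fixes P_K = 1.0.
    redistribute_cl : bool
        Replace the fixed internal Cl- with its passive-equilibrium value for
        every candidate parameter vector (P_Cl then drops out of the voltage).
    n_starts : int
        Multi-start count; initial free parameters are drawn log-uniformly
        from ``start_range``. The objective can be shallow in P_Na, so a few
        restarts guard against poor local optima.
    random_state : int
        Seed for the start draws.

    Attributes
    ----------
    permeabilities_ : PermeabilitySet
    result_ : FitResult
    residuals_ : ndarray, observed minus fitted Em (mV)
    weighted_sse_ : float
    dof_ : int
    """

    def __init__(
        self,
        bath: Optional[BathComposition] = None,
        p_k: Union[float, str] = 1.0,
        p_na: Union[float, str] = FREE,
        p_cl: Union[float, str] = FREE,
        redistribute_cl: bool = False,
        n_starts: int = 5,
        start_range: tuple = (0.01, 20.0),
        random_state: int = 0,
    ):
        self.bath = bath
        self.p_k = p_k
        self.p_na = p_na
        self.p_cl = p_cl
        self.redistribute_cl = redistribute_cl
        self.n_starts = n_starts
        self.start_range = start_range
        self.random_state = random_state

    def _constraints(self) -> ConstraintSet:
        return ConstraintSet(p_k=self.p_k, p_na=self.p_na, p_cl=self.p_cl)

    def fit(self, X, y, sample_weight=None):
        """Fit the free permeabilities to Em (mV) measured at K_out values.

        ``X`` is the external K+ concentration in mM, shape (n,) or (n, 1);
        ``y`` the mean membrane potential in mV; ``sample_weight`` typically
        1/SEM^2 (unit weights if omitted).
        """
        k = np.asarray(X, dtype=float)
        if k.ndim == 2:
            if k.shape[1] != 1:
                raise ValueError("X must contain a single K_out column")
            k = k[:, 0]
        y = np.asarray(y, dtype=float)
        if k.shape != y.shape:
            raise ValueError("X and y have mismatched lengths")
        if np.unique(k).size < 3:
            raise ValueError("need >= 3 distinct K_out values")
        w = np.ones_like(y) if sample_weight is None else np.asarray(sample_weight, float)
        if (w <= 0).any():
            raise ValueError("sample_weight must be positive")
        bath = self.bath if self.bath is not None else BathComposition()
        constraints = self._constraints()
        free = constraints.free_names
        if len(free) > np.unique(k).size:
            raise ValueError("more free permeabilities than distinct K_out values")
        sqrt_w = np.sqrt(w)

        def residual(theta):
            perms = constraints.assemble(theta)
            return sqrt_w * (y - ghk_em_curve(perms, bath, k, self.redistribute_cl))

        if free:
            rng = np.random.default_rng(self.random_state)
            lo, hi = self.start_range
            starts = [np.full(len(free), 1.0)]
            starts += [
                np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(free)))
                for _ in range(max(self.n_starts - 1, 0))
            ]
            best = None
            for x0 in starts:
                sol = optimize.least_squares(
                    residual, x0, bounds=(0.0, np.inf), method="trf", xtol=1e-12,
                    ftol=1e-12, gtol=1e-12,
                )
                if best is None or sol.cost < best.cost:
                    best = sol
            theta, converged, message = best.x, bool(best.success), str(best.message)
            if not converged:
                raise RuntimeError(
                    f"GHK fit failed to converge: {message}; last iterate {theta}"
                )
        else:
            theta, converged, message = np.empty(0), True, "all parameters fixed"

        perms = constraints.assemble(theta)
        model = ghk_em_curve(perms, bath, k, self.redistribute_cl)
        resid = y - model
        self.n_features_in_ = 1
        self.permeabilities_ = perms
        self.residuals_ = resid
        self.weighted_sse_ = float(np.sum(w * resid**2))
        self.dof_ = int(len(y) - len(free))
        self.result_ = FitResult(
            permeabilities=perms,
            residuals_mV=resid,
            weighted_sse=self.weighted_sse_,
            dof=self.dof_,
            constraints=constraints,
            converged=converged,
            message=str(message),
            bath=bath,
            redistribute_cl=self.redistribute_cl,
        )
        return self

    def predict(self, X) -> np.ndarray:
        """Model Em (mV) at the given external K+ concentrations."""
        if not hasattr(self, "permeabilities_"):
            raise AttributeError("fitter is not fitted yet; call fit first")
        k = np.asarray(X, dtype=float)
        if k.ndim == 2:
            k = k[:, 0]
        bath = self.bath if self.bath is not None else BathComposition()
        return ghk_em_curve(self.permeabilities_, bath, k, self.redistribute_cl)


def _table_fit(
    table: EmTable,
    bath: Optional[BathComposition],
    constraints: ConstraintSet,
    redistribute_cl: bool = False,
    n_starts: int = 5,
    random_state: int = 0,
) -> FitResult:
    bath = bath or table.bath or BathComposition()
    fitter = GHKPermeabilityFitter(
        bath=bath,
        p_k=constraints.p_k,
        p_na=constraints.p_na,
        p_cl=constraints.p_cl,
        redistribute_cl=redistribute_cl,
        n_starts=n_starts,
        random_state=random_state,
    )
    fitter.fit(table.k_out, table.em, sample_weight=table.weights())
    result = fitter.result_
    result.label = table.label
    result.constraints = constraints  # keep caller's reference note
    return result


def fit_ghk(
    table: EmTable,
    bath_template: Optional[BathComposition] = None,
    constraints: Optional[ConstraintSet] = None,
    **options,
) -> FitResult:
    """Fit free permeabilities of one Em table (weights 1/SEM^2 when present)."""
    constraints = constraints or ConstraintSet()
    return _table_fit(table, bath_template, constraints, **options)


def fit_ghk_no_chloride(
    table: EmTable,
    bath_template: Optional[BathComposition] = None,
    constraints: Optional[ConstraintSet] = None,
    **options,
) -> FitResult:
    """Same objective as :func:`fit_ghk` with P_Cl pinned to zero."""
    base = constraints or ConstraintSet()
    no_cl = ConstraintSet(p_k=base.p_k, p_na=base.p_na, p_cl=0.0, reference=base.reference)
    return _table_fit(table, bath_template, no_cl, **options)


def _stage3_constraints(
    condition: Optional[ConditionSpec], stage1: PermeabilitySet, wildtype_p_k: float
) -> ConstraintSet:
    """Condition-appropriate stage-3 constraints.

    Default holds P_Na and P_Cl at the stage-1 baseline and frees P_K (the
    capacitation/pH-8 effect is a K+ permeability change). Amiloride fits
    hold the genotype's P_K and free P_Na with no chloride term; low-Na and
    low-Cl media drop the chloride term and free P_K.
    """
    if condition is None:
        return ConstraintSet(p_k=FREE, p_na=stage1.p_na, p_cl=stage1.p_cl)
    if condition.blocker == "amiloride":
        p_k = wildtype_p_k if condition.genotype == "wild-type" else 1.0
        return ConstraintSet(p_k=p_k, p_na=FREE, p_cl=0.0)
    if condition.media != "normal":
        return ConstraintSet(p_k=FREE, p_na=stage1.p_na, p_cl=0.0)
    return ConstraintSet(p_k=FREE, p_na=stage1.p_na, p_cl=stage1.p_cl)


def staged_fit(
    noncap_mutant: EmTable,
    noncap_wildtype: EmTable,
    other_conditions: Iterable[EmTable] = (),
    bath_template: Optional[BathComposition] = None,
    all_free_check: bool = False,
    **options,
) -> list:
    """Run the staged, constrained permeability analysis across conditions.

    Returns one :class:`FitResult` per table, in order: mutant baseline,
    wild-type baseline, then the other conditions. All permeabilities are
    normalized to the mutant non-capacitated P_K = 1.0 by construction of
    the stage-1 constraint. With ``all_free_check`` each stage-3 result also
    records (in ``message``) the weighted SSE of a fit in which all three
    permeabilities float (anchored only by the stage-1 scale), a check that
    the constrained fits are not materially worse.
    """
    stage1 = fit_ghk(
        noncap_mutant,
        bath_template,
        ConstraintSet(p_k=1.0, p_na=FREE, p_cl=FREE),
        **options,
    )
    p = stage1.permeabilities
    stage2 = fit_ghk(
        noncap_wildtype,
        bath_template,
        ConstraintSet(p_k=FREE, p_na=p.p_na, p_cl=p.p_cl),
        **options,
    )
    results = [stage1, stage2]
    for table in other_conditions:
        constraints = _stage3_constraints(
            table.condition, p, stage2.permeabilities.p_k
        )
        bath = bath_template or table.bath
        result = _table_fit(table, bath, constraints, **options)
        if all_free_check:
            loose = ConstraintSet(p_k=FREE, p_na=FREE, p_cl=p.p_cl)
            free_fit = _table_fit(table, bath, loose, **options)
            result.message = (
                f"{result.message}; all-free weighted SSE {free_fit.weighted_sse:.4g} "
                f"vs constrained {result.weighted_sse:.4g}"
            )
        results.append(result)
    return results


def compare_curves_chisq(a: EmTable, b: EmTable) -> CurveComparison:
    """Chi-square comparison of two Em-vs-K_out curves with SEM weighting.

    statistic = sum_k (Em_a - Em_b)^2 / (sem_a^2 + sem_b^2) over the shared
    K_out grid, referred to a chi-square with one degree of freedom per point.
    """
    ka, kb = a.k_out, b.k_out
    if len(ka) != len(kb) or not np.allclose(np.sort(ka), np.sort(kb)):
        raise ValueError("curve comparison requires identical K_out grids")
    da = a.data.sort_values("K_out_mM")
    db = b.data.sort_values("K_out_mM")
    sa = da["sem_mV"].to_numpy(dtype=float)
    sb = db["sem_mV"].to_numpy(dtype=float)
    if not (np.isfinite(sa).all() and np.isfinite(sb).all()):
        raise ValueError("curve comparison requires SEMs in both tables")
    diff = da["Em_mV"].to_numpy(dtype=float) - db["Em_mV"].to_numpy(dtype=float)
    statistic = float(np.sum(diff**2 / (sa**2 + sb**2)))
    dof = len(diff)
    return CurveComparison(statistic, dof, float(stats.chi2.sf(statistic, dof)))


def permeability_p_values(
    table: EmTable,
    bath_template: Optional[BathComposition] = None,
    constraints: Optional[ConstraintSet] = None,
    **options,
) -> dict:
    """Nested-fit p-value for each permeability in a GHK fit.

    Each ion's contribution is assessed by refitting with that permeability
    pinned to zero (other constraints unchanged) and referring the increase
    in weighted SSE to a chi-square with one degree of freedom — a
    likelihood-ratio comparison under the Gaussian error model with known
    per-point SEMs. If dropping a parameter would leave no fixed parameter
    (scale degeneracy), the first remaining free one is fixed at its full-fit
    estimate.
    """
    constraints = constraints or ConstraintSet()
    full = _table_fit(table, bath_template, constraints, **options)
    out = {}
    for name in _PARAM_NAMES:
        value = getattr(constraints, name)
        if value != FREE and float(value) == 0.0:
            continue  # not in the model
        spec = {n: getattr(constraints, n) for n in _PARAM_NAMES}
        spec[name] = 0.0
        if all(v == FREE for n, v in spec.items() if n != name) and len(spec) > 1:
            others = [n for n in _PARAM_NAMES if n != name]
            spec[others[0]] = getattr(full.permeabilities, others[0])
        dropped = _table_fit(table, bath_template, ConstraintSet(**spec), **options)
        delta = max(dropped.weighted_sse - full.weighted_sse, 0.0)
        out[name] = float(stats.chi2.sf(delta, 1))
    return out
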