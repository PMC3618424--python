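"""Valinomycin/KCl-step calibration of potentiometric-dye fluorescence.

The population assay reads out membrane potential with a cationic
carbocyanine dye (DiSC3-(5)) whose fluorescence falls as the cell
hyperpolarizes. Each recording carries its own internal calibration: adding
valinomycin clamps the membrane at the K+ Nernst potential, and sequential
KCl additions step that potential through a known ladder (5 -> 7.2 -> 11.7 ->
20.7 -> 38.7 mM K+, i.e. −84.9 ... −30.2 mV with [K+]_i = 120 mM at 37 degC).
Pairing each post-step fluorescence plateau with its Nernst voltage yields an
anchor set; membrane potential is read off by linear interpolation between
anchors. Because every trace is calibrated against itself, any affine
gain/offset in the fluorescence channel cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .ghk import nernst_potential

__all__ = [
    "TraceEvent",
    "FluorescenceTrace",
    "CalibrationCurve",
    "FluorescenceCalibrator",
    "theoretical_calibration_voltages",
    "build_calibration",
    "fluorescence_to_em",
    "VALINOMYCIN_LABEL",
    "DEFAULT_KCL_STEPS",
]

VALINOMYCIN_LABEL = "valinomycin"
#: Final [K+]_e after each sequential KCl addition (mM).
DEFAULT_KCL_STEPS = (7.2, 11.7, 20.7, 38.7)


@dataclass(frozen=True)
class TraceEvent:
    time_s: float
    label: str
    K_out_mM: Optional[float] = None

    def to_dict(self) -> dict:
        return {"time_s": self.time_s, "label": self.label, "K_out_mM": self.K_out_mM}


@dataclass
class FluorescenceTrace:
    """One dye recording: fluorescence (AU) vs time plus annotated additions."""

    time_s: np.ndarray
    fluorescence_au: np.ndarray
    events: List[TraceEvent] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fluorescence_au = np.asarray(self.fluorescence_au, dtype=float)
        if self.time_s.shape != self.fluorescence_au.shape:
            raise ValueError("time and fluorescence arrays differ in length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")
        self.events = sorted(self.events, key=lambda e: e.time_s)
        steps = [e.K_out_mM for e in self.calibration_events]
        if any(b <= a for a, b in zip(steps, steps[1:])):
            raise ValueError("calibration K_out steps must be strictly increasing")

    @property
    def calibration_events(self) -> List[TraceEvent]:
        """Valinomycin clamp plus subsequent KCl additions, in time order."""
        vals = [e for e in self.events if e.label == VALINOMYCIN_LABEL]
        if not vals:
            return []
        t0 = vals[0].time_s
        out = [vals[0]]
        out += [
            e
            for e in self.events
            if e.time_s > t0 and e.K_out_mM is not None and e.label != VALINOMYCIN_LABEL
        ]
        return out


@dataclass
class CalibrationCurve:
    """Anchor pairs (fluorescence AU, theoretical Em mV) for one trace.

    ``mode`` is either ``"piecewise"`` (linear interpolation between
    bracketing anchors, terminal-segment extrapolation) or ``"line"``
    (single least-squares line through the anchors).
    """

    anchor_em_mV: np.ndarray
    anchor_fluorescence_au: np.ndarray
    mode: str = "piecewise"
    warnings: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.anchor_em_mV = np.asarray(self.anchor_em_mV, dtype=float)
        self.anchor_fluorescence_au = np.asarray(self.anchor_fluorescence_au, dtype=float)
        if self.anchor_em_mV.size < 2:
            raise ValueError("a calibration curve needs at least 2 anchors")
        if np.any(np.diff(self.anchor_em_mV) <= 0):
            raise ValueError("anchor Em values must be strictly increasing")
        if self.mode not in ("piecewise", "line"):
            raise ValueError(f"unknown calibration mode {self.mode!r}")
        if np.unique(self.anchor_fluorescence_au).size < 2 or np.any(
            np.diff(self.anchor_fluorescence_au) == 0
        ):
            raise ValueError("degenerate calibration: equal anchor fluorescences")
        # hyperpolarization quenches the dye, so fluorescence should rise with
        # depolarization (dF/dEm > 0 over the anchors); sign anomalies and
        # non-monotone plateaus are flagged, not fatal
        slopes = np.diff(self.anchor_fluorescence_au) / np.diff(self.anchor_em_mV)
        if np.any(np.sign(slopes) != np.sign(slopes[0])):
            self.warnings.append("non-monotone plateau fluorescence vs Em")

    @property
    def dye_slope_sign(self) -> int:
        """Sign of the overall dF/dEm across the anchor span."""
        df = self.anchor_fluorescence_au[-1] - self.anchor_fluorescence_au[0]
        dem = self.anchor_em_mV[-1] - self.anchor_em_mV[0]
        return int(np.sign(df / dem))

    def em_from_fluorescence(self, f) -> np.ndarray:
        """Map fluorescence (AU) to membrane potential (mV)."""
        f = np.asarray(f, dtype=float)
        em, fl = self.anchor_em_mV, self.anchor_fluorescence_au
        if self.mode == "line":
            slope, intercept = np.polyfit(fl, em, 1)
            return slope * f + intercept
        order = np.argsort(fl)
        fs, es = fl[order], em[order]
        out = np.interp(f, fs, es)
        # linear extrapolation beyond the end anchors with terminal slopes
        lo = f < fs[0]
        hi = f > fs[-1]
        out = np.where(lo, es[0] + (f - fs[0]) * (es[1] - es[0]) / (fs[1] - fs[0]), out)
        out = np.where(
            hi, es[-1] + (f - fs[-1]) * (es[-1] - es[-2]) / (fs[-1] - fs[-2]), out
        )
        return out

    def to_dict(self) -> dict:
        return {
            "anchor_em_mV": self.anchor_em_mV.tolist(),
            "anchor_fluorescence_au": self.anchor_fluorescence_au.tolist(),
            "mode": self.mode,
            "warnings": list(self.warnings),
            "dye_slope_sign": self.dye_slope_sign,
        }


def theoretical_calibration_voltages(
    k_steps: Sequence[float], k_in: float = 120.0, temperature_c: float = 37.0
) -> np.ndarray:
    """Nernst anchor voltages (mV) for a ladder of external K+ steps."""
    k = np.asarray(k_steps, dtype=float)
    if np.any(k <= 0):
        raise ValueError("K steps must be positive")
    if np.any(np.diff(k) <= 0):
        raise ValueError("K steps must be strictly increasing")
    return np.array([nernst_potential(k_in, ko, 1, temperature_c) for ko in k])


def build_calibration(
    trace: FluorescenceTrace,
    k_in: float = 120.0,
    plateau_window_s: float = 30.0,
    mode: str = "piecewise",
) -> CalibrationCurve:
    """Anchor the trace's post-step plateaus to their Nernst voltages.

    For each calibration event (the valinomycin clamp and every subsequent
    KCl addition) the plateau fluorescence is the median over a fixed-length
    window ending just before the next event (or at the end of the trace),
    paired with the Nernst potential of the event's final [K+]_e.
    """
    cal_events = trace.calibration_events
    if len(cal_events) < 3:  # valinomycin + >= 2 KCl steps
        raise ValueError(
            "calibration requires a valinomycin event followed by at least two "
            "KCl-step events"
        )
    t, f = trace.time_s, trace.fluorescence_au
    anchors_f, anchors_k = [], []
    for event, nxt in zip(cal_events, cal_events[1:] + [None]):
        end = nxt.time_s if nxt is not None else t[-1] + np.finfo(float).eps
        start = max(event.time_s, end - plateau_window_s)
        mask = (t >= start) & (t < end) if nxt is not None else (t >= start)
        if not mask.any():
            continue
        anchors_f.append(float(np.median(f[mask])))
        anchors_k.append(event.K_out_mM)
    if len(anchors_f) < 2:
        raise ValueError("fewer than 2 usable calibration anchors")
    temperature = 37.0
    em = theoretical_calibration_voltages(anchors_k, k_in, temperature)
    return CalibrationCurve(
        anchor_em_mV=em, anchor_fluorescence_au=np.asarray(anchors_f), mode=mode
    )


def fluorescence_to_em(curve: CalibrationCurve, f) -> np.ndarray:
    """Convert fluorescence (AU) to membrane potential (mV) via the curve."""
    return curve.em_from_fluorescence(f)


class FluorescenceCalibrator(TransformerMixin, BaseEstimator):
    """Transformer from dye fluorescence (AU) to membrane potential (mV).

    ``fit`` takes a :class:`FluorescenceTrace` (as ``X``) and builds the
    anchor calibration; ``transform`` maps fluorescence values to mV. The
    physically expected dye response has fluorescence increasing with
    depolarization; ``dye_response_ok_`` records that validity check.
    """

    def __init__(
        self,
        k_in: float = 120.0,
        plateau_window_s: float = 30.0,
        mode: str = "piecewise",
    ):
        self.k_in = k_in
        self.plateau_window_s = plateau_window_s
        self.mode = mode

    def fit(self, X: FluorescenceTrace, y=None):
        if not isinstance(X, FluorescenceTrace):
            raise TypeError("FluorescenceCalibrator.fit expects a FluorescenceTrace")
        self.curve_ = build_calibration(
            X, k_in=self.k_in, plateau_window_s=self.plateau_window_s, mode=self.mode
        )
        self.anchor_em_mV_ = self.curve_.anchor_em_mV
        self.anchor_fluorescence_au_ = self.curve_.anchor_fluorescence_au
        self.dye_response_ok_ = self.curve_.dye_slope_sign > 0
        self.warnings_ = list(self.curve_.warnings)
        if not self.dye_response_ok_:
            self.warnings_.append("dye fluorescence does not increase with depolarization")
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "curve_"):
            raise AttributeError("calibrator is not fitted yet; call fit first")
        return self.curve_.em_from_fluorescence(np.asarray(X, dtype=float))
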