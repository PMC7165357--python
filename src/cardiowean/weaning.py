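"""Model-based weaning analysis.

Given the fitted flow-response (control) coefficients of a weaning test,
this module extrapolates the cardiovascular parameters to zero
extracorporeal flow, simulates the unsupported circulation and evaluates the
clinical weaning-readiness criteria used at the bedside:

* aortic velocity-time integral VTI > 12 cm, with
  ``SV = pi * (phi_LVOT / 2)^2 * VTI``;
* left-ventricular ejection fraction ``SV / max(V_h)`` > 20-25 %;
* mean arterial pressure > 60 mmHg.

It also reports the normalized parameter changes for a 0-to-1 l/min flow
increase, the per-parameter summary used to compare control responses
across subjects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .identify import ControlCoefficients, FreeParameterSet, WeaningDataset
from .model import DriverConfig, ML_S_PER_L_MIN
from .simulate import (MeasurementVector, SimulationSettings,
                       simulate_to_steady_state, summarize_beat)

__all__ = [
    "NormalizedDeltas",
    "WeaningThresholds",
    "WeaningPrediction",
    "params_at_flow",
    "normalized_deltas",
    "predict_weaning",
    "delta_sign_report",
    "extrapolate_heart_rate",
]


def params_at_flow(c: ControlCoefficients, Q_d: float) -> FreeParameterSet:
    """Evaluate the linear control laws at ``Q_d`` (ml/s).

    At ``Q_d = 0`` the parameters equal the intercepts exactly.  Raises
    ValueError naming the offending parameter when a mapped value is
    non-positive (extrapolation outside the laws' validity).
    """
    return c.at_flow(Q_d)


@dataclass(frozen=True)
class NormalizedDeltas:
    """Fractional parameter changes for a 0-to-1 l/min flow increase:
    ``slope * (1 l/min in ml/s) / intercept`` per parameter."""

    d1_Eh: float
    d1_Ah: float
    d1_Ea: float
    d1_Rs: float
    d1_SBV: float

    def as_dict(self) -> dict:
        return asdict(self)

    def rounded(self, ndigits: int = 2) -> dict:
        """Values rounded for reporting (2 decimals by convention)."""
        return {k: round(v, ndigits) for k, v in self.as_dict().items()}


def normalized_deltas(c: ControlCoefficients) -> NormalizedDeltas:
    """Normalized parameter changes between Q_d = 0 and Q_d = 1 l/min."""
    d = c.slopes() * ML_S_PER_L_MIN / c.intercepts()
    return NormalizedDeltas(d1_Eh=float(d[0]), d1_Ah=float(d[1]),
                            d1_Ea=float(d[2]), d1_Rs=float(d[3]),
                            d1_SBV=float(d[4]))


def delta_sign_report(c: ControlCoefficients, near_zero: float = 0.005) -> dict:
    """Classify each normalized delta as positive, negative or near-zero.

    A delta with magnitude below ``near_zero`` counts as near-zero;
    otherwise the sign equals the sign of the slope (intercepts are
    positive by construction).
    """
    report = {}
    for name, value in normalized_deltas(c).as_dict().items():
        if abs(value) < near_zero:
            report[name] = "near-zero"
        else:
            report[name] = "positive" if value > 0 else "negative"
    return report


@dataclass(frozen=True)
class WeaningThresholds:
    """Bedside weaning criteria thresholds (all strict inequalities).

    ``EF_min`` defaults to the upper end of the accepted 20-25 % band; the
    prediction additionally reports the EF verdict at 0.20.  ``phi_LVOT``
    (LVOT diameter, cm) has no default — it is echo-derived in practice;
    without it the VTI criterion is reported unavailable and excluded from
    the overall verdict.
    """

    VTI_min: float = 12.0
    EF_min: float = 0.25
    MAP_min: float = 60.0
    phi_LVOT: float | None = None

    def __post_init__(self) -> None:
        for name in ("VTI_min", "EF_min", "MAP_min"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"WeaningThresholds.{name} must be > 0, got {v!r}")
        if self.phi_LVOT is not None and not self.phi_LVOT > 0:
            raise ValueError(f"phi_LVOT must be > 0 cm, got {self.phi_LVOT!r}")


@dataclass
class WeaningPrediction:
    """Predicted unsupported (Q_d = 0) hemodynamics and criteria verdicts."""

    params_at_zero: FreeParameterSet
    observables_at_zero: MeasurementVector
    HR_used: float
    EF: float
    VTI: float | None
    criteria: dict
    overall: bool
    EF_verdict_band: dict
    thresholds: WeaningThresholds

    def to_dict(self) -> dict:
        return {
            "params_at_zero": asdict(self.params_at_zero),
            "observables_at_zero": asdict(self.observables_at_zero),
            "HR_used": self.HR_used,
            "EF": self.EF,
            "VTI": self.VTI,
            "criteria": dict(self.criteria),
            "overall": self.overall,
            "EF_verdict_band": {str(k): v for k, v in self.EF_verdict_band.items()},
            "thresholds": asdict(self.thresholds),
        }


def extrapolate_heart_rate(data: WeaningDataset, Q_d: float = 0.0) -> float:
    """Heart rate at ``Q_d`` by ordinary-least-squares linear extrapolation
    of the dataset's (Q_d, HR) pairs (constant when only one record)."""
    q, hr = data.flows(), data.heart_rates()
    if len(q) < 2:
        return float(hr[0])
    slope, intercept = np.polyfit(q, hr, 1)
    return float(slope * Q_d + intercept)


def predict_weaning(c: ControlCoefficients, HR,
                    thresholds: WeaningThresholds | None = None,
                    fixed: dict | None = None,
                    settings: SimulationSettings | None = None,
                    cfg: DriverConfig | None = None) -> WeaningPrediction:
    """In-silico weaning test: simulate the circulation at Q_d = 0.

    Parameters
    ----------
    c : ControlCoefficients
        Fitted flow-response coefficients of the weaning test.
    HR : float or WeaningDataset
        Heart rate at zero flow (1/s), or the weaning dataset from which it
        is linearly extrapolated to Q_d = 0.
    thresholds : WeaningThresholds
        Criteria thresholds; without ``phi_LVOT`` the VTI criterion is
        unavailable and excluded from the overall verdict.

    All three criteria are strict inequalities: a value exactly at its
    threshold fails.
    """
    thresholds = thresholds or WeaningThresholds()
    hr0 = extrapolate_heart_rate(HR) if isinstance(HR, WeaningDataset) else float(HR)
    if not hr0 > 0:
        raise ValueError(f"extrapolated heart rate must be > 0, got {hr0!r}")
    free = c.at_flow(0.0)
    p = free.to_cvs(hr0, **(fixed or {}))
    trace = simulate_to_steady_state(p, Q_d=0.0, settings=settings, cfg=cfg)
    obs = summarize_beat(trace)

    ef = obs.SV / obs.maxV_h
    if thresholds.phi_LVOT is not None:
        vti = obs.SV / (math.pi * (thresholds.phi_LVOT / 2.0) ** 2)
        vti_ok = vti > thresholds.VTI_min
    else:
        warnings.warn("phi_LVOT not supplied: VTI unavailable, criterion "
                      "excluded from the overall verdict", stacklevel=2)
        vti, vti_ok = None, None
    criteria = {
        "VTI": vti_ok,
        "EF": ef > thresholds.EF_min,
        "MAP": obs.P_a_mean > thresholds.MAP_min,
    }
    overall = all(v for v in criteria.values() if v is not None)
    return WeaningPrediction(
        params_at_zero=free, observables_at_zero=obs, HR_used=hr0,
        EF=float(ef), VTI=vti, criteria=criteria, overall=bool(overall),
        EF_verdict_band={0.20: ef > 0.20, 0.25: ef > 0.25},
        thresholds=thresholds)
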