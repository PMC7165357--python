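"""Three-compartment lumped-parameter model of the cardiovascular system
coupled to venoarterial extracorporeal life support (VA-ECLS).

The circulation is reduced to a heart, an arterial and a venous compartment,
each characterized by its stressed blood volume.  The heart is a time-varying
elastance chamber driven by a periodic activation function ``e(t)`` that
interpolates between the end-diastolic pressure-volume relationship (EDPVR,
exponential in volume with parameters ``A_h`` and ``B_h``) and the
end-systolic pressure-volume relationship (ESPVR, linear with slope ``E_h``).
Arteries and veins are linear elastances (``E_a``, ``E_v``).  Blood moves
through three resistances: the input valve ``R_i`` (veins to heart), the
output valve ``R_o`` (heart to arteries) and the systemic circulation ``R_s``
(arteries to veins).  Valves are ideal diodes: flow is clipped at zero when
the pressure gradient reverses.

The VA-ECLS device is represented purely by its extracorporeal blood flow
``Q_d``, an imposed constant that drains the venous compartment and returns
blood to the arterial compartment.  Total stressed blood volume (SBV) is
conserved exactly by the dynamics.

Internal units are mmHg, ml and s throughout; ``Q_d`` is stored in ml/s and
clinical l/min values are converted with the exact factor 1000/60.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, fields, asdict

import numpy as np

__all__ = [
    "ML_S_PER_L_MIN",
    "l_min_to_ml_s",
    "ml_s_to_l_min",
    "InfeasibleParameterError",
    "CVSParameters",
    "ECLSSetting",
    "CVSState",
    "DriverConfig",
    "FlowSet",
    "driver_value",
    "heart_pressure",
    "chamber_pressures",
    "compute_flows",
    "rhs",
]

#: Exact conversion factor from l/min (clinical convention for pump flow)
#: to ml/s (internal unit): 1 l/min = 1000 ml / 60 s.
ML_S_PER_L_MIN = 1000.0 / 60.0

#: Guard on the EDPVR exponent A_h * V_sh; beyond this the exponential
#: pressure exceeds any physiologic value and signals runaway volumes.
EDPVR_EXPONENT_CAP = 50.0


def l_min_to_ml_s(q_l_min: float) -> float:
    """Convert an extracorporeal flow from l/min to ml/s (exact 1000/60)."""
    return q_l_min * ML_S_PER_L_MIN


def ml_s_to_l_min(q_ml_s: float) -> float:
    """Convert an extracorporeal flow from ml/s to l/min."""
    return q_ml_s / ML_S_PER_L_MIN


class InfeasibleParameterError(RuntimeError):
    """Raised when a parameter set drives the model out of its physiologic
    domain (runaway volumes, EDPVR overflow, negative compartment volume)."""


def _require_positive(obj, names) -> None:
    for name in names:
        value = getattr(obj, name)
        if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
            raise ValueError(f"{type(obj).__name__}.{name} must be strictly positive, got {value!r}")


def _strict_from_dict(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class CVSParameters:
    """Full physical parameter set of the cardiovascular model.

    Five parameters are subject-specific and identified from data
    (``E_h``, ``A_h``, ``E_a``, ``R_s``, ``SBV``); the heart rate ``HR`` is
    measured directly; the remaining four default to literature values.

    Attributes
    ----------
    E_h : float
        Heart end-systolic elastance (ESPVR slope), mmHg/ml.
    A_h : float
        EDPVR exponential parameter, 1/ml.
    E_a : float
        Arterial elastance, mmHg/ml.
    R_s : float
        Systemic resistance, mmHg·s/ml.
    SBV : float
        Total stressed blood volume, ml.
    HR : float
        Heart rate, 1/s (beat period is ``1/HR``).
    B_h : float
        EDPVR pre-exponential parameter, mmHg (literature value).
    E_v : float
        Venous elastance, mmHg/ml (literature value).
    R_i : float
        Input-valve resistance, mmHg·s/ml (literature value).
    R_o : float
        Output-valve resistance, mmHg·s/ml (literature value).
    """

    E_h: float
    A_h: float
    E_a: float
    R_s: float
    SBV: float
    HR: float
    B_h: float = 0.35
    E_v: float = 0.014
    R_i: float = 0.015
    R_o: float = 0.03

    def __post_init__(self) -> None:
        _require_positive(self, (f.name for f in fields(self)))

    @property
    def period(self) -> float:
        """Cardiac period T = 1/HR, s."""
        return 1.0 / self.HR

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "CVSParameters":
        """Build from a mapping; unknown keys are rejected."""
        return _strict_from_dict(cls, data)

    def to_json(self) -> str:
        doc = {"units": {"E_h": "mmHg/ml", "A_h": "1/ml", "E_a": "mmHg/ml",
                         "R_s": "mmHg*s/ml", "SBV": "ml", "HR": "1/s",
                         "B_h": "mmHg", "E_v": "mmHg/ml",
                         "R_i": "mmHg*s/ml", "R_o": "mmHg*s/ml"},
               "values": self.to_dict()}
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CVSParameters":
        doc = json.loads(text)
        extra = set(doc) - {"units", "values"}
        if extra:
            raise ValueError(f"unknown top-level keys in parameter document: {sorted(extra)}")
        return cls.from_dict(doc["values"])


@dataclass(frozen=True)
class ECLSSetting:
    """Extracorporeal pump setting: the imposed blood flow Q_d in ml/s."""

    Q_d: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.Q_d) and self.Q_d >= 0):
            raise ValueError(f"Q_d must be finite and >= 0 ml/s, got {self.Q_d!r}")

    @classmethod
    def from_l_min(cls, q_l_min: float) -> "ECLSSetting":
        """Construct from a clinical flow in l/min (converted by 1000/60)."""
        return cls(Q_d=l_min_to_ml_s(q_l_min))

    @property
    def Q_d_l_min(self) -> float:
        return ml_s_to_l_min(self.Q_d)


@dataclass
class CVSState:
    """Stressed blood volumes of the three compartments, ml."""

    V_sh: float
    V_sa: float
    V_sv: float

    @classmethod
    def equal_split(cls, SBV: float) -> "CVSState":
        """Initial state with SBV split equally across the compartments."""
        return cls(SBV / 3.0, SBV / 3.0, SBV / 3.0)

    def as_array(self) -> np.ndarray:
        return np.array([self.V_sh, self.V_sa, self.V_sv], dtype=float)

    @property
    def total(self) -> float:
        return self.V_sh + self.V_sa + self.V_sv


@dataclass(frozen=True)
class DriverConfig:
    """Periodic cardiac activation e(t) = exp(-W (mod(t,T) - kappa*T)^2).

    ``W`` (1/s^2) sets the width of the systolic activation peak and
    ``kappa`` its position as a fraction of the beat period.  The Gaussian
    form follows the minimal closed-loop model family this model belongs to.
    """

    W: float = 80.0
    kappa: float = 0.375

    def __post_init__(self) -> None:
        if not (math.isfinite(self.W) and self.W > 0):
            raise ValueError(f"DriverConfig.W must be > 0, got {self.W!r}")
        if not (0.0 < self.kappa < 1.0):
            raise ValueError(f"DriverConfig.kappa must lie in (0, 1), got {self.kappa!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "DriverConfig":
        return _strict_from_dict(cls, data)


@dataclass(frozen=True)
class FlowSet:
    """Instantaneous flows, ml/s.  Valve flows Q_i, Q_o are unidirectional
    (>= 0); the systemic flow Q_s and the pump flow Q_d are pass-through."""

    Q_i: float
    Q_o: float
    Q_s: float
    Q_d: float


def driver_value(t, T: float, cfg: DriverConfig = DriverConfig()):
    """Cardiac activation at time ``t`` for beat period ``T``.

    Periodic with period T; equals 1 at the systolic peak ``t = kappa*T``
    (mod T) and decays as a Gaussian of width ``1/sqrt(W)`` around it.
    Accepts scalars or arrays.
    """
    if not T > 0:
        raise ValueError(f"beat period T must be > 0, got {T!r}")
    phase = np.mod(t, T) - cfg.kappa * T
    return np.exp(-cfg.W * phase * phase)


def heart_pressure(V_sh, e, p: CVSParameters):
    """Ventricular pressure from the time-varying elastance law, mmHg.

    ``P_h = e*E_h*V_sh + (1-e)*B_h*(exp(A_h*V_sh) - 1)``: at full activation
    (e = 1) this is the ESPVR, at rest (e = 0) the EDPVR.  Raises
    :class:`InfeasibleParameterError` when the EDPVR exponent exceeds the
    overflow guard, signalling runaway heart volumes.
    """
    exponent = np.asarray(p.A_h * np.asarray(V_sh, dtype=float))
    if np.any(exponent > EDPVR_EXPONENT_CAP):
        raise InfeasibleParameterError(
            f"EDPVR exponent A_h*V_sh = {float(np.max(exponent)):.1f} exceeds "
            f"{EDPVR_EXPONENT_CAP}: runaway heart volume")
    out = e * p.E_h * np.asarray(V_sh, dtype=float) + (1.0 - np.asarray(e)) * p.B_h * np.expm1(exponent)
    return float(out) if out.ndim == 0 else out


def chamber_pressures(state: CVSState, e, p: CVSParameters):
    """Pressures of the three compartments (P_h, P_a, P_v), mmHg."""
    P_h = heart_pressure(state.V_sh, e, p)
    return P_h, p.E_a * state.V_sa, p.E_v * state.V_sv


def compute_flows(P_h, P_a, P_v, p: CVSParameters, Q_d: float = 0.0) -> FlowSet:
    """Flows through the valves, the systemic circulation and the pump.

    Valves are ideal diodes with resistance: ``Q_o = max(0, P_h-P_a)/R_o``,
    ``Q_i = max(0, P_v-P_h)/R_i``.  The systemic flow may take either sign.
    """
    Q_o = np.maximum(0.0, np.asarray(P_h) - np.asarray(P_a)) / p.R_o
    Q_i = np.maximum(0.0, np.asarray(P_v) - np.asarray(P_h)) / p.R_i
    Q_s = (np.asarray(P_a) - np.asarray(P_v)) / p.R_s
    if Q_o.ndim == 0:
        return FlowSet(float(Q_i), float(Q_o), float(Q_s), Q_d)
    return FlowSet(Q_i, Q_o, Q_s, Q_d)


def rhs(t: float, state, p: CVSParameters, Q_d: float = 0.0,
        cfg: DriverConfig = DriverConfig()):
    """Right-hand side of the volume ODEs, ml/s.

    ``dV_sh/dt = Q_i - Q_o``; ``dV_sa/dt = Q_o - Q_s + Q_d``;
    ``dV_sv/dt = Q_s - Q_i - Q_d``.  The three derivatives sum to zero, so
    total stressed blood volume is conserved exactly.
    """
    V_sh, V_sa, V_sv = state[0], state[1], state[2]
    e = driver_value(t, p.period, cfg)
    P_h = heart_pressure(V_sh, e, p)
    P_a = p.E_a * V_sa
    P_v = p.E_v * V_sv
    f = compute_flows(P_h, P_a, P_v, p, Q_d)
    return np.array([f.Q_i - f.Q_o, f.Q_o - f.Q_s + f.Q_d, f.Q_s - f.Q_i - f.Q_d])


def make_scalar_rhs(p: CVSParameters, Q_d: float, cfg: DriverConfig):
    """Closure over plain floats for fast repeated integration.

    Semantically identical to :func:`rhs`; avoids per-call attribute lookups
    and array construction inside the ODE solver's inner loop.
    """
    E_h, A_h, B_h, E_a, E_v = p.E_h, p.A_h, p.B_h, p.E_a, p.E_v
    R_i, R_o, R_s = p.R_i, p.R_o, p.R_s
    W, kT = cfg.W, cfg.kappa * p.period
    T = p.period
    cap = EDPVR_EXPONENT_CAP

    def f(t, y):
        V_sh = y[0]
        phase = (t % T) - kT
        e = math.exp(-W * phase * phase)
        x = A_h * V_sh
        if x > cap:
            raise InfeasibleParameterError(
                f"EDPVR exponent A_h*V_sh = {x:.1f} exceeds {cap}: runaway heart volume")
        P_h = e * E_h * V_sh + (1.0 - e) * B_h * math.expm1(x)
        P_a = E_a * y[1]
        P_v = E_v * y[2]
        Q_o = (P_h - P_a) / R_o if P_h > P_a else 0.0
        Q_i = (P_v - P_h) / R_i if P_v > P_h else 0.0
        Q_s = (P_a - P_v) / R_s
        return (Q_i - Q_o, Q_o - Q_s + Q_d, Q_s - Q_i - Q_d)

    return f
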