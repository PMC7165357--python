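"""Patient-specific parameter identification by weighted least squares.

Two fits are supported:

* **single flow** — at one fixed extracorporeal flow, the five
  subject-specific parameters (E_h, A_h, E_a, R_s, SBV) are estimated by
  minimizing the weighted sum of squared observable residuals
  ``Psi(p) = sum_k ((y_k^data - y_k^model(p)) / sigma_k)^2``;

* **weaning test** — across n flow levels, each parameter is assumed to
  respond linearly to the pump flow (a phenomenological stand-in for the
  body's control mechanisms), ``param(Q_d) = slope*Q_d + intercept``, and the
  ten slope/intercept coefficients are estimated from the pooled residuals
  over all flow levels.

Both fits run `scipy.optimize.least_squares` (trust-region reflective) on
log-transformed positive parameters, so positivity holds by construction and
the sum-of-squares structure is exploited; multi-starts guard against local
minima.  Forward model evaluations warm-start the limit-cycle search from
the previously converged state, which makes a fit cost tens rather than
thousands of beat integrations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, asdict

import numpy as np
from scipy.optimize import least_squares

from .model import CVSParameters, DriverConfig, InfeasibleParameterError
from .simulate import MeasurementVector, SimulationSettings, steady_state_observables

__all__ = [
    "NoiseWeights",
    "FreeParameterSet",
    "ControlCoefficients",
    "WeaningRecord",
    "WeaningDataset",
    "FitResult",
    "objective_psi",
    "identify_single_flow",
    "objective_psi_weaning",
    "identify_weaning",
    "dataset_model_observables",
    "DEFAULT_INITIAL_GUESS",
]

#: Residual magnitude substituted when the forward model is infeasible; large
#: but finite so the optimizer can retreat instead of crashing.
_PENALTY = 1.0e4


@dataclass(frozen=True)
class NoiseWeights:
    """Per-observable measurement standard errors sigma_k.

    Defaults are the study-wide constants obtained by averaging per-record
    beat-to-beat standard deviations over all weaning tests: 2 ml for
    max V_h, 0.4 mmHg for PP_a, 0.2 mmHg for mean P_a, 0.1 mmHg for mean
    P_v, 3 ml for SV.  For raw per-beat data, recompute with
    :meth:`from_beats`.
    """

    sigma_maxVh: float = 2.0
    sigma_PPa: float = 0.4
    sigma_Pa: float = 0.2
    sigma_Pv: float = 0.1
    sigma_SV: float = 3.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"NoiseWeights.{f.name} must be > 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        """Sigmas ordered like the observable vector
        (P_a_mean, PP_a, P_v_mean, maxV_h, SV)."""
        return np.array([self.sigma_Pa, self.sigma_PPa, self.sigma_Pv,
                         self.sigma_maxVh, self.sigma_SV])

    @classmethod
    def unit(cls) -> "NoiseWeights":
        """Unit weights for sigma-less datasets (plain least squares)."""
        return cls(1.0, 1.0, 1.0, 1.0, 1.0)

    @classmethod
    def from_beats(cls, beat_observables) -> "NoiseWeights":
        """Recompute sigmas as the standard deviations of per-beat
        observables (rows ordered like the observable vector)."""
        arr = np.asarray(beat_observables, float)
        if arr.ndim != 2 or arr.shape[1] != 5 or arr.shape[0] < 2:
            raise ValueError("need a (n_beats >= 2, 5) array of per-beat observables")
        sd = arr.std(axis=0, ddof=1)
        return cls(sigma_Pa=sd[0], sigma_PPa=sd[1], sigma_Pv=sd[2],
                   sigma_maxVh=sd[3], sigma_SV=sd[4])


@dataclass(frozen=True)
class FreeParameterSet:
    """The five subject-specific parameters estimated from data."""

    E_h: float
    A_h: float
    E_a: float
    R_s: float
    SBV: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"FreeParameterSet.{f.name} must be > 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.E_h, self.A_h, self.E_a, self.R_s, self.SBV])

    @classmethod
    def from_array(cls, arr) -> "FreeParameterSet":
        return cls(*(float(v) for v in arr))

    def to_cvs(self, HR: float, **fixed) -> CVSParameters:
        """Combine with heart rate and (optionally overridden) literature
        constants into a full :class:`CVSParameters`."""
        return CVSParameters(E_h=self.E_h, A_h=self.A_h, E_a=self.E_a,
                             R_s=self.R_s, SBV=self.SBV, HR=HR, **fixed)

    parameter_names = ("E_h", "A_h", "E_a", "R_s", "SBV")


#: Physiologic starting point for single-flow fits: the mean identified
#: baseline parameters of eight healthy anesthetized pigs.
DEFAULT_INITIAL_GUESS = FreeParameterSet(E_h=1.53, A_h=0.039, E_a=1.44,
                                         R_s=1.59, SBV=1069.0)


@dataclass(frozen=True)
class ControlCoefficients:
    """Slopes and intercepts of the linear flow-response of each parameter.

    ``param(Q_d) = slope * Q_d + intercept`` with Q_d in ml/s.  The
    intercepts are the parameter values extrapolated to zero extracorporeal
    flow and must be positive; slopes may take either sign (they encode the
    direction of the physiological control response).
    """

    E_0_h: float     # mmHg/ml
    A_0_h: float     # 1/ml
    E_0_a: float     # mmHg/ml
    R_0_s: float     # mmHg*s/ml
    SBV_0: float     # ml
    E_Sl_h: float    # mmHg*s/ml^2
    A_Sl_h: float    # s/ml^2
    E_Sl_a: float    # mmHg*s/ml^2
    R_Sl_s: float    # mmHg*s^2/ml^2
    SBV_Sl: float    # s

    def __post_init__(self) -> None:
        for name in ("E_0_h", "A_0_h", "E_0_a", "R_0_s", "SBV_0"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"ControlCoefficients.{name} (intercept) must be > 0, got {v!r}")
        for name in ("E_Sl_h", "A_Sl_h", "E_Sl_a", "R_Sl_s", "SBV_Sl"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"ControlCoefficients.{name} must be finite")

    def intercepts(self) -> np.ndarray:
        """Intercepts ordered like FreeParameterSet (E_h, A_h, E_a, R_s, SBV)."""
        return np.array([self.E_0_h, self.A_0_h, self.E_0_a, self.R_0_s, self.SBV_0])

    def slopes(self) -> np.ndarray:
        """Slopes (per ml/s) in the same order."""
        return np.array([self.E_Sl_h, self.A_Sl_h, self.E_Sl_a, self.R_Sl_s, self.SBV_Sl])

    def at_flow(self, Q_d: float) -> FreeParameterSet:
        """Evaluate the linear laws at ``Q_d`` (ml/s).

        Raises ValueError naming the offending parameter if any mapped value
        is non-positive (the linear description is being extrapolated
        outside its validity range).
        """
        vals = self.slopes() * Q_d + self.intercepts()
        for name, v in zip(FreeParameterSet.parameter_names, vals):
            if not v > 0:
                raise ValueError(
                    f"mapped parameter {name} = {v:.4g} is non-positive at "
                    f"Q_d = {Q_d:.4g} ml/s: linear control law extrapolated "
                    "outside its validity range")
        return FreeParameterSet.from_array(vals)

    @classmethod
    def from_arrays(cls, intercepts, slopes) -> "ControlCoefficients":
        i, s = np.asarray(intercepts, float), np.asarray(slopes, float)
        return cls(E_0_h=i[0], A_0_h=i[1], E_0_a=i[2], R_0_s=i[3], SBV_0=i[4],
                   E_Sl_h=s[0], A_Sl_h=s[1], E_Sl_a=s[2], R_Sl_s=s[3], SBV_Sl=s[4])

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class WeaningRecord:
    """One flow level of a weaning test: pump flow (ml/s), heart rate (1/s)
    and the averaged observable vector."""

    Q_d: float
    HR: float
    y: MeasurementVector


@dataclass
class WeaningDataset:
    """Ordered per-flow records of one weaning test for one subject."""

    records: list
    subject: str = ""
    test: str = ""
    noradrenaline_ug_min: float | None = None

    def __post_init__(self) -> None:
        if len(self.records) < 1:
            raise ValueError("WeaningDataset needs at least one record")
        qd = [r.Q_d for r in self.records]
        if len(set(qd)) != len(qd):
            raise ValueError("Q_d values in a weaning dataset must be distinct")

    @property
    def n(self) -> int:
        return len(self.records)

    def flows(self) -> np.ndarray:
        return np.array([r.Q_d for r in self.records])

    def heart_rates(self) -> np.ndarray:
        return np.array([r.HR for r in self.records])


@dataclass
class FitResult:
    """Outcome of an identification run.

    ``residuals`` holds the sigma-weighted residual matrix (records x 5
    observables) at the optimum; ``psi`` is its squared Frobenius norm, the
    value of the weighted objective.
    """

    estimate: object
    psi: float
    n_function_evals: int
    converged: bool
    residuals: np.ndarray
    sigma: NoiseWeights
    seed: int | None = None
    message: str = ""

    def __post_init__(self) -> None:
        if self.psi < 0:
            raise ValueError("psi must be >= 0")


def _validate_complete(y: MeasurementVector) -> None:
    for name, v in zip(MeasurementVector.component_names, y.as_array()):
        if v is None or not math.isfinite(v):
            raise ValueError(f"observable component {name!r} is missing or non-finite")


def _forward(free: FreeParameterSet, Q_d, HR, fixed, settings, cfg, warm,
             jac_cache=None):
    p = free.to_cvs(HR, **fixed)
    obs, y0, _ = steady_state_observables(p, Q_d, settings, cfg,
                                          warm_state=warm, jac_cache=jac_cache)
    return obs, y0


def objective_psi(free: FreeParameterSet, y_data: MeasurementVector,
                  weights: NoiseWeights | None = None, *, Q_d: float, HR: float,
                  fixed: dict | None = None,
                  settings: SimulationSettings | None = None,
                  cfg: DriverConfig | None = None) -> float:
    """Weighted single-flow objective Psi(p).

    Forward-simulates to the limit cycle at (Q_d, HR), extracts the model
    observables and returns the sum of squared sigma-weighted residuals.
    Infeasible parameters yield a large finite penalty instead of raising.
    """
    weights = weights or NoiseWeights()
    _validate_complete(y_data)
    try:
        obs, _ = _forward(free, Q_d, HR, fixed or {}, settings, cfg, None)
    except (InfeasibleParameterError, ValueError):
        return float(5 * _PENALTY ** 2)
    r = (y_data.as_array() - obs.as_array()) / weights.as_array()
    return float(np.dot(r, r))


def _sample_starts(x0: np.ndarray, n_starts: int, spread: float, rng) -> list:
    starts = [x0]
    for _ in range(max(0, n_starts - 1)):
        starts.append(x0 + rng.uniform(np.log(1.0 - spread), np.log(1.0 + spread), size=x0.size))
    return starts


def identify_single_flow(y_data: MeasurementVector, *, Q_d: float, HR: float,
                         weights: NoiseWeights | None = None,
                         fixed: dict | None = None,
                         x0: FreeParameterSet | None = None,
                         n_starts: int = 5, spread: float = 0.5, seed: int = 0,
                         settings: SimulationSettings | None = None,
                         cfg: DriverConfig | None = None,
                         diff_step: float = 1e-3,
                         max_nfev: int = 200) -> FitResult:
    """Estimate the five subject-specific parameters at one flow level.

    Multi-start weighted least squares on log-transformed parameters: the
    first start is the physiologic initial guess (or ``x0``), the remaining
    ``n_starts - 1`` are drawn log-uniformly within ``1 +/- spread`` of it
    (seeded, reproducible).  Returns the best :class:`FitResult`.
    """
    weights = weights or NoiseWeights()
    fixed = fixed or {}
    _validate_complete(y_data)
    sig = weights.as_array()
    target = y_data.as_array()
    guess = (x0 or DEFAULT_INITIAL_GUESS).as_array()
    rng = np.random.default_rng(seed)
    starts = _sample_starts(np.log(guess), n_starts, spread, rng)

    best = None
    total_nfev = 0
    for start in starts:
        # warm state frozen per start: residuals stay a deterministic
        # function of x while nearby evaluations need only a few beats
        jac_cache = {}
        try:
            _, warm_y0 = _forward(FreeParameterSet.from_array(np.exp(start)),
                                  Q_d, HR, fixed, settings, cfg, None, jac_cache)
        except (InfeasibleParameterError, ValueError):
            warm_y0 = None

        def residual(x):
            free = FreeParameterSet.from_array(np.exp(x))
            try:
                obs, _ = _forward(free, Q_d, HR, fixed, settings, cfg, warm_y0,
                                  jac_cache)
            except (InfeasibleParameterError, ValueError):
                return np.full(5, _PENALTY)
            return (obs.as_array() - target) / sig

        res = least_squares(residual, start, method="trf", diff_step=diff_step,
                            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=max_nfev)
        total_nfev += res.nfev
        psi = float(2.0 * res.cost)
        if best is None or psi < best[0]:
            best = (psi, res)
        if psi < 1e-8:     # perfect fit found; further starts are redundant
            break

    psi, res = best
    estimate = FreeParameterSet.from_array(np.exp(res.x))
    feasible = bool(np.all(np.abs(res.fun) < _PENALTY))
    return FitResult(estimate=estimate, psi=psi, n_function_evals=total_nfev,
                     converged=bool(res.status > 0 and feasible),
                     residuals=res.fun.reshape(1, 5), sigma=weights, seed=seed,
                     message=res.message)


def objective_psi_weaning(coeffs: ControlCoefficients, data: WeaningDataset,
                          weights: NoiseWeights | None = None, *,
                          fixed: dict | None = None,
                          settings: SimulationSettings | None = None,
                          cfg: DriverConfig | None = None) -> float:
    """Pooled weaning objective Psi(c): the single-flow objective accumulated
    over every (Q_d, HR) record with parameters mapped through the linear
    control laws."""
    weights = weights or NoiseWeights()
    total = 0.0
    for rec in data.records:
        try:
            free = coeffs.at_flow(rec.Q_d)
        except ValueError:
            total += float(5 * _PENALTY ** 2)
            continue
        total += objective_psi(free, rec.y, weights, Q_d=rec.Q_d, HR=rec.HR,
                               fixed=fixed, settings=settings, cfg=cfg)
    return total


def _seed_coefficients(data: WeaningDataset, weights, fixed, settings, cfg,
                       seed) -> tuple[np.ndarray, np.ndarray]:
    """Data-driven seed: single-flow fits at the lowest and highest flow
    levels, then exact line through the two fitted parameter sets."""
    order = np.argsort(data.flows())
    lo, hi = data.records[order[0]], data.records[order[-1]]
    fit_lo = identify_single_flow(lo.y, Q_d=lo.Q_d, HR=lo.HR, weights=weights,
                                  fixed=fixed, settings=settings, cfg=cfg,
                                  n_starts=2, seed=seed)
    fit_hi = identify_single_flow(hi.y, Q_d=hi.Q_d, HR=hi.HR, weights=weights,
                                  fixed=fixed, settings=settings, cfg=cfg,
                                  x0=fit_lo.estimate, n_starts=2, seed=seed + 1)
    p_lo, p_hi = fit_lo.estimate.as_array(), fit_hi.estimate.as_array()
    span = hi.Q_d - lo.Q_d
    if span > 0:
        slopes = (p_hi - p_lo) / span
        intercepts = p_lo - slopes * lo.Q_d
    else:       # degenerate: all records at the same flow
        slopes = np.zeros(5)
        intercepts = p_lo
    bad = intercepts <= 0
    if np.any(bad):     # fall back to flat laws through the low-flow fit
        slopes[bad] = 0.0
        intercepts[bad] = p_lo[bad]
    return intercepts, slopes


def identify_weaning(data: WeaningDataset, *,
                     weights: NoiseWeights | None = None,
                     fixed: dict | None = None,
                     settings: SimulationSettings | None = None,
                     cfg: DriverConfig | None = None,
                     n_starts: int = 1, spread: float = 0.2, seed: int = 0,
                     diff_step: float = 1e-3,
                     max_nfev: int = 400) -> FitResult:
    """Estimate the ten control coefficients from a weaning test.

    Requires at least two flow levels (ten unknowns against five observables
    per level); two levels make the system exactly determined, so a warning
    is issued and three or more are recommended.  The joint fit is seeded by
    single-flow fits at the extreme flows; optional extra multi-starts
    jitter that seed.
    """
    weights = weights or NoiseWeights()
    fixed = fixed or {}
    if data.n < 2:
        raise ValueError(
            "weaning identification needs records at >= 2 distinct flows: "
            "10 coefficients cannot be identified from 5 observables")
    if data.n == 2:
        warnings.warn("only 2 flow levels: the 10-coefficient fit is exactly "
                      "determined and noise-sensitive; n >= 3 is recommended",
                      stacklevel=2)
    for rec in data.records:
        _validate_complete(rec.y)

    sig = weights.as_array()
    q = data.flows()
    q_ref = float(q.max()) if q.max() > 0 else 1.0
    targets = np.stack([r.y.as_array() for r in data.records])

    i_seed, s_seed = _seed_coefficients(data, weights, fixed, settings, cfg, seed)
    ref = i_seed.copy()     # fixed scaling constants for the slope coordinates

    def unpack(x):
        intercepts = np.exp(x[:5])
        slopes = x[5:] * ref / q_ref
        return ControlCoefficients.from_arrays(intercepts, slopes)

    x_seed = np.concatenate([np.log(i_seed), s_seed * q_ref / ref])
    rng = np.random.default_rng(seed)
    starts = [x_seed]
    for _ in range(max(0, n_starts - 1)):
        jitter = rng.uniform(-spread, spread, size=10)
        starts.append(x_seed + jitter)

    best = None
    total_nfev = 0
    for start in starts:
        # frozen per-record warm states (see identify_single_flow)
        warm = {}
        jac_caches = {rec.Q_d: {} for rec in data.records}
        start_coeffs = unpack(start)
        for rec in data.records:
            try:
                _, warm[rec.Q_d] = _forward(start_coeffs.at_flow(rec.Q_d),
                                            rec.Q_d, rec.HR, fixed, settings,
                                            cfg, None, jac_caches[rec.Q_d])
            except (InfeasibleParameterError, ValueError):
                warm[rec.Q_d] = None

        def residual(x):
            coeffs = unpack(x)
            rows = np.empty((data.n, 5))
            for j, rec in enumerate(data.records):
                try:
                    free = coeffs.at_flow(rec.Q_d)
                except ValueError:
                    vals = coeffs.slopes() * rec.Q_d + coeffs.intercepts()
                    deficit = float(np.sum(np.maximum(0.0, -vals) / np.maximum(ref, 1e-12)))
                    rows[j] = _PENALTY * (1.0 + deficit)
                    continue
                try:
                    obs, _ = _forward(free, rec.Q_d, rec.HR, fixed, settings,
                                      cfg, warm.get(rec.Q_d),
                                      jac_caches[rec.Q_d])
                except (InfeasibleParameterError, ValueError):
                    rows[j] = _PENALTY
                    continue
                rows[j] = (obs.as_array() - targets[j]) / sig
            return rows.ravel()

        res = least_squares(residual, start, method="trf", diff_step=diff_step,
                            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=max_nfev)
        total_nfev += res.nfev
        psi = float(2.0 * res.cost)
        if best is None or psi < best[0]:
            best = (psi, res)
        if psi < 1e-8:
            break

    psi, res = best
    estimate = unpack(res.x)
    feasible = bool(np.all(np.abs(res.fun) < _PENALTY))
    return FitResult(estimate=estimate, psi=psi, n_function_evals=total_nfev,
                     converged=bool(res.status > 0 and feasible),
                     residuals=res.fun.reshape(data.n, 5), sigma=weights,
                     seed=seed, message=res.message)


def dataset_model_observables(coeffs: ControlCoefficients, data: WeaningDataset,
                              fixed: dict | None = None,
                              settings: SimulationSettings | None = None,
                              cfg: DriverConfig | None = None) -> list:
    """Model observable vectors at each record's (Q_d, HR) under the fitted
    control coefficients — the simulated side of an error report."""
    out = []
    warm = None
    for rec in data.records:
        obs, warm = _forward(coeffs.at_flow(rec.Q_d), rec.Q_d, rec.HR,
                             fixed or {}, settings, cfg, warm)
        out.append(obs)
    return out
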