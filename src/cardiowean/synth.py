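"""Synthetic weaning-test data with the statistical structure the analysis
assumes.

A scenario fixes the true flow-response coefficients, a heart-rate profile,
a flow schedule and a measurement-noise model.  For each scheduled flow the
generator maps the coefficients to the physical parameters, simulates the
limit cycle, and emulates the measurement protocol: independent Gaussian
per-beat noise on each observable (maximum-entropy choice given that only
standard errors are known) averaged over ``n_beats_averaged`` beats, which
is how real records are reduced (the reported observables are means over
the recorded beats).  Ground truth is returned alongside, so recovery can
be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import (PORCINE_BASELINE_MEAN, POSTARREST_MEAN_COEFFS,
                       WEANING_EXAMPLE_COEFFS)
from .identify import (ControlCoefficients, FreeParameterSet, NoiseWeights,
                       WeaningDataset, WeaningRecord)
from .model import DriverConfig, l_min_to_ml_s
from .simulate import (MeasurementVector, SimulationSettings,
                       steady_state_observables)

__all__ = [
    "HRProfile",
    "ScenarioSpec",
    "GroundTruth",
    "GroundTruthRecord",
    "default_scenario",
    "generate_weaning_dataset",
    "noise_free_records",
    "apply_measurement_noise",
    "SCENARIO_NAMES",
]


@dataclass(frozen=True)
class HRProfile:
    """Linear heart-rate dependence on pump flow: HR(Q_d) = intercept +
    slope*Q_d (1/s, Q_d in ml/s).  Slope 0 gives a constant heart rate."""

    intercept: float
    slope: float = 0.0

    def __call__(self, Q_d: float) -> float:
        hr = self.intercept + self.slope * Q_d
        if not hr > 0:
            raise ValueError(f"HR profile gives non-positive heart rate at Q_d={Q_d}")
        return hr


def _decreasing_schedule(start_l_min: float, n_levels: int, step: float = 0.85):
    """Flow schedule emulating the weaning protocol: from ``start_l_min``
    decreasing ~15% per step, in ml/s."""
    return tuple(l_min_to_ml_s(start_l_min) * step ** k for k in range(n_levels))


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete specification of a synthetic weaning experiment."""

    name: str
    true_coefficients: ControlCoefficients
    hr_profile: HRProfile
    flow_schedule: tuple     # ml/s, distinct, non-negative
    n_beats_averaged: int = 10
    noise: NoiseWeights = field(default_factory=NoiseWeights)
    seed: int = 0
    noradrenaline_ug_min: float = 0.0

    def __post_init__(self) -> None:
        q = tuple(self.flow_schedule)
        if len(q) < 1 or len(set(q)) != len(q):
            raise ValueError("flow_schedule must be non-empty with distinct values")
        if any(v < 0 or not math.isfinite(v) for v in q):
            raise ValueError("flow_schedule values must be finite and >= 0")
        if self.n_beats_averaged < 1:
            raise ValueError("n_beats_averaged must be >= 1")


def _flat_coeffs(p: FreeParameterSet) -> ControlCoefficients:
    return ControlCoefficients(
        E_0_h=p.E_h, A_0_h=p.A_h, E_0_a=p.E_a, R_0_s=p.R_s, SBV_0=p.SBV,
        E_Sl_h=0.0, A_Sl_h=0.0, E_Sl_a=0.0, R_Sl_s=0.0, SBV_Sl=0.0)


SCENARIO_NAMES = ("pig_like_healthy", "pig_like_postarrest", "failing_heart",
                  "porcine_weaning_example")

#: Heart-rate profile of the post-arrest scenarios: ~1.32 /s under full
#: support, rising to 1.45 /s as the support is removed.
_POSTARREST_HR = HRProfile(intercept=1.45, slope=-0.002)


def default_scenario(name: str, seed: int = 0) -> ScenarioSpec:
    """Fully specified stock scenarios.

    * ``pig_like_healthy`` — flow-independent parameters equal to the mean
      healthy porcine baseline; a single record at Q_d = 0 (baseline
      emulation), constant HR 1.32 /s.
    * ``pig_like_postarrest`` — cohort-mean post-arrest coefficients;
      5 flow levels from 4 l/min decreasing ~15 % per step.
    * ``porcine_weaning_example`` — coefficients of one representative
      post-arrest weaning test; 5 levels from 2 l/min (the flow range the
      porcine experiments actually reached).
    * ``failing_heart`` — the post-arrest cohort means with the zero-flow
      contractility E_0,h reduced 4-fold; 5 levels from 2 l/min.
    """
    base = PORCINE_BASELINE_MEAN
    if name == "pig_like_healthy":
        free = FreeParameterSet(E_h=base.E_h, A_h=base.A_h, E_a=base.E_a,
                                R_s=base.R_s, SBV=base.SBV)
        return ScenarioSpec(name=name, true_coefficients=_flat_coeffs(free),
                            hr_profile=HRProfile(intercept=base.HR),
                            flow_schedule=(0.0,), seed=seed)
    if name == "pig_like_postarrest":
        return ScenarioSpec(name=name, true_coefficients=POSTARREST_MEAN_COEFFS,
                            hr_profile=_POSTARREST_HR,
                            flow_schedule=_decreasing_schedule(4.0, 5), seed=seed)
    if name == "porcine_weaning_example":
        return ScenarioSpec(name=name, true_coefficients=WEANING_EXAMPLE_COEFFS,
                            hr_profile=_POSTARREST_HR,
                            flow_schedule=_decreasing_schedule(2.0, 5), seed=seed)
    if name == "failing_heart":
        weak = replace(POSTARREST_MEAN_COEFFS, E_0_h=POSTARREST_MEAN_COEFFS.E_0_h / 4.0)
        return ScenarioSpec(name=name, true_coefficients=weak,
                            hr_profile=_POSTARREST_HR,
                            flow_schedule=_decreasing_schedule(2.0, 5), seed=seed)
    raise ValueError(f"unknown scenario {name!r}; known: {SCENARIO_NAMES}")


@dataclass(frozen=True)
class GroundTruthRecord:
    Q_d: float
    HR: float
    params: FreeParameterSet
    y_true: MeasurementVector


@dataclass(frozen=True)
class GroundTruth:
    """Exact generating quantities of a synthetic dataset."""

    coefficients: ControlCoefficients
    records: tuple


def noise_free_records(spec: ScenarioSpec,
                       settings: SimulationSettings | None = None,
                       cfg: DriverConfig | None = None,
                       fixed: dict | None = None) -> GroundTruth:
    """Forward-simulate the exact observables at every scheduled flow."""
    out = []
    warm = None
    for q in spec.flow_schedule:
        free = spec.true_coefficients.at_flow(q)
        hr = spec.hr_profile(q)
        obs, warm, _ = steady_state_observables(
            free.to_cvs(hr, **(fixed or {})), q, settings, cfg, warm_state=warm)
        out.append(GroundTruthRecord(Q_d=q, HR=hr, params=free, y_true=obs))
    return GroundTruth(coefficients=spec.true_coefficients, records=tuple(out))


def apply_measurement_noise(truth: GroundTruth, noise: NoiseWeights,
                            n_beats_averaged: int, rng) -> list:
    """Emulate the measurement reduction: per-beat Gaussian noise with the
    given sigmas, averaged over the recorded beats.  Returns the noisy
    MeasurementVector list (one per record)."""
    sig = noise.as_array()
    noisy = []
    for rec in truth.records:
        beats = rec.y_true.as_array() + rng.normal(0.0, sig, size=(n_beats_averaged, 5))
        noisy.append(MeasurementVector.from_array(beats.mean(axis=0)))
    return noisy


def generate_weaning_dataset(spec: ScenarioSpec, seed: int | None = None,
                             settings: SimulationSettings | None = None,
                             cfg: DriverConfig | None = None,
                             fixed: dict | None = None):
    """Generate one synthetic weaning dataset plus its ground truth.

    Fully reproducible: the RNG is seeded from ``seed`` (default
    ``spec.seed``).  With all sigmas effectively zero the dataset equals the
    noise-free forward observables.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    truth = noise_free_records(spec, settings, cfg, fixed)
    noisy = apply_measurement_noise(truth, spec.noise, spec.n_beats_averaged, rng)
    records = [WeaningRecord(Q_d=t.Q_d, HR=t.HR, y=y)
               for t, y in zip(truth.records, noisy)]
    dataset = WeaningDataset(records=records, subject=spec.name, test="synthetic",
                             noradrenaline_ug_min=spec.noradrenaline_ug_min)
    return dataset, truth
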