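"""File formats: the weaning-dataset CSV schema and JSON documents for
configurations, fit results, predictions and error reports.

The CSV stores the pump flow in l/min (the clinical convention); the
internal unit is ml/s and the conversion is the exact rational 1000/60.
All formats are plain text; JSON outputs embed the inputs used, for
provenance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .identify import (ControlCoefficients, FitResult, FreeParameterSet,
                       NoiseWeights, WeaningDataset, WeaningRecord)
from .model import CVSParameters, DriverConfig, l_min_to_ml_s, ml_s_to_l_min
from .simulate import MeasurementVector, SimulationSettings
from .weaning import WeaningPrediction, WeaningThresholds

__all__ = [
    "CSV_COLUMNS",
    "read_weaning_csv",
    "write_weaning_csv",
    "write_fit_json",
    "read_coefficients_json",
    "write_prediction_json",
    "RunConfig",
]

CSV_COLUMNS = ["subject", "test", "Qd_l_min", "HR_per_s", "Pa_mean_mmHg",
               "PPa_mmHg", "Pv_mean_mmHg", "maxVh_ml", "SV_ml",
               "noradrenaline_ug_min"]

_NUMERIC = CSV_COLUMNS[2:]


def read_weaning_csv(path) -> WeaningDataset:
    """Read one weaning test from CSV with strict header validation.

    Malformed rows are reported with their file line number; an empty data
    section is an error ("no records").
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s) {missing} in {path}")
    extra = [c for c in df.columns if c not in CSV_COLUMNS]
    if extra:
        raise ValueError(f"unknown column(s) {extra} in {path}")
    if len(df) == 0:
        raise ValueError(f"no records in {path}")

    records = []
    nora = None
    for i, row in df.iterrows():
        line = i + 2        # header is line 1
        vals = {}
        for col in _NUMERIC:
            text = row[col].strip()
            if col == "noradrenaline_ug_min" and text == "":
                vals[col] = math.nan
                continue
            try:
                vals[col] = float(text)
            except ValueError:
                raise ValueError(
                    f"{path} line {line}: column {col!r} has non-numeric value {text!r}") from None
        y = MeasurementVector(P_a_mean=vals["Pa_mean_mmHg"], PP_a=vals["PPa_mmHg"],
                              P_v_mean=vals["Pv_mean_mmHg"], maxV_h=vals["maxVh_ml"],
                              SV=vals["SV_ml"])
        records.append(WeaningRecord(Q_d=l_min_to_ml_s(vals["Qd_l_min"]),
                                     HR=vals["HR_per_s"], y=y))
        if not math.isnan(vals["noradrenaline_ug_min"]):
            nora = vals["noradrenaline_ug_min"]
    return WeaningDataset(records=records,
                          subject=str(df["subject"].iloc[0]),
                          test=str(df["test"].iloc[0]),
                          noradrenaline_ug_min=nora)


def write_weaning_csv(dataset: WeaningDataset, path) -> None:
    """Write a weaning dataset in the canonical CSV schema (lossless
    round trip through :func:`read_weaning_csv` for all numeric fields)."""
    rows = []
    for rec in dataset.records:
        rows.append({
            "subject": dataset.subject, "test": dataset.test,
            "Qd_l_min": repr(ml_s_to_l_min(rec.Q_d)), "HR_per_s": repr(rec.HR),
            "Pa_mean_mmHg": repr(rec.y.P_a_mean), "PPa_mmHg": repr(rec.y.PP_a),
            "Pv_mean_mmHg": repr(rec.y.P_v_mean), "maxVh_ml": repr(rec.y.maxV_h),
            "SV_ml": repr(rec.y.SV),
            "noradrenaline_ug_min": "" if dataset.noradrenaline_ug_min is None
                                    else repr(dataset.noradrenaline_ug_min),
        })
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def _estimate_to_dict(estimate) -> dict:
    d = asdict(estimate)
    d["__type__"] = type(estimate).__name__
    return d


def write_fit_json(result: FitResult, path, config: dict | None = None) -> None:
    """Serialize a fit result (estimate, objective value, residual table,
    sigmas, seed) plus the configuration used."""
    doc = {
        "estimate": _estimate_to_dict(result.estimate),
        "psi": result.psi,
        "n_function_evals": result.n_function_evals,
        "converged": result.converged,
        "residuals": np.asarray(result.residuals).tolist(),
        "residual_components": list(MeasurementVector.component_names),
        "sigma": asdict(result.sigma),
        "seed": result.seed,
        "message": result.message,
        "config": config or {},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def read_coefficients_json(path) -> ControlCoefficients:
    """Load control coefficients from a fit JSON written by
    :func:`write_fit_json`."""
    with open(path) as fh:
        doc = json.load(fh)
    est = dict(doc["estimate"])
    kind = est.pop("__type__", "ControlCoefficients")
    if kind != "ControlCoefficients":
        raise ValueError(f"fit file {path} holds a {kind}, not ControlCoefficients")
    return ControlCoefficients(**est)


def write_prediction_json(pred: WeaningPrediction, path,
                          config: dict | None = None) -> None:
    doc = pred.to_dict()
    doc["config"] = config or {}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def _strict(cls, data, label):
    import dataclasses
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown keys in {label}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class RunConfig:
    """Bundled configuration for a pipeline run: literature-fixed model
    parameters, activation driver, simulation settings, measurement sigmas,
    weaning thresholds and the RNG seed.  Defaults carry the literature /
    study-wide values documented on each component class."""

    fixed: dict = field(default_factory=dict)     # overrides for B_h, E_v, R_i, R_o
    driver: DriverConfig = field(default_factory=DriverConfig)
    settings: SimulationSettings = field(default_factory=SimulationSettings)
    weights: NoiseWeights = field(default_factory=NoiseWeights)
    thresholds: WeaningThresholds = field(default_factory=WeaningThresholds)
    seed: int = 0

    _FIXED_KEYS = ("B_h", "E_v", "R_i", "R_o")

    def __post_init__(self) -> None:
        unknown = set(self.fixed) - set(self._FIXED_KEYS)
        if unknown:
            raise ValueError(f"unknown fixed-parameter keys: {sorted(unknown)}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = json.load(fh)
        known = {"fixed", "driver", "settings", "weights", "thresholds", "seed"}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown keys in run config {path}: {sorted(unknown)}")
        kwargs = {}
        if "fixed" in doc:
            kwargs["fixed"] = doc["fixed"]
        if "driver" in doc:
            kwargs["driver"] = _strict(DriverConfig, doc["driver"], "driver")
        if "settings" in doc:
            d = dict(doc["settings"])
            if "initial_state" in d and d["initial_state"] is not None:
                d["initial_state"] = tuple(d["initial_state"])
            kwargs["settings"] = _strict(SimulationSettings, d, "settings")
        if "weights" in doc:
            kwargs["weights"] = _strict(NoiseWeights, doc["weights"], "weights")
        if "thresholds" in doc:
            kwargs["thresholds"] = _strict(WeaningThresholds, doc["thresholds"], "thresholds")
        if "seed" in doc:
            kwargs["seed"] = int(doc["seed"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {"fixed": dict(self.fixed), "driver": asdict(self.driver),
                "settings": asdict(self.settings), "weights": asdict(self.weights),
                "thresholds": asdict(self.thresholds), "seed": self.seed}
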