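"""Error metrics for model-vs-data comparison.

The headline statistic is the mean relative error per observable over the
flow levels of a weaning test, computed both unsigned (with absolute
values, quantifying accuracy) and signed (without, quantifying systematic
over/under-estimation), plus the conventional mean +/- sample standard
deviation aggregation used in parameter summary tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import MeasurementVector

__all__ = ["ErrorReport", "relative_error_report", "aggregate_mean_sd"]

_COMPONENTS = MeasurementVector.component_names


@dataclass
class ErrorReport:
    """Per-observable mean relative errors of one weaning-test fit.

    ``unsigned[k] = (1/n) sum_j |sim_jk - exp_jk| / exp_jk`` and the signed
    version drops the absolute value; both are fractions.  ``psi`` carries
    the weighted objective value of the fit the report describes.
    """

    psi: float
    unsigned: dict
    signed: dict
    n: int

    def __post_init__(self) -> None:
        for k in _COMPONENTS:
            if self.unsigned[k] < 0 or self.unsigned[k] + 1e-12 < abs(self.signed[k]):
                raise ValueError(f"inconsistent error pair for {k}: "
                                 f"unsigned {self.unsigned[k]}, signed {self.signed[k]}")

    def to_row(self) -> pd.DataFrame:
        """Single-row table: Psi, the five unsigned errors, the five signed
        errors, and the record count."""
        row = {"psi": self.psi}
        row.update({f"unsigned_{k}": self.unsigned[k] for k in _COMPONENTS})
        row.update({f"signed_{k}": self.signed[k] for k in _COMPONENTS})
        row["n"] = self.n
        return pd.DataFrame([row])


def relative_error_report(sim, exp, psi: float = float("nan")) -> ErrorReport:
    """Mean relative errors between simulated and experimental observables.

    Parameters
    ----------
    sim, exp : list of MeasurementVector
        Equal-length lists, one entry per flow level; ``exp`` components
        must be non-zero (they divide).
    psi : float
        Objective value to attach to the report.
    """
    if len(sim) != len(exp):
        raise ValueError(f"length mismatch: {len(sim)} simulated vs {len(exp)} experimental")
    if len(sim) == 0:
        raise ValueError("need at least one record")
    s = np.stack([v.as_array() for v in sim])
    e = np.stack([v.as_array() for v in exp])
    if np.any(e == 0):
        bad = _COMPONENTS[int(np.argwhere(e == 0)[0][1])]
        raise ZeroDivisionError(f"experimental component {bad!r} is zero; relative error undefined")
    rel = (s - e) / e
    unsigned = np.abs(rel).mean(axis=0)
    signed = rel.mean(axis=0)
    return ErrorReport(psi=float(psi),
                       unsigned=dict(zip(_COMPONENTS, unsigned.tolist())),
                       signed=dict(zip(_COMPONENTS, signed.tolist())),
                       n=len(sim))


def aggregate_mean_sd(values) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation.

    For a single value the standard deviation is reported as 0 with a
    warning (it is undefined with the n-1 denominator).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot aggregate an empty list")
    if arr.size == 1:
        warnings.warn("standard deviation of a single value reported as 0",
                      stacklevel=2)
        return float(arr[0]), 0.0
    return float(arr.mean()), float(arr.std(ddof=1))
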