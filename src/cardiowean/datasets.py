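"""Published reference values used as defaults, examples and test anchors.

These are identified parameter values from porcine VA-ECLS experiments
(healthy baseline estimates for eight anesthetized pigs, flow-response
coefficients for a representative post-arrest weaning test and the
cohort mean) and from a re-analysis of an external porcine VA-ECMO dataset.
They serve as realistic anchors for synthetic scenarios; no raw measurement
data is bundled.
"""

from __future__ import annotations

from .identify import ControlCoefficients, FreeParameterSet
from .model import CVSParameters

__all__ = [
    "PORCINE_BASELINE",
    "PORCINE_BASELINE_MEAN",
    "POSTARREST_MEAN_COEFFS",
    "WEANING_EXAMPLE_COEFFS",
    "QD_RESPONSE_REFIT_COEFFS",
]

#: Identified baseline (no extracorporeal support, healthy heart) parameters
#: and measured heart rates for eight anesthetized pigs.  Literature-fixed
#: parameters take their default values.
PORCINE_BASELINE: dict[str, CVSParameters] = {
    "Pig1": CVSParameters(E_h=1.17, A_h=0.025, E_a=0.82, R_s=0.93, SBV=846.0, HR=1.26),
    "Pig2": CVSParameters(E_h=1.15, A_h=0.052, E_a=1.47, R_s=1.58, SBV=1046.0, HR=1.18),
    "Pig3": CVSParameters(E_h=1.24, A_h=0.046, E_a=1.72, R_s=1.62, SBV=1064.0, HR=1.35),
    "Pig4": CVSParameters(E_h=1.74, A_h=0.035, E_a=0.83, R_s=0.91, SBV=1764.0, HR=1.69),
    "Pig5": CVSParameters(E_h=1.75, A_h=0.035, E_a=1.70, R_s=2.05, SBV=691.0, HR=1.17),
    "Pig6": CVSParameters(E_h=1.25, A_h=0.032, E_a=1.40, R_s=1.63, SBV=1093.0, HR=1.23),
    "Pig7": CVSParameters(E_h=2.37, A_h=0.054, E_a=2.03, R_s=2.21, SBV=1085.0, HR=1.31),
    "Pig8": CVSParameters(E_h=1.58, A_h=0.031, E_a=1.59, R_s=1.83, SBV=961.0, HR=1.33),
}

#: Cohort mean of the baseline estimates above (2-decimal convention of the
#: source summary).
PORCINE_BASELINE_MEAN = CVSParameters(E_h=1.53, A_h=0.039, E_a=1.44,
                                      R_s=1.59, SBV=1069.0, HR=1.32)

#: Cohort-mean flow-response coefficients over all post-arrest porcine
#: weaning tests (intercepts = parameter values extrapolated to Q_d = 0;
#: slopes per ml/s).
POSTARREST_MEAN_COEFFS = ControlCoefficients(
    E_0_h=0.99, A_0_h=0.036, E_0_a=1.49, R_0_s=1.28, SBV_0=1099.0,
    E_Sl_h=0.015, A_Sl_h=-9e-6, E_Sl_a=0.006, R_Sl_s=-0.013, SBV_Sl=2.081,
)

#: Flow-response coefficients identified in one representative post-arrest
#: porcine weaning test (no noradrenaline support), used as ground truth for
#: the synthetic weaning-test scenario.
WEANING_EXAMPLE_COEFFS = ControlCoefficients(
    E_0_h=0.93, A_0_h=0.027, E_0_a=1.62, R_0_s=1.55, SBV_0=1016.0,
    E_Sl_h=0.005, A_Sl_h=6e-5, E_Sl_a=-0.011, R_Sl_s=-0.023, SBV_Sl=4.609,
)

#: Flow-response coefficients from a re-analysis of an external porcine
#: VA-ECMO dataset in which only ventricular pressures/volumes were
#: available: the arterial elastance could not be identified there and was
#: held at the literature value 0.76 mmHg/ml (zero slope).
QD_RESPONSE_REFIT_COEFFS = ControlCoefficients(
    E_0_h=0.905, A_0_h=0.035, E_0_a=0.76, R_0_s=0.356, SBV_0=769.0,
    E_Sl_h=0.0034, A_Sl_h=4e-5, E_Sl_a=0.0, R_Sl_s=0.0020, SBV_Sl=1.44,
)
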