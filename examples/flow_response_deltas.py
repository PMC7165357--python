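"""Normalized flow-response of the cardiovascular parameters.

Given fitted slope/intercept coefficients, computes how much each
parameter changes (as a fraction of its zero-flow value) when the
extracorporeal flow is raised from 0 to 1 l/min — the compact summary of
the body's control response used to compare subjects.
"""

from cardiowean import (QD_RESPONSE_REFIT_COEFFS, delta_sign_report,
                        normalized_deltas, params_at_flow)

c = QD_RESPONSE_REFIT_COEFFS
deltas = normalized_deltas(c).rounded(2)
signs = delta_sign_report(c)

print("parameters at Q_d = 0 (the intercepts):",
      dict(zip(("E_h", "A_h", "E_a", "R_s", "SBV"),
               (round(float(v), 3) for v in params_at_flow(c, 0.0).as_array()))))
print("normalized change for a 0 -> 1 l/min flow increase:")
for key, value in deltas.items():
    print(f"  {key:<7s} {value:+.2f}  ({signs[key]})")
print("positive d1_Eh: contractility rises with pump flow; "
      "positive d1_Rs: vessels constrict as flow increases.")
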