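"""Simulate a healthy baseline circulation to its limit cycle.

Builds the identified baseline parameter set of one reference pig (no
extracorporeal support), integrates the three-compartment model to its
periodic steady state and prints the five clinical observables of the
converged beat.
"""

from cardiowean import PORCINE_BASELINE, simulate_to_steady_state, summarize_beat

p = PORCINE_BASELINE["Pig1"]
trace = simulate_to_steady_state(p, Q_d=0.0)
obs = summarize_beat(trace)

print(f"converged={trace.converged} after {trace.beats_used} beats "
      f"(HR {p.HR} /s, period {p.period:.3f} s)")
for name, value, unit in [
    ("mean arterial pressure (1/3 sys + 2/3 dia)", obs.P_a_mean, "mmHg"),
    ("arterial pulse pressure", obs.PP_a, "mmHg"),
    ("mean venous pressure", obs.P_v_mean, "mmHg"),
    ("maximal heart volume", obs.maxV_h, "ml"),
    ("stroke volume", obs.SV, "ml"),
]:
    print(f"  {name:<45s} {value:8.2f} {unit}")
print(f"  ejection fraction SV/max(V_h)                 {obs.SV / obs.maxV_h:8.2f}")
print("These are the quantities a parameter fit compares against measured data.")
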