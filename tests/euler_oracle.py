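"""Independent fixed-step forward-Euler integrator used as an oracle.

Deliberately naive and separate from the package's adaptive integrator:
a plain Python time-stepping loop over the same model equations, written
directly from their definition.
"""

from __future__ import annotations

import math

import numpy as np


def euler_beats(p, Q_d, y0, n_beats, dt=1e-5, W=80.0, kappa=0.375):
    """Integrate ``n_beats`` beats with forward Euler; return the last beat
    sampled at every step: (t, V_sh, V_sa, V_sv) arrays."""
    T = 1.0 / p.HR
    n_steps = int(round(T / dt))
    vh, va, vv = float(y0[0]), float(y0[1]), float(y0[2])
    kT = kappa * T
    last = None
    for _ in range(n_beats):
        ts = np.empty(n_steps + 1)
        vhs = np.empty(n_steps + 1)
        vas = np.empty(n_steps + 1)
        vvs = np.empty(n_steps + 1)
        for k in range(n_steps + 1):
            t = k * dt
            ts[k], vhs[k], vas[k], vvs[k] = t, vh, va, vv
            if k == n_steps:
                break
            e = math.exp(-W * ((t % T) - kT) ** 2)
            P_h = e * p.E_h * vh + (1.0 - e) * p.B_h * math.expm1(p.A_h * vh)
            P_a = p.E_a * va
            P_v = p.E_v * vv
            Q_o = (P_h - P_a) / p.R_o if P_h > P_a else 0.0
            Q_i = (P_v - P_h) / p.R_i if P_v > P_h else 0.0
            Q_s = (P_a - P_v) / p.R_s
            vh += dt * (Q_i - Q_o)
            va += dt * (Q_o - Q_s + Q_d)
            vv += dt * (Q_s - Q_i - Q_d)
        last = (ts, vhs, vas, vvs)
    return last


def euler_observables(p, Q_d, y0, n_beats=4, dt=1e-5):
    """Observable 5-vector (P_a_mean, PP_a, P_v_mean, maxV_h, SV) from the
    last Euler beat."""
    t, vh, va, vv = euler_beats(p, Q_d, y0, n_beats, dt=dt)
    P_a = p.E_a * va
    P_v = p.E_v * vv
    mx, mn = P_a.max(), P_a.min()
    T = 1.0 / p.HR
    return np.array([
        mx / 3.0 + 2.0 * mn / 3.0,
        mx - mn,
        float(np.trapezoid(P_v, t) / T),
        vh.max(),
        vh.max() - vh.min(),
    ])
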