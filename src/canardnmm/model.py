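"""Model equations, observables and equilibria.

Two equivalent forms of the same dynamics are provided:

* ``rhs_original`` -- post-synaptic potentials ``(y0, y1, y2, y3)`` in mV
  and their derivatives ``(y5..y8)`` in mV/s, with time in seconds.
* ``rhs_fast`` -- the rescaled slow-fast form in the dimensionless fast
  time ``t~ = t / tau_g`` and variables ``v_i`` obtained by dividing each
  PSP by its synaptic time constant (v0 = y0/tau_a, v1 = y1/tau_a,
  v2 = y2/tau_b, v3 = y3/tau_g).  In this form the PV+ pair (v3, y8) is
  fast, the pyramidal pairs (v0, y5), (v1, y6) are O(delta) slow and the
  SOM+ pair (v2, y7) is O(delta*epsilon) super-slow.

State vector layout used throughout: ``(v0, v1, v2, v3, y5, y6, y7, y8)``
(or the y-equivalents for the original form).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .params import ModelParams

__all__ = [
    "sigmoid", "sigmoid_prime", "rhs_fast", "rhs_original",
    "to_fast_form", "to_original_form", "lfp", "psp_components",
    "jacobian_full", "solve_equilibria", "equilibrium_state",
    "equilibrium_closure",
]


def sigmoid(v, params: ModelParams | None = None):
    """Wave-to-pulse transfer: average firing rate for potential ``v`` (mV).

    Numerically stable for arbitrarily large |v| (the exponent is clamped
    far beyond the double-precision saturation point).
    """
    sg = params.sigmoid if params is not None else None
    vmax = sg.vmax if sg else 5.0
    r = sg.steepness if sg else 0.56
    vh = sg.v_half if sg else 6.0
    x = np.clip(r * (vh - np.asarray(v, dtype=float)), -700.0, 700.0)
    return vmax / (1.0 + np.exp(x))


def sigmoid_prime(v, params: ModelParams | None = None):
    """dS/dv, expressed through S to stay stable at saturation."""
    sg = params.sigmoid if params is not None else None
    vmax = sg.vmax if sg else 5.0
    r = sg.steepness if sg else 0.56
    s = sigmoid(v, params)
    return r * s * (1.0 - s / vmax)


def rhs_fast(state, p: ModelParams, p_instant: float | None = None):
    """Right-hand side of the rescaled slow-fast system (dimensionless time).

    Returns the 8 derivatives ordered as the state vector; the pyramidal
    rows carry the factor delta and the SOM+ rows delta*epsilon, so the
    magnitudes directly expose the three-scale structure.
    """
    v0, v1, v2, v3, y5, y6, y7, y8 = np.asarray(state, dtype=float)
    d, e = p.delta, p.epsilon
    pin = p.p_mean if p_instant is None else p_instant
    a5 = p.A * p.tau_a * pin + p.C2 * p.tau_a * v1 \
        - p.C4 * p.tau_b * v2 - p.C7 * p.tau_g * v3
    return np.array([
        d * y5,
        d * y6,
        d * e * y7,
        y8,
        d * (p.A * sigmoid(a5, p) - v0 - 2.0 * y5),
        d * (p.A * sigmoid(p.C1 * p.tau_a * v0, p) - v1 - 2.0 * y6),
        d * e * (p.B * sigmoid(p.C3 * p.tau_a * v0, p) - v2 - 2.0 * y7),
        p.G * sigmoid(p.C5 * p.tau_a * v0 - p.C6 * p.tau_b * v2, p)
        - v3 - 2.0 * y8,
    ])


def rhs_original(state, p: ModelParams, p_instant: float | None = None):
    """Right-hand side in physical units (PSPs in mV, time in seconds)."""
    y0, y1, y2, y3, y5, y6, y7, y8 = np.asarray(state, dtype=float)
    ta, tb, tg = p.tau_a, p.tau_b, p.tau_g
    pin = p.p_mean if p_instant is None else p_instant
    a5 = p.A * ta * pin + p.C2 * y1 - p.C4 * y2 - p.C7 * y3
    return np.array([
        y5,
        y6,
        y7,
        y8,
        p.A / ta * sigmoid(a5, p) - 2.0 / ta * y5 - y0 / ta**2,
        p.A / ta * sigmoid(p.C1 * y0, p) - 2.0 / ta * y6 - y1 / ta**2,
        p.B / tb * sigmoid(p.C3 * y0, p) - 2.0 / tb * y7 - y2 / tb**2,
        p.G / tg * sigmoid(p.C5 * y0 - p.C6 * y2, p)
        - 2.0 / tg * y8 - y3 / tg**2,
    ])


def to_fast_form(y, p: ModelParams):
    """Convert an original-form state (mV) to the rescaled variables."""
    y = np.asarray(y, dtype=float)
    out = y.copy()
    out[..., 0] = y[..., 0] / p.tau_a
    out[..., 1] = y[..., 1] / p.tau_a
    out[..., 2] = y[..., 2] / p.tau_b
    out[..., 3] = y[..., 3] / p.tau_g
    return out


def to_original_form(v, p: ModelParams):
    """Inverse of :func:`to_fast_form`."""
    v = np.asarray(v, dtype=float)
    out = v.copy()
    out[..., 0] = v[..., 0] * p.tau_a
    out[..., 1] = v[..., 1] * p.tau_a
    out[..., 2] = v[..., 2] * p.tau_b
    out[..., 3] = v[..., 3] * p.tau_g
    return out


def lfp(state, p: ModelParams, convention: str = "weighted"):
    """Local field potential observed at the pyramidal population.

    ``simple``   -- the sum of PSPs, tau_a*v1 - tau_b*v2 - tau_g*v3
                    (y1 - y2 - y3 after conversion).
    ``weighted`` -- the synaptically weighted sum including the constant
                    external-drive term:
                    A*tau_a*p + C2*tau_a*v1 - C4*tau_b*v2 - C7*tau_g*v3.
    """
    st = np.asarray(state, dtype=float)
    v1, v2, v3 = st[..., 1], st[..., 2], st[..., 3]
    if convention == "simple":
        return p.tau_a * v1 - p.tau_b * v2 - p.tau_g * v3
    if convention == "weighted":
        return (p.A * p.tau_a * p.p_mean + p.C2 * p.tau_a * v1
                - p.C4 * p.tau_b * v2 - p.C7 * p.tau_g * v3)
    raise ValueError(f"unknown LFP convention {convention!r}")


def psp_components(state, p: ModelParams):
    """(EPSP, slow IPSP, fast IPSP) summands of the weighted LFP."""
    st = np.asarray(state, dtype=float)
    return (p.C2 * p.tau_a * st[..., 1],
            p.C4 * p.tau_b * st[..., 2],
            p.C7 * p.tau_g * st[..., 3])


def jacobian_full(state, p: ModelParams):
    """Analytic 8x8 Jacobian of :func:`rhs_fast` at ``state``."""
    v0, v1, v2, v3 = np.asarray(state, dtype=float)[:4]
    d, e = p.delta, p.epsilon
    ta, tb, tg = p.tau_a, p.tau_b, p.tau_g
    a5 = p.A * ta * p.p_mean + p.C2 * ta * v1 - p.C4 * tb * v2 - p.C7 * tg * v3
    k = p.C5 * ta * v0 - p.C6 * tb * v2
    s5 = sigmoid_prime(a5, p)
    J = np.zeros((8, 8))
    J[0, 4] = d
    J[1, 5] = d
    J[2, 6] = d * e
    J[3, 7] = 1.0
    J[4, 1] = d * p.A * s5 * p.C2 * ta
    J[4, 2] = -d * p.A * s5 * p.C4 * tb
    J[4, 3] = -d * p.A * s5 * p.C7 * tg
    J[4, 0] = -d
    J[4, 4] = -2.0 * d
    J[5, 0] = d * p.A * sigmoid_prime(p.C1 * ta * v0, p) * p.C1 * ta
    J[5, 1] = -d
    J[5, 5] = -2.0 * d
    J[6, 0] = d * e * p.B * sigmoid_prime(p.C3 * ta * v0, p) * p.C3 * ta
    J[6, 2] = -d * e
    J[6, 6] = -2.0 * d * e
    J[7, 0] = p.G * sigmoid_prime(k, p) * p.C5 * ta
    J[7, 2] = -p.G * sigmoid_prime(k, p) * p.C6 * tb
    J[7, 3] = -1.0
    J[7, 7] = -2.0
    return J


def equilibrium_closure(v0, p: ModelParams):
    """Scalar residual whose roots are the equilibrium v0 values.

    At equilibrium every derivative variable vanishes and
    v1 = A*S(C1*tau_a*v0), v2 = B*S(C3*tau_a*v0),
    v3 = G*S(C5*tau_a*v0 - C6*tau_b*v2); substituting into the pyramidal
    balance leaves one equation in v0.
    """
    ta, tb, tg = p.tau_a, p.tau_b, p.tau_g
    v1 = p.A * sigmoid(p.C1 * ta * v0, p)
    v2 = p.B * sigmoid(p.C3 * ta * v0, p)
    v3 = p.G * sigmoid(p.C5 * ta * v0 - p.C6 * tb * v2, p)
    arg = p.A * ta * p.p_mean + p.C2 * ta * v1 - p.C4 * tb * v2 - p.C7 * tg * v3
    return p.A * sigmoid(arg, p) - v0


def equilibrium_state(v0: float, p: ModelParams):
    """Full 8-dimensional equilibrium state for a given root v0."""
    ta, tb = p.tau_a, p.tau_b
    v1 = p.A * sigmoid(p.C1 * ta * v0, p)
    v2 = p.B * sigmoid(p.C3 * ta * v0, p)
    v3 = p.G * sigmoid(p.C5 * ta * v0 - p.C6 * tb * v2, p)
    return np.array([v0, v1, v2, v3, 0.0, 0.0, 0.0, 0.0])


def solve_equilibria(p: ModelParams, v0_window=(0.0, None), n_scan: int = 20000):
    """All equilibria of the deterministic system, sorted by v0.

    A dense sign-change scan of the scalar closure over ``v0_window``
    (default: the full reachable range (0, A*vmax)) brackets every root,
    each then polished by Brent's method.  A root within one scan step of
    the window boundary raises, as the window may be clipping the branch.
    """
    lo, hi = v0_window
    if hi is None:
        hi = p.A * p.sigmoid.vmax
    grid = np.linspace(lo + 1e-9, hi - 1e-9, n_scan)
    res = equilibrium_closure(grid, p)
    roots = []
    for i in range(n_scan - 1):
        if res[i] == 0.0:
            roots.append(grid[i])
        elif (res[i] > 0) != (res[i + 1] > 0):
            roots.append(brentq(equilibrium_closure, grid[i], grid[i + 1],
                                args=(p,), xtol=1e-13))
    step = (hi - lo) / n_scan
    for r in roots:
        if r - lo < step or hi - r < step:
            raise RuntimeError(
                f"equilibrium at v0={r:.4f} touches the scan window boundary;"
                " widen v0_window")
    return [equilibrium_state(r, p) for r in sorted(roots)]
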