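"""Slow-fast reduction: critical manifold, super-slow manifold and folded
singularities.

Sending the fast scale ratio to zero collapses the PV+ pair onto the
critical manifold, the explicit graph ``v3 = K(v0, v2)``.  Sending the
super-slow ratio to zero afterwards restricts the remaining slow flow to
the super-slow manifold L0, the implicit curve obtained by balancing the
pyramidal closure on that graph.  Writing L0 locally as ``v2 = M(v0)``,
the super-slow flow desingularized by the factor dM/dv0 is the planar
system

    v0' = -y7,      y7' = -(dM/dv0) * F7(v0, M(v0), y7),

whose equilibria on the fold set dM/dv0 = 0 are the folded singularities.
Because the model is built from second-order synaptic kinetics, the trace
of the desingularized Jacobian vanishes identically on the fold set, so a
folded equilibrium is a saddle (det < 0), a center (det > 0) or nilpotent
(det = 0); the nilpotent case marks a degenerate transcritical interaction
with an ordinary equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .params import ModelParams
from .model import sigmoid, sigmoid_prime

__all__ = [
    "ManifoldBranch", "FoldPoint", "SingularPoint",
    "critical_manifold_v3", "implicit_residual", "trace_L0", "fold_points",
    "manifold_value", "manifold_slope", "manifold_curvature",
    "dsrs_rhs", "classify_folded", "classify_regular", "transcritical_B",
    "slow_layer_jacobian",
]

# default tracing windows: v0 is bounded by the pyramidal sigmoid ceiling
# A*vmax = 25 mV; v2 by the SOM+ ceiling with margin for the off-branch scan
_V0_RANGE = (0.02, 24.95)
_V2_SCAN = (-30.0, 200.0)
_JUMP = 0.5  # nearest-neighbour continuation threshold in v2 (mV)


@dataclass
class ManifoldBranch:
    v0: np.ndarray          # strictly increasing grid
    v2: np.ndarray          # M(v0) samples
    dM: np.ndarray          # implicit first derivative
    d2M: np.ndarray         # second derivative (FD of the analytic slope)
    labels: list            # per point: stable-left / unstable-middle / stable-right

    @property
    def folded(self) -> bool:
        return bool(np.any(np.sign(self.dM[:-1]) != np.sign(self.dM[1:])))


@dataclass
class FoldPoint:
    v0: float
    v2: float
    label: str      # "F1" (lower v0) or "F2"
    d2M: float


@dataclass
class SingularPoint:
    v0: float
    y7: float
    kind: str            # "folded" | "regular"
    classification: str  # saddle | center | nilpotent | stable-focus | node
    eigenvalues: tuple


def critical_manifold_v3(v0, v2, p: ModelParams):
    """Fast-layer equilibrium v3 = K(v0, v2) = G*S(C5*ta*v0 - C6*tb*v2)."""
    return p.G * sigmoid(p.C5 * p.tau_a * np.asarray(v0)
                         - p.C6 * p.tau_b * np.asarray(v2), p)


def implicit_residual(v0, v2, p: ModelParams):
    """Residual of the super-slow manifold equation at (v0, v2)."""
    ta, tb, tg = p.tau_a, p.tau_b, p.tau_g
    arg = (p.A * ta * p.p_mean
           + p.C2 * ta * p.A * sigmoid(p.C1 * ta * np.asarray(v0), p)
           - p.C4 * tb * np.asarray(v2)
           - p.C7 * tg * critical_manifold_v3(v0, v2, p))
    return p.A * sigmoid(arg, p) - np.asarray(v0)


def _partials(v0, v2, p: ModelParams):
    """Analytic partial derivatives of the implicit residual."""
    ta, tb, tg = p.tau_a, p.tau_b, p.tau_g
    k = p.C5 * ta * np.asarray(v0) - p.C6 * tb * np.asarray(v2)
    Kv0 = p.G * sigmoid_prime(k, p) * p.C5 * ta
    Kv2 = -p.G * sigmoid_prime(k, p) * p.C6 * tb
    arg = (p.A * ta * p.p_mean
           + p.C2 * ta * p.A * sigmoid(p.C1 * ta * np.asarray(v0), p)
           - p.C4 * tb * np.asarray(v2) - p.C7 * tg * p.G * sigmoid(k, p))
    sp = p.A * sigmoid_prime(arg, p)
    phi_v0 = sp * (p.C2 * ta * p.A * sigmoid_prime(p.C1 * ta * np.asarray(v0), p)
                   * p.C1 * ta - p.C7 * tg * Kv0) - 1.0
    phi_v2 = sp * (-p.C4 * tb - p.C7 * tg * Kv2)
    return phi_v0, phi_v2


def _slope(v0, v2, p: ModelParams):
    phi_v0, phi_v2 = _partials(v0, v2, p)
    return -phi_v0 / phi_v2


def _v2_roots(v0: float, p: ModelParams, n: int = 2301):
    lo, hi = _V2_SCAN
    grid = np.linspace(lo, hi, n)
    f = implicit_residual(v0, grid, p)
    out = []
    for i in range(n - 1):
        if (f[i] > 0) != (f[i + 1] > 0):
            out.append(brentq(lambda v2: float(implicit_residual(v0, v2, p)),
                              grid[i], grid[i + 1], xtol=1e-13))
    return out


_TRACE_CACHE: dict = {}


def trace_L0(p: ModelParams, v0_range=_V0_RANGE, n_points: int = 1400):
    """Trace every branch of the super-slow manifold over ``v0_range``.

    For each v0 gridpoint all v2 roots of the implicit equation are found
    by a dense sign scan plus Brent refinement, then chained into branches
    by nearest-neighbour continuation (jump threshold 0.5 mV in v2); a
    root with no predecessor starts a new branch, so branch birth/death at
    turning points is explicit rather than silently bridged.

    The result is cached: the equation contains neither B nor C3, so the
    same trace serves every point of a (B, C3) scan.
    """
    key = (p.geometry_key(), tuple(v0_range), n_points)
    if key in _TRACE_CACHE:
        return _TRACE_CACHE[key]

    v0_grid = np.linspace(v0_range[0], v0_range[1], n_points)
    chains: list[list[tuple]] = []
    open_tips: list[tuple] = []  # (chain_index, last_v2); refreshed per column
    for i, v0 in enumerate(v0_grid):
        roots = _v2_roots(v0, p)
        new_tips = []
        used = set()
        for v2 in roots:
            best = None
            for ci, tip_v2 in open_tips:
                if ci in used:
                    continue
                dist = abs(tip_v2 - v2)
                if dist < _JUMP and (best is None or dist < best[1]):
                    best = (ci, dist)
            if best is not None:
                chains[best[0]].append((v0, v2))
                used.add(best[0])
                new_tips.append((best[0], v2))
            else:
                chains.append([(v0, v2)])
                new_tips.append((len(chains) - 1, v2))
        open_tips = new_tips

    branches = []
    for ch in chains:
        if len(ch) < 8:
            continue
        arr = np.asarray(ch)
        v0s, v2s = arr[:, 0], arr[:, 1]
        dM = _slope(v0s, v2s, p)
        d2M = _curvature_fd(v0s, v2s, p)
        branches.append(ManifoldBranch(v0s, v2s, dM, d2M,
                                       _stability_labels(v0s, dM)))
    branches.sort(key=lambda b: float(np.median(b.v2)))
    _TRACE_CACHE[key] = branches
    return branches


def _curvature_fd(v0s, v2s, p: ModelParams, h: float = 1e-5):
    """d2M/dv0^2 by central differencing the analytic slope on-branch."""
    out = np.empty_like(v0s)
    for i, (v0, v2) in enumerate(zip(v0s, v2s)):
        sp = _slope(v0, v2, p)
        vp = _polish(v0 + h, v2 + sp * h, p)
        vm = _polish(v0 - h, v2 - sp * h, p)
        out[i] = (_slope(v0 + h, vp, p) - _slope(v0 - h, vm, p)) / (2 * h)
    return out


def _polish(v0: float, v2_guess: float, p: ModelParams, span: float = 0.2):
    """Solve the implicit equation for v2 near a guess (on-branch tracking)."""
    f = lambda v2: float(implicit_residual(v0, v2, p))
    lo, hi = v2_guess - span, v2_guess + span
    flo, fhi = f(lo), f(hi)
    width = span
    while (flo > 0) == (fhi > 0):
        width *= 2.0
        if width > 64.0:
            raise RuntimeError(f"lost the manifold branch near v0={v0:.4f}")
        lo, hi = v2_guess - width, v2_guess + width
        flo, fhi = f(lo), f(hi)
    return brentq(f, lo, hi, xtol=1e-13)


def _stability_labels(v0s, dM):
    """Branch segment names, switching only at slope sign changes."""
    sign_flips = np.where(np.sign(dM[:-1]) != np.sign(dM[1:]))[0]
    labels = []
    if len(sign_flips) == 2:
        f1, f2 = sign_flips
        for i in range(len(v0s)):
            if i <= f1:
                labels.append("stable-left")
            elif i <= f2:
                labels.append("unstable-middle")
            else:
                labels.append("stable-right")
    else:
        labels = ["unfolded"] * len(v0s)
    return labels


def _folded_branch(p: ModelParams, window=(0.0, 12.0)):
    """The unique branch carrying a fold pair inside ``window``."""
    cands = []
    for b in trace_L0(p):
        m = (b.v0 >= window[0]) & (b.v0 <= window[1])
        if m.sum() > 8:
            d = b.dM[m]
            if np.any(np.sign(d[:-1]) != np.sign(d[1:])):
                cands.append(b)
    if len(cands) != 1:
        raise RuntimeError(
            f"expected exactly one folded manifold branch in v0 window "
            f"{window}, found {len(cands)}; parameter regime out of scope")
    return cands[0]


def fold_points(p: ModelParams, window=(0.0, 12.0)):
    """The two folds (F1, F2) of the super-slow manifold, |dM| < 1e-10."""
    b = _folded_branch(p, window)
    flips = np.where(np.sign(b.dM[:-1]) != np.sign(b.dM[1:]))[0]
    folds = []
    for i in flips:
        if not (window[0] <= b.v0[i] <= window[1]):
            continue

        def slope_at(v0, _i=i):
            frac = (v0 - b.v0[_i]) / (b.v0[_i + 1] - b.v0[_i])
            guess = b.v2[_i] + frac * (b.v2[_i + 1] - b.v2[_i])
            return _slope(v0, _polish(v0, guess, p), p)

        v0f = brentq(slope_at, b.v0[i], b.v0[i + 1], xtol=1e-13)
        v2f = _polish(v0f, np.interp(v0f, b.v0, b.v2), p)
        d2 = _curvature_fd(np.array([v0f]), np.array([v2f]), p)[0]
        folds.append((v0f, v2f, d2))
    if len(folds) != 2:
        raise RuntimeError(f"expected 2 fold points, found {len(folds)}")
    folds.sort()
    return (FoldPoint(folds[0][0], folds[0][1], "F1", folds[0][2]),
            FoldPoint(folds[1][0], folds[1][1], "F2", folds[1][2]))


def manifold_value(v0: float, p: ModelParams):
    """M(v0) on the folded branch."""
    b = _folded_branch(p)
    if not (b.v0[0] <= v0 <= b.v0[-1]):
        raise ValueError(f"v0={v0} outside the traced branch "
                         f"[{b.v0[0]:.3f}, {b.v0[-1]:.3f}]")
    return _polish(v0, float(np.interp(v0, b.v0, b.v2)), p)


def manifold_slope(v0: float, p: ModelParams):
    return _slope(v0, manifold_value(v0, p), p)


def manifold_curvature(v0: float, p: ModelParams):
    v2 = manifold_value(v0, p)
    return _curvature_fd(np.array([v0]), np.array([v2]), p)[0]


def _F7(v0, v2, y7, p: ModelParams):
    return p.B * sigmoid(p.C3 * p.tau_a * v0, p) - v2 - 2.0 * y7


def dsrs_rhs(v0: float, y7: float, p: ModelParams):
    """Desingularized super-slow flow on the folded branch of L0.

    Desingularized time runs backwards on the repelling side (where
    dM/dv0 < 0); no attempt is made to undo that orientation reversal.
    """
    m = manifold_value(v0, p)
    return np.array([-y7, -manifold_slope(v0, p) * _F7(v0, m, y7, p)])


def classify_folded(fold: FoldPoint, p: ModelParams,
                    nilpotent_tol: float = 1e-8) -> SingularPoint:
    """Classify a folded singularity from the desingularized Jacobian.

    On the fold set the trace vanishes identically, so
    det = -d2M(v0) * F7(v0, M(v0), 0) decides: saddle (det < 0),
    center (det > 0), nilpotent (det ~ 0 after normalizing by |d2M|).
    """
    f7 = _F7(fold.v0, fold.v2, 0.0, p)
    det = -fold.d2M * f7
    if abs(det) / max(abs(fold.d2M), 1e-300) < nilpotent_tol:
        cls, eig = "nilpotent", (0.0, 0.0)
    elif det < 0:
        cls, eig = "saddle", (np.sqrt(-det), -np.sqrt(-det))
    else:
        cls, eig = "center", (1j * np.sqrt(det), -1j * np.sqrt(det))
    return SingularPoint(fold.v0, 0.0, "folded", cls, eig)


def classify_regular(p: ModelParams, B: float | None = None):
    """Ordinary singularities of the desingularized flow on the folded branch.

    These are the intersections of the SOM+ nullcline v2 = B*S(C3*ta*v0)
    with L0 (also equilibria of the full system).  The planar Jacobian has
    tr = 2*dM and det = -dM * dF7/dv0 (total derivative along the branch).
    """
    q = p if B is None else p.with_(B=B)
    b = _folded_branch(q)
    res = q.B * sigmoid(q.C3 * q.tau_a * b.v0, q) - b.v2
    out = []
    for i in np.where(np.sign(res[:-1]) != np.sign(res[1:]))[0]:
        v0s = brentq(
            lambda v0: float(q.B * sigmoid(q.C3 * q.tau_a * v0, q)
                             - _polish(v0, np.interp(v0, b.v0, b.v2), q)),
            b.v0[i], b.v0[i + 1], xtol=1e-12)
        dM = manifold_slope(v0s, q)
        dF7 = (q.B * sigmoid_prime(q.C3 * q.tau_a * v0s, q) * q.C3 * q.tau_a
               - dM)
        tr, det = 2.0 * dM, -dM * dF7
        disc = tr * tr - 4.0 * det
        if disc >= 0:
            eig = ((tr + np.sqrt(disc)) / 2, (tr - np.sqrt(disc)) / 2)
        else:
            eig = ((tr + 1j * np.sqrt(-disc)) / 2, (tr - 1j * np.sqrt(-disc)) / 2)
        if det < 0:
            cls = "saddle"
        elif disc < 0:
            cls = "stable-focus" if tr < 0 else "unstable-focus"
        else:
            cls = "node"
        out.append(SingularPoint(v0s, 0.0, "regular", cls, eig))
    return out


def transcritical_B(p: ModelParams, which: str):
    """Gain at which the folded singularity meets an ordinary one.

    Setting F7(v0_fold, M(v0_fold), 0) = 0 gives
    B* = M(v0_fold) / S(C3*tau_a*v0_fold); at that gain the folded point
    is nilpotent and the two singularities exchange type.
    """
    f1, f2 = fold_points(p)
    f = {"p1": f1, "p2": f2}[which]
    return f.v2 / float(sigmoid(p.C3 * p.tau_a * f.v0, p))


def slow_layer_jacobian(v0: float, v2: float, p: ModelParams):
    """4x4 Jacobian of the slow layer (v0, y5, v1, y6) on the critical
    manifold, with the super-slow pair frozen.

    Along the attracting branches of L0 all four eigenvalues have negative
    real part; one real eigenvalue changes sign exactly at the folds.
    """
    ta, tb, tg = p.tau_a, p.tau_b, p.tau_g
    k = p.C5 * ta * v0 - p.C6 * tb * v2
    Kv0 = p.G * sigmoid_prime(k, p) * p.C5 * ta
    v1 = p.A * sigmoid(p.C1 * ta * v0, p)
    arg = (p.A * ta * p.p_mean + p.C2 * ta * v1 - p.C4 * tb * v2
           - p.C7 * tg * p.G * sigmoid(k, p))
    sp = p.A * sigmoid_prime(arg, p)
    F5_v0 = -sp * p.C7 * tg * Kv0 - 1.0
    F5_v1 = sp * p.C2 * ta
    F6_v0 = p.A * sigmoid_prime(p.C1 * ta * v0, p) * p.C1 * ta
    return np.array([
        [0.0, 1.0, 0.0, 0.0],
        [F5_v0, -2.0, F5_v1, 0.0],
        [0.0, 0.0, 0.0, 1.0],
        [F6_v0, 0.0, -1.0, -2.0],
    ])
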