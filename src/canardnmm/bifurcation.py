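"""Equilibrium continuation in the slow-inhibitory gain B with
eigenvalue-based Hopf and limit-point detection.

Equilibria of the full system are exactly the points of the super-slow
manifold L0 that also satisfy the SOM+ balance v2 = B*S(C3*tau_a*v0), so
the one-parameter equilibrium branch for fixed C3 can be parameterized by
v0: every traced manifold point (v0, v2) yields the unique gain
B(v0) = v2 / S(C3*tau_a*v0) at which it is an equilibrium.  Folds of the
diagram in B are then ordinary turning points of the smooth scalar B(v0)
and nothing is lost near limit points.  The spectrum along the branch is
taken from the analytic 8x8 Jacobian; the trivial fast pair (-1, -1)
never participates in any crossing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .params import ModelParams
from .model import sigmoid, sigmoid_prime, jacobian_full, equilibrium_state
from . import manifold as mf

__all__ = [
    "EquilibriumBranch", "BifPoint", "continue_equilibria", "detect_hopf",
    "detect_limit_points", "hopf_points", "label_hopf_points",
    "scan_hopf_count", "hopf_count_threshold", "count_limit_points",
    "scan_cusp",
]

_RE_TOL = 1e-12  # an eigenvalue is "unstable" if its real part exceeds this


@dataclass
class BifPoint:
    kind: str                 # "Hopf" | "LP"
    B: float
    v0: float
    frequency_hz: float | None = None
    label: str = ""


@dataclass
class EquilibriumBranch:
    params: ModelParams       # includes the C3 used for the closure
    v0: np.ndarray
    v2: np.ndarray
    B: np.ndarray
    states: np.ndarray        # (n, 8)
    spectra: np.ndarray       # (n, 8) complex
    excluded: list = field(default_factory=list)  # v0 intervals with B <= 0

    # -- local evaluators (track the branch off-grid) -------------------
    def v2_at(self, v0: float) -> float:
        return mf._polish(v0, float(np.interp(v0, self.v0, self.v2)),
                          self.params)

    def B_at(self, v0: float) -> float:
        return self.v2_at(v0) / float(
            sigmoid(self.params.C3 * self.params.tau_a * v0, self.params))

    def Bprime_at(self, v0: float) -> float:
        p = self.params
        v2 = self.v2_at(v0)
        s = float(sigmoid(p.C3 * p.tau_a * v0, p))
        sp = float(sigmoid_prime(p.C3 * p.tau_a * v0, p)) * p.C3 * p.tau_a
        dM = mf._slope(v0, v2, p)
        return (dM * s - v2 * sp) / s**2

    def spectrum_at(self, v0: float):
        p = self.params.with_(B=self.B_at(v0))
        st = equilibrium_state(v0, p)
        return np.linalg.eigvals(jacobian_full(st, p))


def continue_equilibria(p: ModelParams, C3: float | None = None,
                        v0_window=(0.02, 24.95), n: int = 2200):
    """Equilibrium branches for fixed C3, one per manifold branch.

    ``n`` is the number of v0 samples of the underlying manifold trace;
    at least ~2000 is needed for detection-grade eigenvalue resolution.
    """
    q = p if C3 is None else p.with_(C3=C3)
    out = []
    for b in mf.trace_L0(q, v0_range=v0_window, n_points=n):
        s = sigmoid(q.C3 * q.tau_a * b.v0, q)
        B = b.v2 / s
        ok = B > 0
        excluded = _mask_intervals(b.v0, ~ok)
        v0s, v2s, Bs = b.v0[ok], b.v2[ok], B[ok]
        states = np.zeros((len(v0s), 8))
        spectra = np.zeros((len(v0s), 8), dtype=complex)
        for i, (v0, v2, Bv) in enumerate(zip(v0s, v2s, Bs)):
            qi = q.with_(B=float(Bv))
            states[i] = equilibrium_state(v0, qi)
            spectra[i] = np.linalg.eigvals(jacobian_full(states[i], qi))
        out.append(EquilibriumBranch(q, v0s, v2s, Bs, states, spectra,
                                     excluded))
    return out


def _mask_intervals(x, mask):
    runs = []
    i = 0
    while i < len(x):
        if mask[i]:
            j = i
            while j + 1 < len(x) and mask[j + 1]:
                j += 1
            runs.append((float(x[i]), float(x[j])))
            i = j + 1
        else:
            i += 1
    return runs


def _n_unstable(spec):
    return int(np.sum(spec.real > _RE_TOL))


def _critical_pair_re(spec):
    """Real part of the complex pair closest to the imaginary axis."""
    cplx = spec[np.abs(spec.imag) > 1e-9]
    if len(cplx) == 0:
        return np.nan
    return float(cplx.real[np.argmin(np.abs(cplx.real))])


def detect_hopf(branch: EquilibriumBranch, warn=None):
    """Hopf points: a complex pair crossing the imaginary axis.

    Grid events where the unstable count jumps by 2 are bisected on the
    real part of the critical pair to |Re| < 1e-8.  Events closer than
    two grid intervals trigger ``warn`` (if given) instead of silently
    merging.
    """
    pts = []
    nu = np.array([_n_unstable(s) for s in branch.spectra])
    events = np.where(np.abs(np.diff(nu)) == 2)[0]
    if warn is not None and len(events) > 1 and np.any(np.diff(events) < 2):
        warn("Hopf candidates closer than grid resolution")
    for i in events:
        lo, hi = branch.v0[i], branch.v0[i + 1]
        f = lambda v0: _critical_pair_re(branch.spectrum_at(v0))
        try:
            v0c = brentq(f, lo, hi, xtol=1e-12)
        except ValueError:
            continue  # grazing pair, no genuine sign change
        spec = branch.spectrum_at(v0c)
        cplx = spec[np.abs(spec.imag) > 1e-9]
        lam = cplx[np.argmin(np.abs(cplx.real))]
        freq = abs(lam.imag) / (2.0 * np.pi * branch.params.tau_g)
        pts.append(BifPoint("Hopf", branch.B_at(v0c), v0c, freq))
    return pts


def turning_points(grid, fprime, fprime_values=None, xtol: float = 1e-12):
    """Roots of ``fprime`` bracketed by sign changes on ``grid``.

    ``fprime_values`` may supply precomputed samples (e.g. a vectorized
    evaluation); refinement always calls ``fprime`` pointwise.
    """
    fp = (np.asarray(fprime_values) if fprime_values is not None
          else np.array([fprime(x) for x in grid]))
    step = float(np.max(np.diff(grid)))
    out: list[float] = []
    for i in range(len(grid) - 1):
        if fp[i] == 0.0:
            r = float(grid[i])
        elif fp[i] * fp[i + 1] < 0:
            r = brentq(fprime, grid[i], grid[i + 1], xtol=xtol)
        else:
            continue
        if not out or abs(r - out[-1]) > step:  # grid-exact zeros dedupe
            out.append(r)
    return out


def detect_limit_points(branch: EquilibriumBranch):
    """Turning points of B(v0): sign changes of dB/dv0, Brent-refined."""
    p = branch.params
    s = sigmoid(p.C3 * p.tau_a * branch.v0, p)
    sp = sigmoid_prime(p.C3 * p.tau_a * branch.v0, p) * p.C3 * p.tau_a
    dM = mf._slope(branch.v0, branch.v2, p)
    dB = (dM * s - branch.v2 * sp) / s**2
    return [BifPoint("LP", branch.B_at(v0c), v0c)
            for v0c in turning_points(branch.v0, branch.Bprime_at, dB)]


def hopf_points(p: ModelParams, C3: float | None = None, **kw):
    """All Hopf points across branches, with paper-style labels."""
    branches = continue_equilibria(p, C3=C3, **kw)
    per_branch = [detect_hopf(b) for b in branches]
    return label_hopf_points(per_branch)


def label_hopf_points(per_branch):
    """Assign H1..H4 by the branch geometry.

    The two harmonic points H1 (low v0) and H2 (high v0) live on the
    low-v2 manifold branch; the singular-Hopf points sit on the folded
    branch next to the folded singularities: H4 near the lower fold p1
    (low v0), H3 near the upper fold p2 (high v0).  When the geometry is
    not the expected two-branch layout, points are labelled H1..Hn in
    order of increasing B.
    """
    flat = [pt for pts in per_branch for pt in pts]
    if len(per_branch) == 2:
        low, folded = per_branch
        if len(low) <= 2 and len(folded) <= 2:
            for pt, lab in zip(sorted(low, key=lambda q: q.v0), ("H1", "H2")):
                pt.label = lab
            folded_sorted = sorted(folded, key=lambda q: q.v0)
            if len(folded_sorted) == 2:
                folded_sorted[0].label = "H4"
                folded_sorted[1].label = "H3"
            elif len(folded_sorted) == 1:
                # the surviving singular Hopf: H4 if at low v0 (near p1)
                folded_sorted[0].label = (
                    "H4" if folded_sorted[0].v0 < 6.0 else "H3")
            return flat
    for i, pt in enumerate(sorted(flat, key=lambda q: q.B)):
        pt.label = f"H{i + 1}"
    return flat


def scan_hopf_count(p: ModelParams, c3_values, **kw):
    """Number of Hopf bifurcations along the branch for each C3."""
    return [(float(c3), len(hopf_points(p, C3=float(c3), **kw)))
            for c3 in np.atleast_1d(c3_values)]


def hopf_count_threshold(p: ModelParams, c3_lo: float, c3_hi: float,
                         tol: float = 0.05, **kw):
    """Bisect the C3 value where the Hopf count changes.

    The endpoints must have different counts; returns the threshold and
    the (low, high) counts.
    """
    n_lo = len(hopf_points(p, C3=c3_lo, **kw))
    n_hi = len(hopf_points(p, C3=c3_hi, **kw))
    if n_lo == n_hi:
        raise ValueError(f"Hopf count is {n_lo} at both endpoints")
    lo, hi = c3_lo, c3_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if len(hopf_points(p, C3=mid, **kw)) == n_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi), (n_lo, n_hi)


def count_limit_points(p: ModelParams, C3: float, **kw):
    return sum(len(detect_limit_points(b))
               for b in continue_equilibria(p, C3=C3, **kw))


def scan_cusp(p: ModelParams, c3_range=(120.0, 160.0), coarse: float = 5.0,
              tol: float = 0.2, **kw):
    """C3 values where the number of limit points changes by 2.

    A fold pair being created or annihilated (cusp) changes the LP count
    by two; each such transition in ``c3_range`` is located by bisection
    to within ``tol``.
    """
    grid = np.arange(c3_range[0], c3_range[1] + 1e-9, coarse)
    counts = [count_limit_points(p, float(c3), **kw) for c3 in grid]
    thresholds = []
    for i in range(len(grid) - 1):
        if abs(counts[i + 1] - counts[i]) == 2:
            lo, hi = float(grid[i]), float(grid[i + 1])
            nlo = counts[i]
            while hi - lo > tol:
                mid = 0.5 * (lo + hi)
                if count_limit_points(p, mid, **kw) == nlo:
                    lo = mid
                else:
                    hi = mid
            thresholds.append(0.5 * (lo + hi))
    return thresholds
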