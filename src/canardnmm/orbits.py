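"""Deterministic orbit characterization: limit cycles, fast-spike counts,
canard classification, bistability and excitability.

All integrations run on the rescaled slow-fast form with a stiff adaptive
solver; reported times are SI seconds (t = tau_g * t~).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .params import ModelParams
from . import model
from . import manifold as mf

__all__ = [
    "TimeSeries", "LimitCycle", "BistabilityResult", "NoPeriodicAttractor",
    "PeriodAmbiguity", "integrate", "find_limit_cycle", "count_fast_spikes",
    "classify_cycle", "probe_bistability", "bistability_interval",
    "excitability_type",
]


class NoPeriodicAttractor(RuntimeError):
    """The trajectory settled on a non-oscillatory attractor."""


class PeriodAmbiguity(RuntimeError):
    """Poincare return times are inconsistent (no simple periodic orbit)."""


@dataclass
class TimeSeries:
    t: np.ndarray              # seconds
    y: np.ndarray              # (n, 8) rescaled states
    params: ModelParams

    @property
    def v0(self):
        return self.y[:, 0]

    def lfp(self, convention: str = "weighted"):
        return model.lfp(self.y, self.params, convention)

    def psp_components(self):
        return model.psp_components(self.y, self.params)


@dataclass
class LimitCycle:
    t: np.ndarray              # one period, seconds, starting at 0
    y: np.ndarray              # (n, 8)
    period_s: float
    params: ModelParams
    label: str = ""

    @property
    def frequency_hz(self):
        return 1.0 / self.period_s

    @property
    def amplitude_v0(self):
        return float(self.y[:, 0].max() - self.y[:, 0].min())


@dataclass
class BistabilityResult:
    B: float
    amp_small: float
    amp_large: float
    coexist: bool
    states: tuple = field(default=(), repr=False)


def integrate(p: ModelParams, ic, t_end_s: float, rtol: float = 1e-8,
              atol: float = 1e-10, n_out: int | None = None,
              method: str = "LSODA") -> TimeSeries:
    """Deterministic solution of the slow-fast system over ``t_end_s``.

    The three-scale stiffness wants tight tolerances; the defaults keep
    the end state stable to ~1e-5 under tolerance halving.
    """
    t_end = t_end_s / p.tau_g
    t_eval = None if n_out is None else np.linspace(0.0, t_end, n_out)
    sol = solve_ivp(lambda t, x: model.rhs_fast(x, p), (0.0, t_end),
                    np.asarray(ic, dtype=float), method=method,
                    rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    return TimeSeries(sol.t * p.tau_g, sol.y.T, p)


def _upward_crossings(t, x):
    """Linearly interpolated times of upward mid-level crossings."""
    mid = 0.5 * (x.max() + x.min())
    idx = np.where((x[:-1] < mid) & (x[1:] >= mid))[0]
    frac = (mid - x[idx]) / (x[idx + 1] - x[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def find_limit_cycle(p: ModelParams, ic, transient_s: float = 20.0,
                     window_s: float = 20.0, section: str = "v2",
                     amp_tol: float = 0.05, cv_tol: float = 0.01,
                     n_samples: int = 4000) -> LimitCycle:
    """Locate the periodic attractor reached from ``ic``.

    After discarding the transient, the period is read from successive
    upward crossings of the mid-level of the section variable (the
    super-slow ``v2`` by default: it traverses its range exactly once per
    cycle, so bursting orbits do not generate spurious returns).  Raises
    :class:`NoPeriodicAttractor` if the post-transient amplitude is below
    ``amp_tol`` and :class:`PeriodAmbiguity` if the return times vary by
    more than ``cv_tol``.
    """
    ts = integrate(p, ic, transient_s)
    run = integrate(p, ts.y[-1], window_s)
    sec = run.y[:, {"v0": 0, "v1": 1, "v2": 2, "v3": 3}[section]]
    if run.v0.max() - run.v0.min() < amp_tol:
        raise NoPeriodicAttractor(
            f"amplitude {run.v0.max() - run.v0.min():.2e} below tolerance")
    crossings = _upward_crossings(run.t, sec)
    if len(crossings) < 3:
        raise PeriodAmbiguity("fewer than 3 section returns in the window")
    periods = np.diff(crossings)
    if periods.std() / periods.mean() > cv_tol:
        raise PeriodAmbiguity(
            f"return-time CV {periods.std() / periods.mean():.3f} exceeds "
            f"{cv_tol}")
    period = float(periods.mean())
    # resample exactly one period from the last full crossing
    start = crossings[-2]
    i0 = np.searchsorted(run.t, start)
    dense = integrate(p, run.y[min(i0, len(run.t) - 1)], period,
                      n_out=n_samples)
    return LimitCycle(dense.t, dense.y, period, p)


def count_fast_spikes(cycle: LimitCycle, prominence_frac: float = 0.05,
                      fast_factor: float = 10.0) -> int:
    """Number of fast spikes per period of a cycle.

    Prominent v0 maxima (prominence above ``prominence_frac`` of the
    cycle amplitude) are grouped into clusters separated by gaps longer
    than ``fast_factor * tau_a``; each cluster of k maxima contributes
    k - 1 fast spikes, so the solitary crest of a relaxation or sinusoidal
    cycle counts zero and an n-spike burst (n spikes plus the terminating
    slow-wave crest) counts n.
    """
    v0 = cycle.y[:, 0]
    amp = v0.max() - v0.min()
    if amp <= 0:
        return 0
    # tile two periods so wrap-around peaks are seen, then keep one period
    t2 = np.concatenate([cycle.t, cycle.t + cycle.period_s])
    x2 = np.concatenate([v0, v0])
    peaks, _ = find_peaks(x2, prominence=prominence_frac * amp)
    tp = t2[peaks]
    tp = tp[(tp >= 0.5 * cycle.period_s) & (tp < 1.5 * cycle.period_s)]
    if len(tp) == 0:
        return 0
    gap = fast_factor * cycle.params.tau_a
    n = 0
    cluster = 1
    for dt_ in np.diff(np.sort(tp)):
        if dt_ <= gap:
            cluster += 1
        else:
            n += cluster - 1
            cluster = 1
    n += cluster - 1
    return n


def classify_cycle(cycle: LimitCycle, branches=None, folds=None,
                   dwell_dist: float = 0.3, dwell_frac: float = 0.05,
                   sin_frac: float = 0.25) -> str:
    """Qualitative label of a periodic orbit against the manifold geometry.

    bursting             -- at least one fast spike;
    sinusoidal           -- v0 amplitude under ``sin_frac`` of the
                            fold-to-fold span, no spikes;
    canard-without-head  -- dwells along the repelling middle branch
                            (>= ``dwell_frac`` of the period within
                            ``dwell_dist``) without reaching the left
                            attracting branch;
    canard-with-head     -- dwells on the middle branch and crosses to
                            the left branch;
    relaxation           -- large-amplitude orbit hugging only the
                            attracting branches;
    unclassifiable       -- none of the above.
    """
    p = cycle.params
    if folds is None:
        folds = mf.fold_points(p)
    f1, f2 = folds
    if branches is None:
        branches = mf.trace_L0(p)
    n_spk = count_fast_spikes(cycle)
    if n_spk >= 1:
        return "bursting"
    span = f2.v0 - f1.v0
    if cycle.amplitude_v0 < sin_frac * span:
        return "sinusoidal"
    # distance to the repelling middle segment in the (v0, v2) plane
    folded = next(b for b in branches if b.folded)
    mid_mask = (folded.v0 >= f1.v0) & (folded.v0 <= f2.v0)
    mb = np.column_stack([folded.v0[mid_mask], folded.v2[mid_mask]])
    pts = cycle.y[:, [0, 2]]
    d = np.sqrt(((pts[:, None, :] - mb[None, :, :]) ** 2).sum(-1)).min(1)
    dwell = float(np.mean(d < dwell_dist))
    reaches_left = bool(cycle.y[:, 0].min() < f1.v0 - 0.25 * span)
    if dwell >= dwell_frac:
        return "canard-with-head" if reaches_left else "canard-without-head"
    return "relaxation"


def _settle_amplitude(p: ModelParams, ic, t_s: float, keep_s: float):
    ts = integrate(p, ic, t_s)
    m = ts.t > (t_s - keep_s)
    v0 = ts.y[m, 0]
    return float(v0.max() - v0.min()), ts.y[-1]


_LARGE_IC = np.array([2.0, 10.0, 10.0, 30.0, 0.0, 0.0, 0.0, 0.0])


def _small_ic(p: ModelParams):
    """Perturbed upper equilibrium: seeds the small-amplitude attractor."""
    eqs = model.solve_equilibria(p)
    x = eqs[-1].copy()
    x[0] += 0.05
    return x


def probe_bistability(p: ModelParams, B: float, ic_small=None, ic_large=None,
                      t_s: float = 50.0, keep_s: float = 20.0,
                      distinct_frac: float = 0.25) -> BistabilityResult:
    """Integrate from a small-attractor and a large-attractor seed.

    The two runs witness coexistence when both sustain oscillations and
    their v0 amplitudes differ by more than ``distinct_frac`` of the
    larger one.  (A fixed amplitude *ratio* fails inside a canard
    explosion, where the small branch inflates to within a factor ~2 of
    the relaxation cycle before it dies.)
    """
    q = p.with_(B=B)
    if ic_small is None:
        ic_small = _small_ic(q)
    if ic_large is None:
        ic_large = _LARGE_IC
    a_s, xs = _settle_amplitude(q, ic_small, t_s, keep_s)
    a_l, xl = _settle_amplitude(q, ic_large, t_s, keep_s)
    hi = max(a_s, a_l)
    coexist = (min(a_s, a_l) > 0.05 and hi > 0
               and (hi - min(a_s, a_l)) / hi > distinct_frac)
    return BistabilityResult(B, a_s, a_l, coexist, (xs, xl))


def bistability_interval(p: ModelParams, B_bracket=(4.6, 5.0),
                         tol: float = 0.005, t_s: float = 50.0,
                         keep_s: float = 20.0):
    """Hysteresis-bisected endpoints of the coexistence window in B.

    A coarse scan of the bracket finds one coexistence point; the upper
    endpoint is then bisected on survival of the small attractor
    (inheriting its state upward) and the lower endpoint on survival of
    the large attractor (inheriting downward), to a width below ``tol``.
    """
    lo, hi = B_bracket
    seed = None
    for B in np.linspace(lo + 0.25 * (hi - lo), hi - 0.25 * (hi - lo), 7):
        r = probe_bistability(p, float(B), t_s=t_s, keep_s=keep_s)
        if r.coexist:
            seed = r
            break
    if seed is None:
        raise RuntimeError(f"no coexistence found in bracket {B_bracket}")
    amp_ref = max(seed.amp_small, seed.amp_large)
    x_small = seed.states[0] if seed.amp_small < seed.amp_large else seed.states[1]
    x_large = seed.states[1] if seed.amp_small < seed.amp_large else seed.states[0]

    def is_large(amp):
        return amp > 0.75 * amp_ref

    def small_survives(B, state):
        amp, x_end = _settle_amplitude(p.with_(B=B), state, t_s, keep_s)
        return (not is_large(amp)) and amp > 0.05, x_end

    def large_survives(B, state):
        amp, x_end = _settle_amplitude(p.with_(B=B), state, t_s, keep_s)
        return is_large(amp), x_end

    upper, _ = bisect_boundary(small_survives, seed.B, hi, x_small, tol)
    lower, _ = bisect_boundary(large_survives, seed.B, lo, x_large, tol)
    return lower, upper


def bisect_boundary(keep, inside, outside, state, tol):
    """Bisect the edge of a parameter region where ``keep`` holds.

    ``keep(x, state) -> (bool, new_state)``; the carried state implements
    hysteresis (attractor inheritance between steps).  ``inside`` must
    satisfy the predicate, ``outside`` must not.
    """
    while abs(outside - inside) > tol:
        mid = 0.5 * (inside + outside)
        ok, new_state = keep(mid, state)
        if ok:
            inside, state = mid, new_state
        else:
            outside = mid
    return 0.5 * (inside + outside), state


def excitability_type(p: ModelParams, C3: float, b_start: float = 15.0,
                      b_step: float = 0.5, b_max: float = 30.0,
                      t_s: float = 40.0, keep_s: float = 20.0,
                      zero_freq_tol: float = 0.05):
    """Excitability class from the termination of the large attractor.

    The large-amplitude attractor is continued upward in B by simulation
    (states inherited between steps) until it dies at B*.  The class is
    type-I when the measured frequency collapses below ``zero_freq_tol``
    at termination, or when saddle equilibria coexist with the attractor
    at B* (the termination then belongs to the homoclinic family, whose
    period diverges); it is type-II when the oscillation dies with a
    finite frequency next to the subcritical Hopf, with no saddle
    present.  Returns ``(label, B_term, freq_at_term)``.
    """
    q = p.with_(C3=C3)
    x = _LARGE_IC.copy()
    last_freq = None
    B = b_start
    B_term = None
    while B <= b_max:
        qB = q.with_(B=B)
        ts = integrate(qB, x, t_s)
        m = ts.t > (t_s - keep_s)
        v0 = ts.y[m, 0]
        amp = v0.max() - v0.min()
        if amp < 5.0:
            B_term = B
            break
        cr = _upward_crossings(ts.t[m], ts.y[m, 2])
        if len(cr) >= 2:
            last_freq = 1.0 / float(np.diff(cr).mean())
        x = ts.y[-1]
        B += b_step
    if B_term is None:
        return "undetermined", None, last_freq
    if last_freq is not None and last_freq < zero_freq_tol:
        return "type-I", B_term, last_freq
    qT = q.with_(B=B_term)
    saddle = False
    for eq in model.solve_equilibria(qT):
        lam = np.linalg.eigvals(model.jacobian_full(eq, qT))
        if np.any((lam.real > 1e-9) & (np.abs(lam.imag) < 1e-9)):
            saddle = True
            break
    return ("type-I" if saddle else "type-II"), B_term, last_freq
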