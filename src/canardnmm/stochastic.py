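"""Stochastic LFP synthesis: Euler-Maruyama simulation under noisy input,
discharge detection and normalized spectral estimates.

This is the synthetic-data stage of the package.  It emulates the
qualitative features of intracerebral recordings near seizure onset that
the deterministic analysis predicts: background broadband activity,
sporadic large-amplitude discharges, and inter-discharge narrow-band
oscillations (about 3.5 Hz in the type-II excitable setting and about
6 Hz when the system idles next to the singular Hopf point H3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import welch

from .params import ModelParams, table1
from . import model

try:  # compiled stepper; the pure-python fallback is bit-identical
    from numba import njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]

__all__ = [
    "NoiseSpec", "ScenarioPreset", "PRESETS", "EventAnnotation",
    "PSDEstimate", "SDERun", "simulate_sde", "detect_discharges",
    "normalized_psd", "dominant_peak", "generate_scenario",
]

_REF_DT = 1e-4  # reference Euler-Maruyama step (s)


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian perturbation of the external input rate.

    ``p(t) = p_mean + xi_k`` with ``xi_k ~ N(0, sigma^2 * ref_dt/dt)``
    held constant within each step; at the reference step of 1e-4 s the
    per-step deviate has exactly variance sigma^2, and the rescaling
    keeps the realized spectral density consistent across step sizes.
    """
    sigma: float = 2.0   # s^-1
    dt: float = _REF_DT  # s
    seed: int = 0


@dataclass(frozen=True)
class ScenarioPreset:
    name: str
    B: float
    C3: float
    C5: float
    sigma: float = 2.0


# The three pre-ictal scenarios: a type-I excitable setting, a type-II
# excitable setting whose inter-discharge oscillations sit near 3.5 Hz,
# and a setting just below the singular Hopf H3 (about 6 Hz).
PRESETS = {
    "type_I": ScenarioPreset("type_I", B=23.0, C3=35.0, C5=200.0),
    "type_II": ScenarioPreset("type_II", B=17.8, C3=80.0, C5=200.0),
    "near_H3": ScenarioPreset("near_H3", B=4.7, C3=80.0, C5=200.0),
}


@dataclass
class EventAnnotation:
    discharges: list          # (t_start, t_end) seconds, merged
    segments: list            # inter-discharge (t_start, t_end), >= min gap


@dataclass
class PSDEstimate:
    frequencies_hz: np.ndarray
    power: np.ndarray         # unit-peak normalized
    window_s: float
    overlap_frac: float


@dataclass
class SDERun:
    t: np.ndarray             # decimated time axis (s)
    y: np.ndarray             # (n, 8) decimated rescaled states
    lfp_t: np.ndarray         # full-rate time axis (s)
    lfp: np.ndarray           # full-rate weighted LFP (mV)
    fs: float                 # LFP sampling rate (Hz)
    params: ModelParams
    noise: NoiseSpec


@njit(cache=True)
def _em_loop(y, n, dt, xi, A, B, G, C1, C2, C3, C4, C5, C6, C7,
             ta, tb, tg, pbar, vmax, r, vh, out_states, store_every):
    lfp = np.empty(n)
    for i in range(n):
        y0, y1, y2, y3, y5, y6, y7, y8 = (
            y[0], y[1], y[2], y[3], y[4], y[5], y[6], y[7])
        pt = pbar + xi[i]
        a5 = A * ta * pt + C2 * y1 - C4 * y2 - C7 * y3
        e5 = min(max(r * (vh - a5), -700.0), 700.0)
        e6 = min(max(r * (vh - C1 * y0), -700.0), 700.0)
        e7 = min(max(r * (vh - C3 * y0), -700.0), 700.0)
        e8 = min(max(r * (vh - (C5 * y0 - C6 * y2)), -700.0), 700.0)
        S5 = vmax / (1.0 + np.exp(e5))
        S6 = vmax / (1.0 + np.exp(e6))
        S7 = vmax / (1.0 + np.exp(e7))
        S8 = vmax / (1.0 + np.exp(e8))
        y[0] = y0 + dt * y5
        y[1] = y1 + dt * y6
        y[2] = y2 + dt * y7
        y[3] = y3 + dt * y8
        y[4] = y5 + dt * (A / ta * S5 - 2.0 / ta * y5 - y0 / ta**2)
        y[5] = y6 + dt * (A / ta * S6 - 2.0 / ta * y6 - y1 / ta**2)
        y[6] = y7 + dt * (B / tb * S7 - 2.0 / tb * y7 - y2 / tb**2)
        y[7] = y8 + dt * (G / tg * S8 - 2.0 / tg * y8 - y3 / tg**2)
        lfp[i] = A * ta * pbar + C2 * y[1] - C4 * y[2] - C7 * y[3]
        if i % store_every == 0:
            out_states[i // store_every] = y
    return lfp


def simulate_sde(p: ModelParams, noise: NoiseSpec, duration_s: float,
                 ic=None, store_every: int = 10) -> SDERun:
    """Euler-Maruyama trajectory with per-step Gaussian input noise.

    The stepper advances the physical-units form of the model, so the
    step size is in seconds; with ``sigma = 0`` it reduces to fixed-step
    Euler on the deterministic system.  A fixed seed makes the output
    bit-reproducible.  NaN or overflow aborts with a diagnostic.
    """
    n = int(round(duration_s / noise.dt))
    rng = np.random.default_rng(noise.seed)
    scale = noise.sigma * np.sqrt(_REF_DT / noise.dt)
    xi = rng.normal(0.0, 1.0, n) * scale if noise.sigma > 0 else np.zeros(n)
    if ic is None:
        y = np.array([0.05, 0.1, 0.1, 0.01, 0.0, 0.0, 0.0, 0.0])
    else:
        y = model.to_original_form(np.asarray(ic, dtype=float), p)
    n_store = (n + store_every - 1) // store_every
    out_states = np.empty((n_store, 8))
    lfp = _em_loop(y.copy(), n, noise.dt, xi, p.A, p.B, p.G, p.C1, p.C2,
                   p.C3, p.C4, p.C5, p.C6, p.C7, p.tau_a, p.tau_b, p.tau_g,
                   p.p_mean, p.sigmoid.vmax, p.sigmoid.steepness,
                   p.sigmoid.v_half, out_states, store_every)
    if not np.all(np.isfinite(lfp)):
        bad = int(np.argmax(~np.isfinite(lfp)))
        raise FloatingPointError(
            f"Euler-Maruyama overflow at t={bad * noise.dt:.4f} s; "
            "reduce dt or noise amplitude")
    t_full = np.arange(1, n + 1) * noise.dt
    t_dec = t_full[::store_every][:n_store]
    states = model.to_fast_form(out_states, p)
    return SDERun(t_dec, states, t_full, lfp, 1.0 / noise.dt, p, noise)


def detect_discharges(t, x, k: float = 6.0, merge_s: float = 0.5,
                      min_gap_s: float = 2.0) -> EventAnnotation:
    """Large-amplitude discharge events by a robust amplitude criterion.

    Samples deviating from the median by more than ``k`` scaled MADs are
    event samples; events closer than ``merge_s`` are merged, and the
    remaining quiet stretches of at least ``min_gap_s`` become the
    inter-discharge segments.
    """
    t = np.asarray(t)
    x = np.asarray(x)
    med = np.median(x)
    mad = 1.4826 * np.median(np.abs(x - med))
    if mad == 0:
        return EventAnnotation([], [(float(t[0]), float(t[-1]))])
    idx = np.where(np.abs(x - med) > k * mad)[0]
    events = []
    for i in idx:
        if events and t[i] - events[-1][1] < merge_s:
            events[-1][1] = t[i]
        else:
            events.append([float(t[i]), float(t[i])])
    segments = []
    prev = float(t[0])
    for a, b in events:
        if a - prev >= min_gap_s:
            segments.append((prev, a))
        prev = b
    if float(t[-1]) - prev >= min_gap_s:
        segments.append((prev, float(t[-1])))
    return EventAnnotation([tuple(e) for e in events], segments)


def normalized_psd(x, fs: float, window_s: float = 4.0,
                   overlap_frac: float = 0.5) -> PSDEstimate:
    """Averaged-periodogram (Welch, Hann taper) with unit-peak power."""
    x = np.asarray(x, dtype=float)
    nper = int(window_s * fs)
    if len(x) < 3 * nper:
        raise ValueError(
            f"segment of {len(x) / fs:.1f} s too short for {window_s} s "
            "windows (needs >= 3 windows)")
    x = x - x.mean()
    f, P = welch(x, fs=fs, nperseg=nper, noverlap=int(overlap_frac * nper),
                 detrend="linear")
    return PSDEstimate(f, P / P.max(), window_s, overlap_frac)


def dominant_peak(psd: PSDEstimate, band_hz=(1.0, 10.0)) -> float:
    """Frequency of maximal power in ``band_hz``; ties break low."""
    m = (psd.frequencies_hz >= band_hz[0]) & (psd.frequencies_hz <= band_hz[1])
    if not np.any(m):
        raise ValueError(f"empty band {band_hz} at this resolution")
    f, P = psd.frequencies_hz[m], psd.power[m]
    return float(f[np.argmax(P)])


@dataclass
class ScenarioBundle:
    run: SDERun
    annotation: EventAnnotation
    psd: PSDEstimate            # PSD of concatenated inter-discharge LFP
    psp: tuple                  # (EPSP, slow IPSP, fast IPSP) decimated


def generate_scenario(preset: ScenarioPreset | str, duration_s: float = 100.0,
                      seed: int = 0, params: ModelParams | None = None,
                      dt: float = _REF_DT) -> ScenarioBundle:
    """One deterministic-per-seed record of a full pre-ictal scenario."""
    if isinstance(preset, str):
        preset = PRESETS[preset]
    base = params if params is not None else table1()
    p = base.with_(B=preset.B, C3=preset.C3, C5=preset.C5,
                   sigma=preset.sigma)
    run = simulate_sde(p, NoiseSpec(sigma=preset.sigma, dt=dt, seed=seed),
                       duration_s)
    ann = detect_discharges(run.lfp_t, run.lfp)
    seg = interdischarge_signal(run, ann)
    psd = normalized_psd(seg, run.fs)
    return ScenarioBundle(run, ann, psd, model.psp_components(run.y, p))


def interdischarge_signal(run: SDERun, ann: EventAnnotation,
                          skip_s: float = 2.0) -> np.ndarray:
    """Concatenated mean-free LFP over the inter-discharge segments.

    The first ``skip_s`` seconds are always excluded (startup transient).
    Falls back to the post-transient signal when no quiet segment exists.
    """
    fs = run.fs
    parts = []
    for a, b in ann.segments:
        a = max(a, skip_s)
        if b - a < 2.0:
            continue
        i, j = int(a * fs), int(b * fs)
        seg = run.lfp[i:j]
        parts.append(seg - seg.mean())
    if not parts:
        seg = run.lfp[int(skip_s * fs):]
        return seg - seg.mean()
    return np.concatenate(parts)
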