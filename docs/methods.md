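# Methods

## Model and time-scale structure

The model couples four neuronal subpopulations — pyramidal cells, a second
excitatory pool, dendrite-projecting slow interneurons (SOM+) and
soma-projecting fast interneurons (PV+) — through average post-synaptic
potentials. Each synapse class is a critically damped second-order filter
with gain/time-constant pairs (A, τₐ), (B, τ_b), (G, τ_g), and each
population converts potential to rate through the sigmoid
S(v) = vmax / (1 + exp(r (v₀ − v))) with vmax = 5 s⁻¹, r = 0.56 mV⁻¹,
v₀ = 6 mV. Two equivalent forms are implemented: the physical-units form
(PSPs in mV, time in seconds; used by the stochastic stepper) and the
rescaled slow–fast form (each PSP divided by its time constant, time in
units of τ_g; used by all geometric and spectral analysis). The package
treats the rescaled form as the defining one and reconstructs the
physical form by inverting the variable conversion, because only the
rescaled system is internally consistent as printed in its source; the
`tests/test_model.py` dual-integration test pins the equivalence.

Reference parameters (the `table1()` preset): A = 5, B = 5, G = 35 mV,
p = 90 s⁻¹, C1 = 135, C2 = 108, C3 = 80, C4 = 25, C5 = 450, C6 = 121,
C7 = 121, τₐ = 0.01 s, τ_b = 0.05 s, τ_g = 0.003 s, giving δ = τ_g/τₐ =
0.3 and ε = τₐ/τ_b = 0.2. This parse is validated at test time against
the set's own derived anchors — fold points v0 = 1.2343 / 9.9976,
transcritical gains 16.7817 / 5.4817, δ and ε — via
`params.validate_anchors`; a parameter file claiming to be the reference
set but failing the anchors is rejected. (A parse with C6 = 12, C7 = 112
was considered and rejected by exactly this criterion: it produces no
folded manifold in the physical window.)

Parameters that matter most downstream: `B` (slow inhibition, the
bifurcation parameter of every one-parameter diagram), `C3` (pyramidal →
SOM+ contacts; moves the ordinary-singularity curve and hence the
Hopf/limit-point skeleton, switching excitability class), `C5`
(pyramidal → PV+ contacts; sets the number of fast spikes per burst).

## Geometric reduction

* Critical manifold: the explicit graph v3 = K(v0, v2) = G·S(C5 τₐ v0 −
  C6 τ_b v2). The fast-layer Jacobian is state-independent with the double
  eigenvalue −1, so no fold or loss of normal hyperbolicity occurs in the
  fast direction.
* Super-slow manifold L⁰: the zero set of Φ(v0, v2) = A·S(...) − v0 with
  v3 eliminated through K. For each v0 on a uniform grid all v2 roots are
  bracketed by a dense sign scan (window v2 ∈ [−30, 200], 2 300 points)
  and polished by Brent's method, then chained into branches by
  nearest-neighbour continuation with a 0.5 mV jump threshold; a root
  with no predecessor opens a new branch, so branch birth/death is
  explicit. Two branches exist in the physical window; the upper one is
  folded. Traces are cached on the parameters Φ actually contains —
  neither B nor C3 appears, which the tests assert numerically and which
  makes (B, C3) scans cheap.
* Slopes by implicit differentiation of Φ (analytic partials of the
  nested sigmoids); curvature by central differencing of the analytic
  slope with on-branch re-polishing (step 1e−5, cross-checked against a
  finite-difference slope at 1e−4 relative tolerance).
* Folds: sign changes of M′ on the folded branch, refined by Brent to
  |M′| < 1e−10. Exactly two folds are required in v0 ∈ [0, 12]; any other
  count raises rather than guessing.
* Folded singularities are classified through det = −M″·F7 (the trace
  vanishes identically on the fold set): saddle / center / nilpotent with
  a nilpotent tolerance of 1e−8 after normalizing by |M″|. Ordinary
  singularities (intersections of v2 = B·S(C3 τₐ v0) with L⁰) use the
  full planar trace/determinant classification. The desingularized flow
  is implemented exactly as printed; desingularized time runs backwards
  on the repelling side and no orientation correction is attempted.

## Bifurcation scans

Equilibria of the full system are the points of L⁰ satisfying the SOM+
balance, so the equilibrium branch for fixed C3 is parameterized by v0
with B(v0) = M(v0)/S(C3 τₐ v0); folds in B are turning points of a smooth
scalar function and cannot be missed by parameterization. Spectra come
from the analytic 8×8 Jacobian on a 2 200-point grid (the trivial fast
pair −1, −1 never crosses; working on the full 8-D system rather than the
6-D reduction changes no detection). Hopf points are grid events where
the number of unstable eigenvalues jumps by 2, bisected on the real part
of the critical complex pair to |Re λ| < 1e−8; frequencies are reported
in Hz via f = |Im λ|/(2π τ_g). Limit points are sign changes of the
analytic dB/dv0. Events closer than two grid intervals trigger a warning
instead of being merged silently.

Labeling: the two harmonic Hopf points on the low-v2 branch are H1 (low
v0) and H2 (high v0); the singular-Hopf points on the folded branch are
H4 (near fold p1) and H3 (near fold p2). Ordering the four points by v0
does not reproduce the conventional names (H4 sits at lower v0 than H3),
so the branch-geometry rule is used.

Codimension-2 structure is reported as count-change thresholds, not
normal forms: the C3 value where the Hopf count changes (three to four
near C3 ≈ 19) is bisected to ΔC3 < 0.05, and cusp-like fold-pair
creation/annihilation (the LP count changing by two, near C3 ≈ 141) to
ΔC3 < 0.2. A second fold-pair merge, on the folded branch near C3 ≈ 76,
bounds the window in which limit points exist between H3 and H4.

## Orbit characterization

Deterministic integration uses LSODA at rtol 1e−8 / atol 1e−10 (end state
stable to ~1e−5 under tolerance halving). Periods are read from upward
crossings of the mid-level of the super-slow variable v2 — a bursting
orbit crosses a v0 section once per fast spike, whereas v2 traverses its
range exactly once per cycle — and require a return-time coefficient of
variation below 1%; "no periodic attractor" (sub-threshold amplitude) and
"period ambiguity" are distinct failures.

Fast spikes: prominent v0 maxima (prominence ≥ 5% of the cycle amplitude)
are clustered with a gap threshold of 10 τₐ = 0.1 s; each cluster of k
maxima counts k − 1 spikes, so the burst's terminating slow-wave crest is
discounted and a relaxation or sinusoidal cycle counts zero. At (C3 = 80,
C5 = 350) this yields 4 spikes at B = 5 falling monotonically to 0 at
B = 16.

Canard labels are operational, with config-exposed thresholds: sinusoidal
below 25% of the fold-to-fold v0 span; a cycle that spends ≥ 5% of its
period within 0.3 mV (in the (v0, v2) plane) of the repelling middle
branch is a canard, "with head" if it also crosses to the left attracting
branch, "without head" otherwise; a large-amplitude cycle hugging only
attracting branches is relaxation. The distance threshold reflects that
at δ = 0.3, ε = 0.2 the true repelling slow manifold sits an O(ε)
distance from L⁰: measured dwell fractions are 0.06–0.18 for
without-head canards on the small branch and 0.000 for relaxation
cycles. Stable with-head orbits exist only inside the exponentially
narrow canard explosion and are generally not resolvable as a separate
stable family at these scale ratios; the with-head rule is exercised on
synthetic orbits.

Bistability (C3 = 80, C5 = 80): two seeds — a perturbed equilibrium and a
converged large-cycle state — are integrated for 50 s (last 20 s kept);
the runs witness coexistence when their v0 amplitudes differ by more than
25% of the larger. A fixed amplitude *ratio* of 3 was tried first and
discarded: inside the canard explosion the small branch inflates to
~14 mV against the ~25 mV relaxation cycle, so a ratio criterion
truncates the window. Endpoints are bisected to ΔB < 0.005 with attractor
states inherited between steps (hysteresis), giving (4.758, 4.816)
against the reported (4.75, 4.81).

Excitability: the large attractor is continued upward in B by simulation
until it dies at B*. A frequency collapsing below 0.05 Hz at termination
marks type-I directly; that reading alone cannot discriminate here,
because for both C3 = 50 and C3 = 80 the *stable* attractor dies on a
fold of cycles with finite frequency (~1.5 / ~1.9 Hz) — the
zero-frequency termination belongs to the unstable homoclinic family,
whose continuation is out of scope. The implemented discriminator uses
the equilibrium skeleton at B*: saddle equilibria coexisting with the
attractor (termination inside the limit-point window, the homoclinic
class) mark type-I; termination with no saddle, adjacent to the
subcritical Hopf, marks type-II. This reproduces type-I at C3 = 50 and
type-II at C3 = 80, with the type-II terminal frequency inside the
1.8–3.5 Hz range characteristic of that regime.

## Stochastic LFP stage

The stepper is Euler–Maruyama on the physical-units form at dt = 1e−4 s,
with the input rate perturbed as p(t) = p + ξ_k, ξ_k ~ N(0, σ²·(1e−4/dt))
held constant within each step — at the reference step the per-step
deviate has exactly variance σ², and the rescaling keeps the realized
spectral density consistent when the step is halved (the PSD-peak test
asserts this). With σ = 0 the stepper is fixed-step Euler and agrees with
the adaptive solution to <1e−2 away from discharges; through a discharge
the O(dt) error is amplified by the fast dynamics, so trajectory-level
comparisons are made from quiescent states.

The three presets place the system at the pre-ictal reference settings:
`type_I` (B = 23, C3 = 35, C5 = 200), `type_II` (B = 17.8, C3 = 80,
C5 = 200), `near_H3` (B = 4.7, C3 = 80, C5 = 200), all σ = 2 s⁻¹.
Discharges are samples deviating from the median by > 6 scaled MADs,
merged within 0.5 s; inter-discharge segments are the quiet stretches of
≥ 2 s (the 2 s startup transient is always excluded). PSDs are Welch
averages (4 s Hann windows, 50% overlap, linear detrend) normalized to
unit peak. The type-II inter-discharge spectrum peaks at 3.5 Hz — the
noise-driven resonance of the weakly stable focus left by the singular
Hopf H4 (eigenfrequency 3.31 Hz) — the near-H3 setting at 6 Hz, and the
type-I background stays broadband (no bin holds half the 1–40 Hz band
power).

What the generator emulates and what it does not: it reproduces the
background/narrow-band/discharge taxonomy and the band-specific
inter-discharge peaks of intracerebral recordings, deterministically per
seed. It does not emulate electrode physics, 1/f background, artifacts,
or clinically realistic discharge *rates*: under the per-step noise
convention the effective input perturbation (A τₐ σ ≈ 0.1 mV) is small
relative to the excitable threshold at the preset gains, so spontaneous
discharges are rarer than in real recordings — passing tests certify the
spectral biomarkers and the detection pipeline, not event statistics.

## Problem sizes and numerical defaults

Manifold traces use 1 400 v0 points (2 200 for detection-grade
continuation); equilibrium scans 20 000 points; folds and Hopf points are
bisected to 1e−10 or better; orbit work uses 20 s transients and 20 s
measurement windows; bistability endpoints use 50 s runs; spectral
estimates use 100 s records (5 seeds where averaged). These sizes make
every reported quantity stable to grid doubling or tolerance halving, as
the property tests check.

## Known limitations

Unstable periodic orbits, homoclinic branches and two-parameter loci are
not continued (count-change proxies stand in for BT/cusp points); the
maximal canard is only approximated as the with/without-head boundary;
classification stops at the saddle/center/nilpotent trichotomy, with no
unfolding of the degenerate transcritical points; no fitting to recorded
data is provided.
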