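# canardnmm

Three-time-scale analysis of a four-subpopulation neural mass model of
hippocampal/cortical activity, aimed at the dynamics of epileptic
transitions: how narrow-band "pre-ictal" oscillations, large-amplitude
discharges and background activity are organized by canard solutions.

## Who this is for

Computational neuroscientists and applied dynamicists who want a tested,
scriptable implementation of (i) the Wendling-type neural mass model with
pyramidal cells, a second excitatory pool, dendrite-projecting slow (SOM+)
and soma-projecting fast (PV+) interneurons, (ii) its geometric
singular-perturbation reduction and folded-singularity classification,
(iii) eigenvalue-based bifurcation scans replacing interactive
continuation software, and (iv) stochastic LFP synthesis with the spectral
biomarkers that intracerebral recordings are compared against.

## The model

Each subpopulation converts its mean membrane potential to a firing rate
through the sigmoid `S(v) = 5 / (1 + exp(0.56 (6 - v)))` and back to a
post-synaptic potential through second-order synaptic kinetics with gain
`A` (glutamatergic, τₐ = 10 ms), `B` (slow GABAergic dendritic,
τ_b = 50 ms) or `G` (fast GABAergic somatic, τ_g = 3 ms); connectivity
constants `C1..C7` scale the average numbers of synaptic contacts and `p`
is the mean external drive. Dividing each PSP by its time constant and
rescaling time by τ_g puts the 8-dimensional system in slow–fast form with
scale ratios δ = τ_g/τₐ = 0.3 and ε = τₐ/τ_b = 0.2: the PV+ pair is fast,
the two pyramidal pairs are slow, and the SOM+ pair is super-slow.

Sending δ → 0 collapses the fast pair onto the critical manifold
`v3 = K(v0, v2)` (its layer Jacobian has the double eigenvalue −1, so the
manifold is uniformly attracting); sending ε → 0 afterwards restricts the
slow flow to the super-slow manifold L⁰, a folded curve `v2 = M(v0)`. The
desingularized flow on L⁰,

    v0' = −y7,     y7' = −M'(v0) · F7(v0, M(v0), y7),

has *folded singularities* where M'(v0) = 0. Because the synaptic kinetics
are second order, the Jacobian trace vanishes identically on the fold set
and each folded point is a saddle, a center, or nilpotent according to the
sign of `det = −M''(v0) · F7`. The nilpotent case marks a *degenerate
transcritical* interaction with an ordinary equilibrium, the skeleton
around which singular Hopf points, canard explosions, bursting and the
type-I/type-II excitability switch organize.

## Worked example

```python
import canardnmm as cn

p = cn.table1()                      # reference bursting parameter set
f1, f2 = cn.fold_points(p)
print(f1.v0, f2.v0)                  # 1.2342701760 9.9975659070
print(cn.transcritical_B(p, "p1"))   # 16.781603123  (folded/ordinary coincidence)
print(cn.transcritical_B(p, "p2"))   # 5.4816901939

pts = cn.hopf_points(p, C3=80.0)     # four Hopf points along the branch
for q in sorted(pts, key=lambda q: q.B):
    print(q.label, round(q.B, 3), round(q.frequency_hz, 2))
# H1 1.199 29.47
# H2 3.285 29.06
# H3 4.736 6.1
# H4 16.528 3.31

from canardnmm import orbits
cyc = orbits.find_limit_cycle(p.with_(B=5.0, C3=80.0, C5=350.0),
                              orbits._LARGE_IC)
print(cyc.period_s, orbits.count_fast_spikes(cyc))
# 0.4904  4     -> a 2 Hz bursting discharge with 4 fast spikes per burst
```

The fold coordinates are the folded singularities p1/p2 of the reduced
flow; the two transcritical gains bound the B-range in which p1 is a
center and p2 a saddle. H3 and H4 are the singular Hopf points next to
p2 and p1; the orbit at (B=5, C3=80, C5=350) is the 4-spike burster whose
spikes are lost one by one as B grows (0 spikes by B=16).

A stochastic scenario, from the shell:

```bash
canardnmm simulate --preset type_II --duration 100 --seed 1 --out out/
canardnmm spectrum --lfp-csv out/lfp.csv --out out/
# {"peak_hz": 3.5}
```

The `type_II` preset (B=17.8, C3=80, C5=200, σ=2) produces inter-discharge
oscillations whose normalized power spectrum peaks at 3.5 Hz — the
narrow-band biomarker that distinguishes the type-II excitable regime from
the broadband `type_I` background. Other subcommands: `reduce`
(manifold/fold/singularity tables), `bifurcate` (equilibrium branches and
bifurcation points), `orbits` (cycle characterization).

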