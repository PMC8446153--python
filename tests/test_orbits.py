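"""Limit cycles: spike counting, canard classification, bistability."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import canardnmm as cn
from canardnmm import bifurcation as bf, orbits


class TestIntegrate:
    def test_equilibrium_stays_put(self, p_table1):
        q = p_table1.with_(B=25.0, C3=50.0)
        eq = cn.solve_equilibria(q)[0]
        ts = orbits.integrate(q, eq, 2.0)
        assert np.abs(ts.y - eq).max() < 1e-7

    def test_tolerance_halving_stability(self, p_table1):
        q = p_table1.with_(B=25.0, C3=50.0)
        eq = cn.solve_equilibria(q)[0]
        ic = eq + 0.01
        a = orbits.integrate(q, ic, 3.0, rtol=1e-8, atol=1e-10)
        b = orbits.integrate(q, ic, 3.0, rtol=5e-9, atol=5e-11)
        assert np.abs(a.y[-1] - b.y[-1]).max() < 1e-5

    def test_potentials_remain_physically_bounded(self, bursting_cycle):
        p = bursting_cycle.params
        hi = max(p.A, p.B, p.G) + 2.0
        v = bursting_cycle.y[:, :4]
        assert v.min() > -2.0 and v.max() < hi * p.sigmoid.vmax


class TestLimitCycle:
    def test_bursting_attractor_found(self, bursting_cycle):
        assert bursting_cycle.period_s > 0
        assert bursting_cycle.amplitude_v0 > 15.0
        # endpoints close after one period (Poincare closure)
        assert np.abs(bursting_cycle.y[0] - bursting_cycle.y[-1]).max() < 0.5

    def test_no_cycle_in_stable_regime(self, p_table1):
        with pytest.raises(orbits.NoPeriodicAttractor):
            orbits.find_limit_cycle(p_table1.with_(B=25.0),
                                    orbits._LARGE_IC, transient_s=10.0,
                                    window_s=10.0)

    def test_harmonic_cycle_frequency_matches_hopf_pair(self, p_table1):
        """Just past H1 the orbit frequency equals the eigenvalue
        frequency of the crossing pair to within 5%."""
        h1 = next(pt for pt in bf.hopf_points(p_table1, C3=80.0)
                  if pt.label == "H1")
        q = p_table1.with_(C3=80.0, B=h1.B + 0.05)
        eq = cn.solve_equilibria(q)[0]
        cyc = orbits.find_limit_cycle(q, eq + 1e-3, transient_s=4.0,
                                      window_s=2.0, amp_tol=1e-4)
        assert cyc.frequency_hz == pytest.approx(h1.frequency_hz, rel=0.05)


class TestSpikeCount:
    def test_reference_burst_has_four_fast_spikes(self, bursting_cycle):
        assert orbits.count_fast_spikes(bursting_cycle) == 4

    def test_pure_sinusoid_counts_zero(self, p_table1):
        t = np.linspace(0, 0.5, 2000)
        y = np.zeros((len(t), 8))
        y[:, 0] = 10 + 5 * np.sin(2 * np.pi * 2 * t)
        cyc = orbits.LimitCycle(t, y, 0.5, p_table1)
        assert orbits.count_fast_spikes(cyc) == 0

    def test_synthetic_burst_counts_spikes_not_slow_wave(self, p_table1):
        """Three fast crests plus one slow crest -> 3 fast spikes."""
        t = np.linspace(0, 0.5, 5000)
        y = np.zeros((len(t), 8))
        v0 = np.full(len(t), 2.0)
        for tc in (0.05, 0.09, 0.13):     # fast spikes, 40 ms apart
            v0 += 20 * np.exp(-((t - tc) / 0.006) ** 2)
        v0 += 8 * np.exp(-((t - 0.21) / 0.03) ** 2)  # slow-wave crest
        y[:, 0] = v0
        cyc = orbits.LimitCycle(t, y, 0.5, p_table1)
        assert orbits.count_fast_spikes(cyc) == 3

    def test_count_invariant_to_tolerance_halving(self, bursting_cycle):
        q = bursting_cycle.params
        cyc = orbits.find_limit_cycle(q, orbits._LARGE_IC, transient_s=20.0)
        assert orbits.count_fast_spikes(cyc) == 4
        assert cyc.period_s == pytest.approx(bursting_cycle.period_s,
                                             rel=1e-3)


class TestClassification:
    def test_bursting_label(self, bursting_cycle):
        assert orbits.classify_cycle(bursting_cycle) == "bursting"

    def test_relaxation_label_at_high_B(self):
        q = cn.table1().with_(B=16.0, C3=80.0, C5=350.0)
        cyc = orbits.find_limit_cycle(q, orbits._LARGE_IC)
        assert orbits.classify_cycle(cyc) == "relaxation"

    def test_small_cycle_near_h3_is_sinusoidal(self):
        q = cn.table1().with_(B=4.74, C3=80.0, C5=80.0)
        eq = cn.solve_equilibria(q)[-1]
        cyc = orbits.find_limit_cycle(q, eq + 1e-3, transient_s=30.0)
        assert orbits.classify_cycle(cyc) == "sinusoidal"

    def test_canard_without_head_on_small_branch(self):
        """Inside the coexistence window the small-branch attractor dwells
        along the repelling middle branch and returns to the right
        attracting branch without reaching the left one."""
        q = cn.table1().with_(B=4.80, C3=80.0, C5=80.0)
        eq = cn.solve_equilibria(q)[-1]
        cyc = orbits.find_limit_cycle(q, eq + 1e-3, transient_s=40.0)
        assert orbits.classify_cycle(cyc) == "canard-without-head"

    def test_canard_with_head_rule_on_synthetic_orbit(self, p_table1, folds):
        """A cycle tracing the repelling middle branch and crossing to the
        left attracting branch is labelled canard-with-head."""
        from canardnmm import manifold as mf
        f1, f2 = folds
        b = next(br for br in mf.trace_L0(p_table1) if br.folded)
        n = 400
        # follow the middle branch downward, then swing far left and back
        v0_mid = np.linspace(f2.v0, f1.v0, n)
        v2_mid = np.interp(v0_mid, b.v0, b.v2)
        v0_head = np.concatenate([np.linspace(f1.v0, -1.0, n // 2),
                                  np.linspace(-1.0, f2.v0, n // 2)])
        v2_head = np.full(n, v2_mid[-1])
        y = np.zeros((2 * n, 8))
        y[:, 0] = np.concatenate([v0_mid, v0_head])
        y[:, 2] = np.concatenate([v2_mid, v2_head])
        t = np.linspace(0, 1.0, 2 * n)
        cyc = orbits.LimitCycle(t, y, 1.0, p_table1)
        assert orbits.classify_cycle(cyc) == "canard-with-head"

    def test_classification_is_pure(self, bursting_cycle):
        a = orbits.classify_cycle(bursting_cycle)
        b = orbits.classify_cycle(bursting_cycle)
        assert a == b


class TestBistability:
    def test_probe_inside_and_outside_window(self):
        q = cn.table1().with_(C3=80.0, C5=80.0)
        assert orbits.probe_bistability(q, 4.78).coexist
        r = orbits.probe_bistability(q, 4.90)
        assert not r.coexist

    def test_single_attractor_far_below_h3(self):
        q = cn.table1().with_(C3=80.0, C5=80.0)
        r = orbits.probe_bistability(q, 4.5, t_s=20.0, keep_s=8.0)
        assert not r.coexist

    def test_planted_normal_form_endpoints(self):
        """Subcritical-Hopf normal form r' = mu*r + r^3 - r^5: the rest
        state dies at mu = 0 and the large branch at mu = -1/4; the
        hysteresis bisection recovers both closed-form endpoints (the
        rest-state edge to the finite-horizon escape resolution)."""

        def settle(mu, r0, T):
            sol = solve_ivp(lambda t, r: mu * r + r**3 - r**5,
                            (0, T), [r0], rtol=1e-10, atol=1e-12)
            return float(sol.y[0, -1])

        def small_survives(mu, state):
            r_end = settle(mu, max(state, 1e-2), 5000)
            return r_end < 0.5, r_end

        def large_survives(mu, state):
            r_end = settle(mu, state, 5000)
            return r_end > 0.5, r_end

        upper, _ = orbits.bisect_boundary(small_survives, -0.2, 0.2,
                                          1e-2, 1e-4)
        lower, _ = orbits.bisect_boundary(large_survives, -0.2, -0.4,
                                          1.2, 1e-4)
        assert upper == pytest.approx(0.0, abs=2e-3)
        assert lower == pytest.approx(-0.25, abs=1e-3)


class TestExcitability:
    def test_types_match_connectivity_regimes(self, p_table1):
        """Low pyramidal->SOM+ connectivity terminates inside the saddle
        window (type-I); high connectivity terminates at the Hopf with a
        finite low frequency (type-II)."""
        lab50, bterm50, _ = orbits.excitability_type(p_table1, 50.0)
        lab80, bterm80, f80 = orbits.excitability_type(p_table1, 80.0)
        assert lab50 == "type-I"
        assert lab80 == "type-II"
        assert 1.8 <= f80 <= 3.5
        assert bterm80 < bterm50
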