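"""Geometric reduction: manifold tracing, folds and singularity classes."""

import numpy as np
import pytest
from scipy.optimize import bisect

import canardnmm as cn
from canardnmm import manifold as mf, model


class TestTrace:
    def test_curve_independent_of_B_and_C3(self, p_table1):
        base = mf.trace_L0(p_table1)
        for B, C3 in [(2.0, 80.0), (15.0, 80.0), (5.0, 31.0)]:
            other = mf.trace_L0(p_table1.with_(B=B, C3=C3))
            assert len(other) == len(base)
            for a, b in zip(base, other):
                np.testing.assert_allclose(a.v2, b.v2, atol=1e-12)

    def test_gridpoints_verified_by_independent_bisection(self, p_table1):
        b = mf.trace_L0(p_table1)[1]
        for i in range(0, len(b.v0), len(b.v0) // 17):
            f = lambda v2: float(mf.implicit_residual(b.v0[i], v2, p_table1))
            v2 = bisect(f, b.v2[i] - 0.05, b.v2[i] + 0.05, xtol=1e-12)
            assert abs(v2 - b.v2[i]) < 1e-9

    def test_slope_matches_finite_difference(self, p_table1):
        b = mf.trace_L0(p_table1)[1]
        i = len(b.v0) // 3
        h = 1e-5
        v2p = mf._polish(b.v0[i] + h, b.v2[i], p_table1)
        v2m = mf._polish(b.v0[i] - h, b.v2[i], p_table1)
        fd = (v2p - v2m) / (2 * h)
        assert abs(fd - b.dM[i]) / max(abs(fd), 1e-12) < 1e-4

    def test_critical_manifold_graph(self, p_table1):
        p = p_table1
        assert mf.critical_manifold_v3(-1e4, 0.0, p) < 1e-10
        half = mf.critical_manifold_v3(
            (p.sigmoid.v_half + p.C6 * p.tau_b * 2.0) / (p.C5 * p.tau_a),
            2.0, p)
        assert half == pytest.approx(p.G * p.sigmoid.vmax / 2)


class TestFolds:
    def test_two_folds_at_reference_positions(self, folds):
        f1, f2 = folds
        assert f1.v0 == pytest.approx(1.2343, abs=1e-3)
        assert f2.v0 == pytest.approx(9.9976, abs=1e-3)

    def test_slope_vanishes_at_folds(self, p_table1, folds):
        for f in folds:
            assert abs(mf.manifold_slope(f.v0, p_table1)) < 1e-10

    def test_folds_move_continuously_with_drive(self, p_table1, folds):
        for frac in (0.99, 1.01):
            g1, g2 = mf.fold_points(
                p_table1.with_(p_mean=frac * p_table1.p_mean))
            assert abs(g1.v0 - folds[0].v0) < 0.1
            assert abs(g2.v0 - folds[1].v0) < 0.1

    def test_stability_labels_switch_at_folds(self, p_table1, folds):
        b = next(br for br in mf.trace_L0(p_table1) if br.folded)
        labels = dict(zip(b.v0, b.labels))
        assert labels[b.v0[0]] == "stable-left"
        mid = 0.5 * (folds[0].v0 + folds[1].v0)
        i = np.argmin(np.abs(b.v0 - mid))
        assert b.labels[i] == "unstable-middle"
        assert b.labels[-1] == "stable-right"


class TestDesingularizedFlow:
    def test_folded_and_regular_equilibria(self, p_table1, folds):
        f1, _ = folds
        assert np.allclose(mf.dsrs_rhs(f1.v0, 0.0, p_table1), 0.0, atol=1e-8)
        reg = mf.classify_regular(p_table1)[0]
        assert np.allclose(mf.dsrs_rhs(reg.v0, 0.0, p_table1), 0.0,
                           atol=1e-8)

    def test_rhs_second_component_flips_across_fold(self, p_table1, folds):
        f1 = folds[0]
        a = mf.dsrs_rhs(f1.v0 - 0.05, 0.01, p_table1)[1]
        b = mf.dsrs_rhs(f1.v0 + 0.05, 0.01, p_table1)[1]
        assert np.sign(a) != np.sign(b)

    def test_off_branch_evaluation_raises(self, p_table1):
        with pytest.raises(ValueError):
            mf.dsrs_rhs(24.9, 0.0, p_table1)

    def test_classification_against_numeric_jacobian(self, p_table1):
        """Trace/det formulas agree with a finite-difference Jacobian of
        the desingularized flow at a regular singularity."""
        reg = mf.classify_regular(p_table1)[0]
        h = 1e-6
        J = np.empty((2, 2))
        for j, e in enumerate(np.eye(2) * h):
            fp = mf.dsrs_rhs(reg.v0 + e[0], 0.0 + e[1], p_table1)
            fm = mf.dsrs_rhs(reg.v0 - e[0], 0.0 - e[1], p_table1)
            J[:, j] = (fp - fm) / (2 * h)
        tr_formula = sum(e.real for e in reg.eigenvalues)
        det_formula = np.prod([complex(e) for e in reg.eigenvalues]).real
        assert np.trace(J) == pytest.approx(tr_formula, rel=1e-3, abs=1e-6)
        assert np.linalg.det(J) == pytest.approx(det_formula, rel=1e-3)

    def test_folded_det_matches_numeric_jacobian(self, p_table1, folds):
        f1 = folds[0]
        h = 1e-5
        J = np.empty((2, 2))
        for j, e in enumerate(np.eye(2) * h):
            fp = mf.dsrs_rhs(f1.v0 + e[0], e[1], p_table1)
            fm = mf.dsrs_rhs(f1.v0 - e[0], -e[1], p_table1)
            J[:, j] = (fp - fm) / (2 * h)
        sp = mf.classify_folded(f1, p_table1)
        det_formula = np.prod([complex(e) for e in sp.eigenvalues]).real
        assert np.linalg.det(J) == pytest.approx(det_formula, rel=1e-3)
        assert abs(np.trace(J)) < 1e-4


class TestTranscritical:
    def test_reference_gains(self, p_table1):
        assert mf.transcritical_B(p_table1, "p1") == pytest.approx(
            16.7817, abs=1e-3)
        assert mf.transcritical_B(p_table1, "p2") == pytest.approx(
            5.4817, abs=1e-3)

    def test_nilpotent_at_coincidence(self, p_table1):
        for which in ("p1", "p2"):
            Bstar = mf.transcritical_B(p_table1, which)
            q = p_table1.with_(B=Bstar)
            f = mf.fold_points(q)[0 if which == "p1" else 1]
            assert mf.classify_folded(f, q, nilpotent_tol=1e-6) \
                .classification == "nilpotent"

    def test_folded_classes_swap_across_thresholds(self, p_table1):
        bp1 = mf.transcritical_B(p_table1, "p1")
        bp2 = mf.transcritical_B(p_table1, "p2")
        for B, idx, want in [(bp1 - 1, 0, "center"), (bp1 + 1, 0, "saddle"),
                             (bp2 - 1, 1, "saddle"), (bp2 + 1, 1, "center")]:
            q = p_table1.with_(B=B)
            f = mf.fold_points(q)[idx]
            assert mf.classify_folded(f, q).classification == want

    def test_regular_classes_swap_across_thresholds(self, p_table1, folds):
        bp1 = mf.transcritical_B(p_table1, "p1")
        bp2 = mf.transcritical_B(p_table1, "p2")
        for B, fold, want in [(bp1 - 0.5, folds[0], "saddle"),
                              (bp1 + 0.5, folds[0], "stable-focus"),
                              (bp2 - 0.2, folds[1], "stable-focus"),
                              (bp2 + 0.2, folds[1], "saddle")]:
            pts = mf.classify_regular(p_table1, B=B)
            nearest = min(pts, key=lambda s: abs(s.v0 - fold.v0))
            assert nearest.classification == want


class TestSlowLayerStability:
    def test_four_eigenvalues_stable_off_fold(self, p_table1, folds):
        """On attracting branches of the manifold all slow-layer
        eigenvalues are contracting; one real one flips at each fold."""
        b = next(br for br in mf.trace_L0(p_table1) if br.folded)
        f1, f2 = folds
        for v0 in (f1.v0 - 0.5, 0.5 * (f1.v0 + f2.v0), f2.v0 + 0.5):
            v2 = mf._polish(v0, float(np.interp(v0, b.v0, b.v2)), p_table1)
            lam = np.linalg.eigvals(mf.slow_layer_jacobian(v0, v2, p_table1))
            n_unstable = int(np.sum(lam.real > 0))
            inside = f1.v0 < v0 < f2.v0
            assert n_unstable == (1 if inside else 0)
            if inside:
                unstable = lam[lam.real > 0]
                assert np.all(np.abs(unstable.imag) < 1e-10)
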