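import numpy as np
import pytest

import circuitpareto as cp
from circuitpareto.sensitivity import (SensitivityError, grid_sensitivities,
                                       sensitivity_analytic, sensitivity_fd)

from conftest import random_theta


def neg_autoreg_closed_forms(x, n):
    """Hand-derived closed forms for negative autoregulation.

    With h = x^n/(1+x^n):  S_alpha = 1/(1+n*h),
    S_n = -n*h*ln(x)/(1+n*h).
    """
    h = x ** n / (1 + x ** n)
    return 1 / (1 + n * h), -n * h * np.log(x) / (1 + n * h)


def pos_autoreg_closed_forms(x, n):
    """S_alpha = (1+x^n)/(1+x^n-n);  S_n = n*ln(x)/(1+x^n-n)."""
    d = 1 + x ** n - n
    return (1 + x ** n) / d, n * np.log(x) / d


class TestClosedForms:
    def test_negative_autoreg_matches_derived_formulas(self, rng):
        m = cp.make_circuit("negative_autoreg")
        for _ in range(25):
            theta = random_theta(m, rng)
            ss = cp.stable_states(m, theta)[0]
            rec = sensitivity_analytic(m, theta, ss)
            s_a, s_n = neg_autoreg_closed_forms(ss.x, theta["n"])
            assert rec.value("x", "alpha") == pytest.approx(s_a, rel=1e-9)
            assert rec.value("x", "n") == pytest.approx(s_n, rel=1e-9,
                                                        abs=1e-12)

    def test_positive_autoreg_matches_derived_formulas(self, rng):
        m = cp.make_circuit("positive_autoreg")
        for _ in range(40):
            theta = random_theta(m, rng)
            branches = cp.stable_states(m, theta)
            if not branches:
                continue
            ss = branches[-1]
            rec = sensitivity_analytic(m, theta, ss)
            s_a, s_n = pos_autoreg_closed_forms(ss.x, theta["n"])
            assert rec.value("x", "alpha") == pytest.approx(s_a, rel=1e-9)
            assert rec.value("x", "n") == pytest.approx(s_n, rel=1e-9,
                                                        abs=1e-12)

    def test_balanced_negative_autoreg_values(self):
        # at alpha=2, n=1 the root sits exactly at x=1, where the root
        # does not move with n (S_n = 0) and S_alpha = 2/3
        m = cp.make_circuit("negative_autoreg")
        theta = {"alpha": 2.0, "n": 1.0}
        ss = cp.stable_states(m, theta)[0]
        rec = sensitivity_analytic(m, theta, ss)
        assert rec.value("x", "alpha") == pytest.approx(2 / 3, abs=1e-12)
        assert rec.value("x", "n") == pytest.approx(0.0, abs=1e-12)
        fd = sensitivity_fd(m, theta, ss)
        assert fd.value("x", "alpha") == pytest.approx(2 / 3, abs=1e-6)

    def test_saturated_positive_autoreg_pair(self):
        m = cp.make_circuit("positive_autoreg")
        theta = {"alpha": 50.0, "n": 10.0}
        ss = cp.stable_states(m, theta)[0]
        rec = sensitivity_analytic(m, theta, ss)
        assert round(rec.abs_value("x", "alpha"), 2) == 1.0
        assert round(rec.abs_value("x", "n"), 2) == 0.0


class TestFiniteDifferenceOracle:
    def test_analytic_agrees_with_fd_on_random_points(self, rng):
        for name in cp.CIRCUIT_NAMES:
            m = cp.make_circuit(name)
            checked = 0
            while checked < 15:
                theta = random_theta(m, rng)
                for ss in cp.stable_states(m, theta):
                    ana = sensitivity_analytic(m, theta, ss)
                    try:
                        fd = sensitivity_fd(m, theta, ss)
                    except cp.BranchJumpError:
                        continue
                    err = np.max(np.abs(ana.S - fd.S)
                                 / np.maximum(np.abs(ana.S), 1.0))
                    assert err < 1e-5, (name, theta)
                    checked += 1


class TestSignBoundsAndSymmetries:
    def test_positive_autoreg_amplifies_feedback_changes(self, rng):
        # S_alpha >= 1 on the stable branch, everywhere in range
        m = cp.make_circuit("positive_autoreg")
        checked = 0
        while checked < 40:
            theta = random_theta(m, rng)
            for ss in cp.stable_states(m, theta):
                rec = sensitivity_analytic(m, theta, ss)
                assert rec.value("x", "alpha") >= 1.0
                checked += 1

    def test_negative_autoreg_attenuates_feedback_changes(self, rng):
        m = cp.make_circuit("negative_autoreg")
        for _ in range(40):
            theta = random_theta(m, rng)
            ss = cp.stable_states(m, theta)[0]
            rec = sensitivity_analytic(m, theta, ss)
            assert 0.0 < rec.value("x", "alpha") < 1.0

    def test_negative_autoreg_cooperativity_sign_flips_at_balance(self):
        # S_n = 0 exactly where x_ss = 1 (alpha = 2); sign flips across it
        m = cp.make_circuit("negative_autoreg")
        n = 3.0
        vals = {}
        for alpha in (1.5, 2.0, 3.0):
            ss = cp.stable_states(m, {"alpha": alpha, "n": n})[0]
            vals[alpha] = sensitivity_analytic(
                m, {"alpha": alpha, "n": n}, ss).value("x", "n")
        assert vals[2.0] == pytest.approx(0.0, abs=1e-12)
        assert vals[1.5] > 0 and vals[3.0] < 0

    @pytest.mark.parametrize("name", ["double_positive", "toggle"])
    def test_exchange_symmetry_of_sensitivities(self, name):
        # S^x_{beta_x}(a, b) = S^y_{beta_y}(b, a) after relabeling
        m = cp.make_circuit(name)
        a, b, n = 9.0, 4.0, 1.7
        fwd = {"beta_x": a, "beta_y": b, "n": n, "gamma": 1.0}
        rev = {"beta_x": b, "beta_y": a, "n": n, "gamma": 1.0}
        recs_f = [sensitivity_analytic(m, fwd, s)
                  for s in cp.stable_states(m, fwd)]
        recs_r = [sensitivity_analytic(m, rev, s)
                  for s in cp.stable_states(m, rev)]
        got = sorted(r.value("x", "beta_x") for r in recs_f)
        mirrored = sorted(r.value("y", "beta_y") for r in recs_r)
        np.testing.assert_allclose(got, mirrored, rtol=1e-9)

    def test_downstream_gene_leaves_upstream_sensitivities_unchanged(self):
        # the cascade shares the autoregulated gene's sensitivity pair
        m1 = cp.make_circuit("positive_autoreg")
        m2 = cp.make_circuit("autoreg_plus_downstream")
        for alpha, n in ((7.0, 3.0), (50.0, 10.0), (30.0, 0.5)):
            s1 = cp.stable_states(m1, {"alpha": alpha, "n": n})[-1]
            th2 = {"beta_x": alpha, "beta_y": 5.0, "n": n}
            s2 = cp.stable_states(m2, th2)[-1]
            r1 = sensitivity_analytic(m1, {"alpha": alpha, "n": n}, s1)
            r2 = sensitivity_analytic(m2, th2, s2)
            assert r2.value("x", "beta_x") == pytest.approx(
                r1.value("x", "alpha"), rel=1e-10)
            assert r2.value("x", "n") == pytest.approx(
                r1.value("x", "n"), rel=1e-10, abs=1e-14)
            assert r2.value("x", "beta_y") == 0.0

    def test_leakiness_shrinks_negative_autoreg_sensitivities(self):
        # raising the basal rate L raises x_ss, so |S_alpha| shrinks at
        # every grid point; |S_n| changes sign where x_ss crosses 1, so
        # its shrinkage holds for the region's extent (grid max), not
        # pointwise
        m = cp.leaky_variant("negative_autoreg")
        alphas = np.linspace(0.5, 50, 10)
        ns = np.linspace(0.5, 10, 10)
        prev = None
        for L in (0.0, 0.1, 1.0, 10.0):
            vals = np.empty((10, 10, 2))
            for i, a in enumerate(alphas):
                for j, n in enumerate(ns):
                    theta = {"alpha": a, "n": n, "L": L}
                    ss = cp.stable_states(m, theta)[0]
                    rec = sensitivity_analytic(m, theta, ss)
                    vals[i, j] = np.abs(rec.S[0])
            if prev is not None:
                assert np.all(vals[..., 0] <= prev[..., 0] + 1e-12)
                assert vals[..., 1].max() <= prev[..., 1].max() + 1e-12
            prev = vals


class TestErrorHandling:
    def test_unstable_branch_rejected(self):
        m = cp.make_circuit("positive_autoreg")
        theta = {"alpha": 50.0, "n": 10.0}
        unstable = [s for s in cp.find_steady_states(m, theta)
                    if not s.stable and s.x > 1e-8][0]
        with pytest.raises(SensitivityError):
            sensitivity_analytic(m, theta, unstable)

    def test_zero_species_rejected(self):
        m = cp.make_circuit("positive_autoreg")
        theta = {"alpha": 2.0, "n": 3.0}
        zero = cp.find_steady_states(m, theta)[0]
        assert zero.x == 0.0
        with pytest.raises(SensitivityError):
            sensitivity_analytic(m, theta, zero)


class TestGridSensitivities:
    def test_table_has_one_row_per_stable_branch(self):
        m = cp.make_circuit("toggle")
        grid = cp.ParameterGrid(
            axes={"beta_x": (40.0, 50.0, 3), "beta_y": (40.0, 50.0, 3),
                  "n": (2.0, 3.0, 2)},
            fixed={"gamma": 1.0})
        tab = grid_sensitivities(m, grid)
        # deep in the bistable regime every point has two stable branches
        assert len(tab) == 2 * grid.size
        assert set(tab["branch_id"]) == {0, 1}
        for col in ("S_x_beta_x", "S_y_n"):
            assert np.all(np.isfinite(tab[col]))
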