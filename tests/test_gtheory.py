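"""Henderson variance components, SEM/G projections and minimum-sample solvers."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cqival.gtheory import (
    NestedVarianceComponents,
    VarianceComponents,
    dstudy_grid,
    g_coefficient,
    min_departments,
    min_respondents,
    noise_bound,
    pool_components,
    sem_department,
    sem_hospital,
    vc_nested_2level,
    vc_nested_3level,
)
from cqival.reference import PUBLISHED_SHARES, VARIANCE_COMPONENTS


class TestTwoLevel:
    def test_hand_anova_toy(self):
        y = [1, 2, 3, 3, 4]
        d = ["A", "A", "A", "B", "B"]
        vc = vc_nested_2level(y, d)
        assert vc.sigma2_res == pytest.approx(5 / 6)
        assert vc.sigma2_d == pytest.approx(7 / 9)

    def test_all_equal_gives_zero(self):
        vc = vc_nested_2level([2.0] * 6, ["A", "A", "B", "B", "C", "C"])
        assert vc.sigma2_res == 0.0
        assert vc.sigma2_d == 0.0

    def test_label_permutation_invariance(self, rng):
        y = rng.normal(size=30)
        d = rng.integers(0, 5, size=30)
        relabel = {0: "v", 1: "w", 2: "x", 3: "y", 4: "z"}
        a = vc_nested_2level(y, d)
        b = vc_nested_2level(y, [relabel[i] for i in d])
        assert a.sigma2_res == pytest.approx(b.sigma2_res)
        assert a.sigma2_d == pytest.approx(b.sigma2_d)

    def test_negative_component_truncated(self, rng):
        # many singletons-plus-noise configurations push MS_b below MS_w
        y = np.tile([0.0, 10.0], 10)  # huge within, zero between
        d = np.repeat(np.arange(10), 2)
        vc = vc_nested_2level(y, d)
        assert vc.sigma2_d == 0.0
        assert "sigma2_d" in vc.truncated

    def test_singletons_rejected(self):
        with pytest.raises(ValueError, match="singleton"):
            vc_nested_2level([1.0, 2.0], ["A", "B"])

    def test_balanced_matches_classical_anova(self, rng):
        """On a balanced design, the unbalanced estimator is the textbook one."""
        k, n = 8, 6
        y = rng.normal(size=k * n) + np.repeat(rng.normal(scale=2, size=k), n)
        d = np.repeat(np.arange(k), n)
        vc = vc_nested_2level(y, d)
        ym = y.reshape(k, n)
        ms_w = ym.var(axis=1, ddof=1).mean()
        ms_b = n * ym.mean(axis=1).var(ddof=1)
        assert vc.sigma2_res == pytest.approx(ms_w)
        assert vc.sigma2_d == pytest.approx(max((ms_b - ms_w) / n, 0.0))


class TestThreeLevel:
    def _balanced_reference(self, y, a, b, n):
        """Textbook balanced nested ANOVA expected-mean-square solution."""
        ym = y.reshape(a, b, n)
        ms_res = ym.var(axis=2, ddof=1).mean()
        cell = ym.mean(axis=2)
        ms_d = n * cell.var(axis=1, ddof=1).mean()
        ms_h = b * n * cell.mean(axis=1).var(ddof=1)
        s_res = ms_res
        s_d = max((ms_d - ms_res) / n, 0.0)
        s_h = max((ms_h - ms_res - n * s_d) / (b * n), 0.0)
        return s_res, s_d, s_h

    def test_balanced_reduces_to_textbook(self, rng):
        a, b, n = 2, 2, 2
        y = (
            np.repeat(rng.normal(scale=1.5, size=a), b * n)
            + np.repeat(rng.normal(scale=1.0, size=a * b), n)
            + rng.normal(size=a * b * n)
        )
        hosp = np.repeat(np.arange(a), b * n)
        dept = np.repeat(np.arange(a * b), n)
        vc = vc_nested_3level(y, dept, hosp)
        ref = self._balanced_reference(y, a, b, n)
        # estimates solved before truncation may differ in truncation order;
        # compare the untruncated chain on a draw where all are positive
        assert vc.sigma2_res == pytest.approx(ref[0])
        if not vc.truncated:
            assert vc.sigma2_d == pytest.approx(ref[1])
            assert vc.sigma2_h == pytest.approx(ref[2])

    def test_balanced_larger_design_exact(self, rng):
        a, b, n = 6, 4, 10
        y = (
            np.repeat(rng.normal(scale=1.0, size=a), b * n)
            + np.repeat(rng.normal(scale=0.7, size=a * b), n)
            + rng.normal(size=a * b * n)
        )
        hosp = np.repeat(np.arange(a), b * n)
        dept = np.repeat(np.arange(a * b), n)
        vc = vc_nested_3level(y, dept, hosp)
        ref = self._balanced_reference(y, a, b, n)
        assert vc.sigma2_res == pytest.approx(ref[0])
        assert vc.sigma2_d == pytest.approx(ref[1])
        assert vc.sigma2_h == pytest.approx(ref[2])

    def test_null_hospital_effect_truncates_often(self):
        truncated, estimates = 0, []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            a, b, n = 6, 3, 8
            y = np.repeat(rng.normal(scale=0.3, size=a * b), n) + rng.normal(size=a * b * n)
            hosp = np.repeat(np.arange(a), b * n)
            dept = np.repeat(np.arange(a * b), n)
            vc = vc_nested_3level(y, dept, hosp)
            truncated += "sigma2_h" in vc.truncated
            estimates.append(vc.sigma2_h)
        assert truncated >= 16  # >= 40% of replications
        assert np.median(estimates) == pytest.approx(0.0, abs=0.02)

    def test_recovery_from_published_own_contribution(self):
        """500 departments in 25 hospitals recover the published components."""
        from cqival.synthetic import GeneratorConfig, generate

        ests = []
        for seed in range(8):
            cfg = GeneratorConfig(
                n_hospitals=25, departments_per_hospital=20,
                respondents_per_department=50, seed=1000 + seed,
            )
            _, truth = generate(cfg)
            lat = truth.latent_scores
            vc = vc_nested_3level(
                lat["own_contribution"].to_numpy(),
                lat["department_id"].to_numpy(),
                lat["hospital_id"].to_numpy(),
            )
            ests.append([vc.sigma2_res, vc.sigma2_d, vc.sigma2_h])
        mean = np.mean(ests, axis=0)
        truth_vals = (0.404, 0.014, 0.020)
        for got, want in zip(mean, truth_vals):
            assert got == pytest.approx(want, rel=0.20)

    def test_degenerate_strata_named(self):
        with pytest.raises(ValueError, match="hospitals"):
            vc_nested_3level([1.0, 2.0, 3.0], ["A", "A", "B"], ["H", "H", "H"])

    def test_estimator_class_wraps_solvers(self, rng):
        y = rng.normal(size=40)
        d = np.repeat(np.arange(8), 5)
        h = np.repeat(np.arange(4), 10)
        est = NestedVarianceComponents(design="p:d:h").fit(y, d, h)
        direct = vc_nested_3level(y, d, h)
        assert est.components_.sigma2_h == direct.sigma2_h
        assert est.get_params() == {"design": "p:d:h"}


class TestPooling:
    def test_identity_on_identical_inputs(self):
        vc = VarianceComponents(0.1, 0.01, 0.002, "p:d:h")
        pooled = pool_components([vc, vc, vc])
        assert pooled.sigma2_res == pytest.approx(0.1)
        assert pooled.sigma2_d == pytest.approx(0.01)
        assert pooled.sigma2_h == pytest.approx(0.002)

    def test_arithmetic_mean(self):
        a = VarianceComponents(0.058, 0.0, 0.0)
        b = VarianceComponents(0.060, 0.0, 0.0)
        assert pool_components([a, b]).sigma2_res == pytest.approx(0.059)

    def test_admission_share_rounds_to_five_percent(self):
        vc = VarianceComponents(0.059, 0.003, 0.000, "p:d:h")
        assert vc.shares()["department_pct"] == 5  # 0.003/0.062 = 4.84 -> 5

    def test_all_published_shares_reproduced(self):
        for name, (res, d, h) in VARIANCE_COMPONENTS.items():
            vc = VarianceComponents(res, d, h, "p:d:h")
            s = vc.shares()
            dept_pct, hosp_pct, ratio = PUBLISHED_SHARES[name]
            assert s["department_pct"] == dept_pct, name
            assert s["hospital_pct"] == hosp_pct, name
            assert s["hospital_ratio"] == pytest.approx(ratio, abs=0.005), name


class TestProjections:
    admission = VarianceComponents(0.059, 0.003, 0.000, "p:d:h")
    discharge = VarianceComponents(0.089, 0.005, 0.000, "p:d:h")
    doctors = VarianceComponents(0.490, 0.006, 0.004, "p:d:h")

    def test_sem_department_arithmetic(self):
        assert sem_department(self.admission, 100) == pytest.approx(np.sqrt(0.00059))
        assert sem_department(self.admission, 100) < 0.025

    def test_sem_scaling(self):
        s1 = sem_department(self.doctors, 50)
        assert sem_department(self.doctors, 200) == pytest.approx(s1 / 2)

    def test_sem_hospital_arithmetic(self):
        s = sem_hospital(self.admission, 10, 100)
        assert s == pytest.approx(np.sqrt(0.003 / 10 + 0.059 / 1000))

    def test_sem_hospital_collapses_without_department_variance(self):
        vc = VarianceComponents(0.2, 0.0, 0.0)
        assert sem_hospital(vc, 4, 25) == pytest.approx(sem_department(vc, 100))

    def test_sem_hospital_limit(self):
        s = sem_hospital(self.doctors, 10, 10**9)
        assert s == pytest.approx(np.sqrt(0.006 / 10), rel=1e-4)

    def test_g_coefficient_edges(self):
        assert g_coefficient(VarianceComponents(0.3, 0.0), 50) == 0.0
        assert g_coefficient(VarianceComponents(0.3, 0.3), 1) == pytest.approx(0.5)

    def test_g_coefficient_published_doctors_row(self):
        g = g_coefficient(self.doctors, 50)
        assert g == pytest.approx(0.006 / (0.006 + 0.49 / 50), rel=1e-9)
        assert g == pytest.approx(0.380, abs=0.005)

    def test_g_sem_consistency(self):
        for n_p in (25, 50, 100):
            g = g_coefficient(self.doctors, n_p)
            s = sem_department(self.doctors, n_p)
            assert g == pytest.approx(0.006 / (0.006 + s**2))

    def test_noise_bounds(self):
        assert round(noise_bound(0.10), 1) == 0.4
        assert round(noise_bound(0.025), 1) == 0.1


class TestMinimumSamples:
    def test_published_binary_minima(self):
        a = VarianceComponents(0.059, 0.003, 0.000)
        d = VarianceComponents(0.089, 0.005, 0.000)
        assert min_respondents(a, 0.025) == 100
        assert min_respondents(d, 0.025) == 150

    def test_four_point_nurses_minimum(self):
        vc = VarianceComponents(0.360, 0.005, 0.004)
        assert min_respondents(vc, 0.10) == 50

    def test_min_departments_discharge(self):
        d = VarianceComponents(0.089, 0.005, 0.000)
        assert min_departments(d, 100, 0.025) == 10
        assert sem_hospital(d, 9, 100) > 0.025  # boundary check

    def test_min_departments_infinite_threshold(self):
        assert min_departments(self_components(), 100, np.inf) == 1

    def test_min_departments_halving_dominant_term(self):
        big = VarianceComponents(0.001, 0.4, 0.0)
        half = VarianceComponents(0.001, 0.2, 0.0)
        n1 = min_departments(big, 1000, 0.05)
        n2 = min_departments(half, 1000, 0.05)
        assert n2 == pytest.approx(n1 / 2, abs=1)

    @given(step=st.sampled_from([10, 25, 50]), res=st.floats(0.01, 1.0))
    def test_min_respondents_is_minimal_on_grid(self, step, res):
        vc = VarianceComponents(res, 0.0, 0.0)
        n = min_respondents(vc, 0.05, grid_step=step)
        assert sem_department(vc, n) < 0.05
        if n > step:
            assert sem_department(vc, n - step) >= 0.05


def self_components():
    return VarianceComponents(0.089, 0.005, 0.000)


class TestDStudy:
    def test_surface_matches_scalar_ops(self):
        vc = VarianceComponents(0.36, 0.005, 0.004)
        res = dstudy_grid(vc, n_p_grid=(50, 100), n_d_grid=(4, 8), threshold=0.10)
        row = res.hospital_grid.query("n_d == 4 and n_p == 100").iloc[0]
        assert row["sem"] == pytest.approx(sem_hospital(vc, 4, 100))
        assert row["g"] == pytest.approx(g_coefficient(vc, 100, 4))
        dep = res.department_grid.set_index("n_p")
        assert dep.loc[50, "sem"] == pytest.approx(sem_department(vc, 50))

    def test_monotonicity(self):
        vc = VarianceComponents(0.4, 0.01, 0.005)
        res = dstudy_grid(vc, n_p_grid=(25, 50, 100, 200), n_d_grid=(2, 4, 8))
        assert res.department_grid["sem"].is_monotonic_decreasing
        assert res.department_grid["g"].is_monotonic_increasing
        per_np = res.hospital_grid.query("n_p == 50")["sem"]
        assert per_np.is_monotonic_decreasing

    def test_minimum_solutions_embedded(self):
        vc = VarianceComponents(0.089, 0.005, 0.000)
        res = dstudy_grid(vc, threshold=0.025)
        assert res.min_respondents_department == 150
        assert res.min_departments_hospital == min_departments(vc, 150, 0.025)
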