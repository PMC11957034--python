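"""Node-model statistics: basis construction, OLS equivalence, F-tests,
FDR, trajectories, derivative bands, maturation ages, CV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alongtract import gam
from alongtract.errors import ContractError, NumericalError, ParameterError, RankError
from alongtract.io import TractProfileSet

from conftest import make_cohort


class TestBasis:
    def test_k3_design_has_two_smooth_columns(self):
        cohort = make_cohort(50, seed=1)
        X_full, X_red, basis, names, _ = gam.build_design(cohort)
        assert basis.n_columns == 2
        assert X_full.shape[1] == 1 + 2 + 2  # intercept + smooth + sex + motion
        assert names == ("intercept", "s(age).0", "s(age).1", "sex", "motion")

    def test_evaluation_reproduces_training_design(self):
        cohort = make_cohort(80, seed=2)
        basis = gam.TPRSBasis(cohort["age"].to_numpy(), k=3)
        again = basis.design(cohort["age"].to_numpy())
        assert np.allclose(again, basis.design(cohort["age"].to_numpy()), atol=1e-12)
        # centered columns have zero training mean
        assert np.allclose(again.mean(axis=0), 0.0, atol=1e-10)

    def test_linear_signal_reproduced_exactly(self):
        cohort = make_cohort(60, seed=3)
        y = 2.0 + 3.0 * cohort["age"].to_numpy()
        full, _ = gam.fit_node(y, cohort, covariates=())
        pred = full.predict(cohort["age"].to_numpy())
        assert np.allclose(pred, y, atol=1e-9)

    def test_too_few_distinct_ages(self):
        cohort = make_cohort(10, seed=4)
        cohort["age"] = [8.0, 15.0] * 5
        with pytest.raises(RankError, match="distinct"):
            gam.fit_node(np.ones(10), cohort)


class TestFitNode:
    def test_age_free_signal_gives_perfect_both_models(self):
        cohort = make_cohort(40, seed=5)
        y = 5.0 * cohort["sex"].to_numpy()
        full, red = gam.fit_node(y, cohort)
        assert full.r2_adj == pytest.approx(1.0)
        assert red.r2_adj == pytest.approx(1.0)

    def test_matches_qr_least_squares_oracle(self):
        cohort = make_cohort(90, seed=6)
        rng = np.random.default_rng(6)
        y = rng.normal(size=90)
        full, red = gam.fit_node(y, cohort)
        X_full, X_red, _, _, _ = gam.build_design(cohort)
        for fit, X in ((full, X_full), (red, X_red)):
            beta_oracle, *_ = np.linalg.lstsq(X, y, rcond=None)
            assert np.allclose(fit.beta, beta_oracle, atol=1e-8)
            assert fit.rss == pytest.approx(float(np.sum((y - X @ beta_oracle) ** 2)))

    def test_null_delta_r2_small(self):
        cohort = make_cohort(200, seed=7)
        rng = np.random.default_rng(7)
        count = 0
        for _ in range(200):
            y = rng.normal(size=200)
            full, red = gam.fit_node(y, cohort)
            delta, _ = gam.age_effect(full, red)
            count += delta < 0.05
        assert count >= 190

    def test_rank_deficient_design_reported(self):
        cohort = make_cohort(30, seed=8)
        cohort["motion"] = cohort["sex"]  # perfectly collinear
        with pytest.raises(RankError, match="motion|sex"):
            gam.fit_node(np.ones(30), cohort)


class TestAgeEffect:
    def test_identical_fits_give_zero_effect(self):
        cohort = make_cohort(50, seed=9)
        y = np.ones(50) * 3.0
        full, red = gam.fit_node(y, cohort)
        delta, p = gam.age_effect(full, full)
        assert delta == 0.0 and p == 1.0

    def test_pure_age_signal_delta_near_one(self):
        cohort = make_cohort(300, seed=10)
        y = np.sin(cohort["age"].to_numpy() / 4.0)
        full, red = gam.fit_node(y, cohort, covariates=())
        delta, p = gam.age_effect(full, red)
        assert delta > 0.95
        assert p < 1e-10

    def test_partial_f_matches_textbook_computation(self):
        import scipy.stats

        cohort = make_cohort(120, seed=11)
        rng = np.random.default_rng(11)
        y = 0.01 * cohort["age"].to_numpy() + rng.normal(size=120)
        full, red = gam.fit_node(y, cohort)
        _, p = gam.age_effect(full, red)
        df1 = full.p - red.p
        df2 = full.n - full.p
        f_oracle = ((red.rss - full.rss) / df1) / (full.rss / df2)
        p_oracle = float(scipy.stats.f.sf(f_oracle, df1, df2))
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_non_nested_rejected(self):
        cohort = make_cohort(50, seed=12)
        full, red = gam.fit_node(np.ones(50), cohort)
        other_full, _ = gam.fit_node(np.ones(50), cohort, covariates=("sex",))
        with pytest.raises(ContractError):
            gam.age_effect(other_full, red)


class TestFDR:
    def test_hand_computed_bh(self):
        q = gam.fdr_correct(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_and_singleton(self):
        assert np.allclose(gam.fdr_correct(np.ones(5)), 1.0)
        assert gam.fdr_correct(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_matches_brute_force_step_up(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(size=25)
        m = len(p)
        order = np.argsort(p)
        q_oracle = np.empty(m)
        prev = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            prev = min(prev, p[i] * m / (rank_idx + 1))
            q_oracle[i] = prev
        assert np.allclose(gam.fdr_correct(p), q_oracle, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_q_at_least_p_and_bounded(self, pvals):
        p = np.array(pvals)
        q = gam.fdr_correct(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)


class TestTrajectory:
    def test_two_points_are_window_endpoints(self):
        cohort = make_cohort(40, seed=14)
        full, _ = gam.fit_node(np.ones(40), cohort)
        traj = gam.fitted_trajectory(full, n_points=2)
        assert traj["age"].tolist() == [full.age_min, full.age_max]

    def test_linear_signal_linear_trajectory(self):
        cohort = make_cohort(60, seed=15)
        y = 1.0 - 0.05 * cohort["age"].to_numpy()
        full, _ = gam.fit_node(y, cohort, covariates=())
        traj = gam.fitted_trajectory(full)
        slopes = np.diff(traj["fitted"]) / np.diff(traj["age"])
        assert np.allclose(slopes, -0.05, atol=1e-9)

    def test_training_grid_matches_in_sample_predictions(self):
        cohort = make_cohort(50, seed=16)
        rng = np.random.default_rng(16)
        y = rng.normal(size=50)
        full, _ = gam.fit_node(y, cohort)
        ages = cohort["age"].to_numpy()
        X_full, _, _, _, _ = gam.build_design(cohort)
        ref_pred = X_full[:, :3] @ full.beta[:3] + (
            full.covariate_ref["sex"] * full.beta[3]
            + full.covariate_ref["motion"] * full.beta[4]
        )
        assert np.allclose(full.predict(ages), ref_pred, atol=1e-10)


class TestDerivativeBand:
    def test_linear_fit_has_constant_derivative(self):
        cohort = make_cohort(80, seed=17)
        y = 2.0 - 0.03 * cohort["age"].to_numpy()
        full, _ = gam.fit_node(y, cohort, covariates=())
        band = gam.derivative_band(full, n_draws=500, seed=1)
        assert np.allclose(band.estimate, -0.03, atol=1e-6)

    def test_simultaneous_band_at_least_pointwise(self):
        import scipy.stats

        cohort = make_cohort(150, seed=18)
        rng = np.random.default_rng(18)
        y = np.exp(-(cohort["age"].to_numpy() - 8) / 4) + 0.05 * rng.normal(size=150)
        full, _ = gam.fit_node(y, cohort)
        band = gam.derivative_band(full, n_draws=5000, seed=2)
        assert band.crit >= scipy.stats.norm.ppf(0.975) - 0.05

    def test_band_contains_estimate(self):
        cohort = make_cohort(100, seed=19)
        rng = np.random.default_rng(19)
        y = rng.normal(size=100)
        full, _ = gam.fit_node(y, cohort)
        band = gam.derivative_band(full, n_draws=1000, seed=3)
        assert np.all(band.lower <= band.estimate)
        assert np.all(band.estimate <= band.upper)


class TestMaturationAge:
    @staticmethod
    def flat_band(ages, lo, hi):
        return gam.DerivativeBand(ages, np.zeros_like(ages), lo, hi, 2.0, 0.95)

    def test_band_always_contains_zero_matures_at_window_start(self):
        ages = np.linspace(8, 23, 50)
        band = self.flat_band(ages, -np.ones(50), np.ones(50))
        age, matured = gam.age_of_maturation(band, 23.0)
        assert age == 8.0 and matured

    def test_band_never_contains_zero_hits_ceiling(self):
        ages = np.linspace(8, 23, 50)
        band = self.flat_band(ages, np.ones(50), 2 * np.ones(50))
        age, matured = gam.age_of_maturation(band, 23.0)
        assert age == 23.0 and not matured

    def test_decreasing_grid_rejected(self):
        ages = np.linspace(23, 8, 10)
        band = self.flat_band(ages, -np.ones(10), np.ones(10))
        with pytest.raises(ParameterError):
            gam.age_of_maturation(band, 23.0)


class TestCV:
    @staticmethod
    def profiles(values):
        values = np.asarray(values, dtype=float)
        return TractProfileSet(
            "t0",
            [f"s{i}" for i in range(values.shape[0])],
            np.arange(values.shape[1]),
            values,
            metric_name="metric",
        )

    def test_constant_values_zero_cv_and_scale_invariance(self):
        ps = self.profiles(np.ones((5, 4)))
        cv, _ = gam.coefficient_of_variation(ps)
        assert np.allclose(cv, 0.0)
        rng = np.random.default_rng(20)
        vals = 1 + rng.random((6, 8))
        cv1, _ = gam.coefficient_of_variation(self.profiles(vals))
        cv2, _ = gam.coefficient_of_variation(self.profiles(2 * vals))
        assert np.allclose(cv1, cv2, atol=1e-14)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(21)
        vals = 0.5 + rng.random((10, 6))
        cv, bins = gam.coefficient_of_variation(
            self.profiles(vals), deep_nodes=[2, 3], superficial_nodes=[0, 5]
        )
        for j in range(6):
            col = vals[:, j]
            mean = sum(col) / len(col)
            sd = (sum((x - mean) ** 2 for x in col) / (len(col) - 1)) ** 0.5
            assert cv.iloc[j] == pytest.approx(sd / mean, abs=1e-12)
        assert bins["deep"] == pytest.approx((cv.iloc[2] + cv.iloc[3]) / 2)

    def test_zero_mean_rejected(self):
        vals = np.array([[1.0, -1.0], [-1.0, 1.0]])
        with pytest.raises(NumericalError):
            gam.coefficient_of_variation(self.profiles(vals))


class TestInvariances:
    def test_delta_r2_invariant_to_affine_response_rescaling(self):
        cohort = make_cohort(150, seed=22)
        rng = np.random.default_rng(22)
        y = np.exp(-(cohort["age"].to_numpy() - 8) / 4) + 0.1 * rng.normal(size=150)
        d1, _ = gam.age_effect(*gam.fit_node(y, cohort))
        d2, _ = gam.age_effect(*gam.fit_node(3.5 * y - 11.0, cohort))
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_monotone_power_in_amplitude(self):
        cohort = make_cohort(120, seed=23)
        ages = cohort["age"].to_numpy()
        rng = np.random.default_rng(23)
        noise = rng.normal(size=(100, 120))
        medians = []
        for amp in (0.0, 0.05, 0.1, 0.2):
            deltas = []
            for rep in range(100):
                y = amp * np.exp(-(ages - 8) / 3) + 0.05 * noise[rep]
                delta, _ = gam.age_effect(*gam.fit_node(y, cohort))
                deltas.append(delta)
            medians.append(np.median(deltas))
        assert all(b >= a for a, b in zip(medians, medians[1:]))

    def test_node_independence(self, small_dataset):
        cohort, _, _, profiles, _ = small_dataset
        ps = next(iter(profiles.values()))
        res1 = gam.fit_tract(ps, cohort, n_draws=200, seed=4)
        corrupted = ps.values.copy()
        corrupted[:, 50] = 999.0
        ps2 = TractProfileSet(
            ps.tract_id, ps.subjects, ps.node_ids, corrupted, ps.metric_name
        )
        res2 = gam.fit_tract(ps2, cohort, n_draws=200, seed=4)
        keep = ps.node_ids != 50
        cols = ["delta_r2_adj", "p_age", "maturation_age", "cv"]
        a = res1.table.loc[keep.nonzero()[0], cols].reset_index(drop=True)
        b = res2.table.loc[keep.nonzero()[0], cols].reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestAgainstMgcv:
    """Frozen cross-check against R mgcv (gam with s(age, k=3, fx=TRUE) +
    sex + motion) on a deterministic dataset; values computed once with
    mgcv 1.9-3."""

    def test_r2_adj_and_anova_p_match_mgcv(self):
        # deterministic dataset with <= 200 unique ages
        rng = np.random.default_rng(42)
        n = 300
        ages = rng.uniform(8, 23, n)
        sex = rng.integers(0, 2, n)
        motion = rng.uniform(0.05, 0.4, n)
        y = (
            0.8
            + 0.1 * np.exp(-(ages - 8) / 1.5)
            + 0.01 * sex
            + 0.02 * motion
            + 0.01 * rng.normal(size=n)
        )
        cohort = pd.DataFrame(
            {
                "participant_id": [f"s{i}" for i in range(n)],
                "age": ages,
                "sex": sex,
                "motion": motion,
            }
        )
        full, red = gam.fit_node(y, cohort)
        delta, p = gam.age_effect(full, red)
        # mgcv: r.sq full 0.6552046, reduced 0.06461399, anova F p 4.3285e-65
        assert full.r2_adj == pytest.approx(0.6552046, abs=2e-4)
        assert red.r2_adj == pytest.approx(0.06461399, abs=1e-6)
        assert np.log10(p) == pytest.approx(np.log10(4.3285e-65), abs=0.05)
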