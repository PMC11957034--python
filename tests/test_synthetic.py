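"""Generator contracts: cohort draws, geometry, profiles, analytic truth."""

import numpy as np
import pandas as pd
import pytest

from alongtract.errors import ConfigError, ValidationError
from alongtract.synthetic import (
    SimulationConfig,
    Site,
    endpoint_mean_ranks,
    generate_cohort,
    generate_dataset,
    generate_geometry,
    simulate_profiles,
)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs, fragment",
        [
            ({"age_min": 23, "age_max": 8}, "age_min"),
            ({"n_nodes": 10}, "n_nodes"),
            ({"amplitude_deep": 0.2, "amplitude_superficial": 0.1}, "amplitude"),
            ({"tau_fast": 3.0, "tau_slow": 1.0}, "tau"),
            ({"noise_sd": 0.0}, "noise_sd"),
            ({"parcels_per_hemisphere": 4}, "parcels_per_hemisphere"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, fragment):
        with pytest.raises(ConfigError, match=fragment):
            SimulationConfig(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_subjects=50, sites=(Site("a"), Site("b", 0.1, 1.2)))
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = SimulationConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back == cfg


class TestCohort:
    def test_ages_within_window(self):
        cohort = generate_cohort(SimulationConfig(n_subjects=10, seed=1))
        assert len(cohort) == 10
        assert cohort["age"].between(8, 23).all()

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_subjects=40, seed=5)
        pd.testing.assert_frame_equal(generate_cohort(cfg), generate_cohort(cfg))

    def test_uniform_age_mean(self):
        cohort = generate_cohort(SimulationConfig(n_subjects=5000, seed=2))
        assert abs(cohort["age"].mean() - 15.5) < 0.2

    def test_covariate_ranges(self):
        cfg = SimulationConfig(
            n_subjects=500, sites=(Site("a"), Site("b")), seed=3
        )
        cohort = generate_cohort(cfg)
        assert set(cohort["sex"]) == {0, 1}
        assert ((cohort["motion"] > 0) & (cohort["motion"] <= 1)).all()
        # round-robin site assignment balances sites
        counts = cohort["site"].value_counts()
        assert counts["a"] == counts["b"] == 250


class TestGeometry:
    def test_ranks_are_permutation_and_centroids_unit(self):
        atlas, _ = generate_geometry(SimulationConfig(parcels_per_hemisphere=50, seed=4))
        assert sorted(atlas["sa_rank"]) == list(range(1, 101))
        norms = np.linalg.norm(atlas[["x", "y", "z"]].to_numpy(), axis=1)
        assert np.all(np.abs(norms - 1) < 1e-9)

    def test_heterotopic_spans_more_rank_than_homotopic(self):
        for seed in range(20):
            cfg = SimulationConfig(seed=seed)
            atlas, table = generate_geometry(cfg)
            ranks = endpoint_mean_ranks(atlas, table)
            gaps = {
                tract: abs(ranks[(tract, "end_A")] - ranks[(tract, "end_B")])
                for tract in table["tract_id"].unique()
            }
            homo = [g for t, g in gaps.items() if t.endswith("homotopic")]
            hetero = [g for t, g in gaps.items() if t.endswith("heterotopic")]
            assert max(homo) < min(hetero)
            # heterotopic-like ends span more than half the rank range
            assert min(hetero) > (len(atlas) - 1) / 2

    def test_endpoint_table_shape(self, small_dataset):
        _, atlas, table, _, _ = small_dataset
        assert set(table["end_label"]) == {"end_A", "end_B"}
        assert table["probability"].between(0, 1, inclusive="right").all()
        sizes = table.groupby(["tract_id", "end_label"]).size()
        assert sizes.between(2, 4).all()


class TestProfiles:
    def test_null_construction_is_age_free(self):
        cfg = SimulationConfig(
            n_subjects=200,
            n_tracts=2,
            amplitude_deep=0.0,
            amplitude_superficial=0.0,
            noise_sd=1e-12,
            seed=6,
        )
        cohort = generate_cohort(cfg)
        geometry = generate_geometry(cfg)
        profiles, _ = simulate_profiles(cohort, geometry, cfg)
        ps = next(iter(profiles.values()))
        # variance across subjects fully explained by sex and motion
        pred = (
            cfg.sex_effect * cohort["sex"].to_numpy()
            + cfg.motion_effect * cohort["motion"].to_numpy()
        )
        resid = ps.values - pred[:, None]
        assert np.allclose(resid.std(axis=0), 0.0, atol=1e-9)

    def test_amplitude_ratio_is_four_to_one_at_ends(self):
        cfg = SimulationConfig(
            n_subjects=2,
            n_tracts=2,
            amplitude_deep=0.025,
            amplitude_superficial=0.1,
            tau_fast=2.0,
            tau_slow=2.0,  # equal timescales isolate the amplitude gradient
            noise_sd=1e-15,
            sex_effect=0.0,
            motion_effect=0.0,
            seed=8,
        )
        cohort = generate_cohort(cfg).copy()
        cohort.loc[0, "age"] = cfg.age_min
        cohort.loc[1, "age"] = cfg.age_max
        profiles, truth = simulate_profiles(cohort, generate_geometry(cfg), cfg)
        ps = next(iter(profiles.values()))
        span = np.abs(ps.values[0] - ps.values[1])  # |m(age_min) - m(age_max)|
        end_mean = (span[0] + span[-1]) / 2
        mid = span[cfg.n_nodes // 2]
        assert end_mean / mid == pytest.approx(4.0, rel=0.05)
        # and the whole profile matches the generative equation
        tid = ps.tract_id
        expected = truth.amplitude[tid] * (1 - np.exp(-cfg.age_range / truth.tau[tid]))
        assert np.allclose(span, expected, rtol=1e-6)

    def test_shared_endpoint_gives_identical_superficial_timescales(self):
        cfg = SimulationConfig(n_subjects=5, n_tracts=4, seed=9)
        cohort, atlas, table, profiles, truth = generate_dataset(cfg)
        # force two tracts to share end_A parcels, re-simulate
        t0, t1 = sorted(profiles)[:2]
        shared = table[(table["tract_id"] == t0) & (table["end_label"] == "end_A")].copy()
        table2 = table[~((table["tract_id"] == t1) & (table["end_label"] == "end_A"))]
        shared["tract_id"] = t1
        table2 = pd.concat([table2, shared], ignore_index=True)
        _, truth2 = simulate_profiles(cohort, (atlas, table2), cfg)
        half = cfg.n_nodes // 2
        assert np.allclose(truth2.tau[t0][:half], truth2.tau[t1][:half])

    def test_noiseless_metric_nonincreasing_in_age(self):
        cfg = SimulationConfig(
            n_subjects=50, n_tracts=3, noise_sd=1e-15, sex_effect=0.0,
            motion_effect=0.0, seed=10,
        )
        cohort = generate_cohort(cfg).sort_values("age").reset_index(drop=True)
        profiles, _ = simulate_profiles(cohort, generate_geometry(cfg), cfg)
        for ps in profiles.values():
            assert np.all(np.diff(ps.values, axis=0) <= 1e-12)

    def test_true_maturation_increases_with_endpoint_rank(self, small_dataset):
        _, atlas, table, profiles, truth = small_dataset
        ranks = endpoint_mean_ranks(atlas, table)
        pairs = []
        for tid in profiles:
            for end, node in (("end_A", 5), ("end_B", 94)):
                pairs.append((ranks[(tid, end)], truth.maturation_age[tid][node]))
        pairs.sort()
        ages = [age for _, age in pairs]
        unclamped = [a for a in ages if a < 23.0]
        assert all(b >= a for a, b in zip(unclamped, unclamped[1:]))

    def test_empty_cohort_rejected(self, small_config):
        geometry = generate_geometry(small_config)
        with pytest.raises(ValidationError, match="empty"):
            simulate_profiles(
                generate_cohort(small_config).iloc[:0], geometry, small_config
            )

    def test_determinism_of_full_dataset(self, small_config, small_dataset):
        cohort2, _, _, profiles2, _ = generate_dataset(small_config)
        cohort, _, _, profiles, _ = small_dataset
        pd.testing.assert_frame_equal(cohort, cohort2)
        for tid in profiles:
            assert np.array_equal(profiles[tid].values, profiles2[tid].values)
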