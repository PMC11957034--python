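"""Enrichment score and permutation machinery, checked against hand
computations and a full-enumeration oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from alongtract import enrichment as enr
from alongtract.errors import ContractError, ParameterError
from alongtract.gam import SmoothSpec, TPRSBasis
from alongtract.io import TractProfileSet
from alongtract.synthetic import SimulationConfig, generate_cohort

from conftest import make_cohort


def profiles_from(values, tract="t0", node_ids=None, subjects=None):
    values = np.asarray(values, dtype=float)
    return TractProfileSet(
        tract,
        subjects or [f"sub-{i:04d}" for i in range(values.shape[0])],
        np.arange(values.shape[1]) if node_ids is None else node_ids,
        values,
        metric_name="metric",
    )


class TestScore:
    def test_hand_evaluated_running_sum(self):
        stats = {"n1": 4.0, "n2": 3.0, "n3": 2.0, "n4": 1.0}
        contrast = enr.RegionContrast(
            frozenset({"n1", "n2"}), frozenset(stats), "toy"
        )
        # running sum: 4/7, 1, 1/2, 0 -> es = 1.0
        assert enr.enrichment_score(stats, contrast) == pytest.approx(1.0)

    def test_set_equal_background_rejected(self):
        with pytest.raises(ContractError, match="proper subset"):
            enr.RegionContrast(frozenset({1, 2}), frozenset({1, 2}), "bad")

    def test_tied_stats_give_same_score_under_label_swap(self):
        stats = {0: 2.0, 1: 2.0, 2: 1.0, 3: 0.5}
        c1 = enr.RegionContrast(frozenset({0, 2}), frozenset(stats), "a")
        c2 = enr.RegionContrast(frozenset({1, 2}), frozenset(stats), "b")
        assert enr.enrichment_score(stats, c1) == enr.enrichment_score(stats, c2)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        stats = {i: float(v) for i, v in enumerate(rng.random(12))}
        contrast = enr.RegionContrast(frozenset({0, 3, 7}), frozenset(stats), "s")
        es1 = enr.enrichment_score(stats, contrast)
        es2 = enr.enrichment_score({k: 7.3 * v for k, v in stats.items()}, contrast)
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_all_zero_set_stats_warn_and_zero(self):
        stats = {0: 0.0, 1: 0.0, 2: 1.0}
        contrast = enr.RegionContrast(frozenset({0, 1}), frozenset(stats), "z")
        with pytest.warns(UserWarning):
            assert enr.enrichment_score(stats, contrast) == 0.0


class TestDefaultBins:
    def test_default_regions_match_node_numbering(self):
        c = enr.deep_superficial_contrast()
        deep = sorted(c.background_nodes - c.set_nodes)
        assert deep == list(range(46, 56))
        assert sorted(c.set_nodes) == list(range(5, 10)) + list(range(90, 95))

    @pytest.mark.parametrize(
        "size, deep_lo, deep_hi", [(3, 48, 53), (5, 46, 55), (7, 44, 57), (10, 41, 60)]
    )
    def test_bin_recentering(self, size, deep_lo, deep_hi):
        c = enr.deep_superficial_contrast(size)
        deep = sorted(c.background_nodes - c.set_nodes)
        assert deep[0] == deep_lo and deep[-1] == deep_hi
        sup = sorted(c.set_nodes)
        assert sup[0] == 5 and sup[-1] == 94
        assert len(sup) == 2 * size

    def test_overflowing_bin_rejected(self):
        with pytest.raises(ParameterError, match="overflow"):
            enr.deep_superficial_contrast(50)


def _oracle_nest(values, cohort, set_nodes, background, n=5):
    """Independent brute-force oracle: delta adjusted R^2 per node via
    lstsq, unweighted ranking arithmetic, full enumeration of the n!
    age permutations."""
    ages = cohort["age"].to_numpy(float)
    ones = np.ones((len(cohort), 1))
    basis = TPRSBasis(ages, k=3)

    def r2adj(X, y):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        return 1 - (1 - r2) * (len(y) - 1) / (len(y) - X.shape[1])

    def es(perm):
        B = basis.design(ages[perm])
        X = np.column_stack([ones, B])
        Xr = ones
        stats = {}
        for j, node in enumerate(background):
            y = values[:, j]
            stats[node] = abs(r2adj(X, y) - r2adj(Xr, y))
        keys = sorted(background, key=lambda k: (-stats[k], k))
        member = np.array([k in set_nodes for k in keys])
        vals = np.array([stats[k] for k in keys])
        steps = np.where(
            member, vals / vals[member].sum(), -1.0 / (len(keys) - member.sum())
        )
        run = np.cumsum(steps)
        return run[np.argmax(np.abs(run))]

    obs = es(np.arange(n))
    null = [es(np.array(p)) for p in itertools.permutations(range(n))]
    p = (1 + sum(e >= obs - 1e-12 for e in null)) / (1 + len(null))
    return obs, p


class TestNest:
    def test_exhaustive_p_matches_enumeration_oracle(self):
        cohort = make_cohort(5, seed=2)
        rng = np.random.default_rng(2)
        background = list(range(6))
        values = 0.8 + 0.1 * rng.random((5, 6))
        ps = profiles_from(values)
        contrast = enr.RegionContrast(
            frozenset({0, 1, 2}), frozenset(background), "toy", bin_size=3
        )
        res = enr.nest_test(
            ps, cohort, contrast, permutations="exhaustive", n_perm=0, covariates=()
        )
        obs, p = _oracle_nest(values, cohort, {0, 1, 2}, background)
        assert res.es_observed == pytest.approx(obs, abs=1e-10)
        assert res.p_perm == pytest.approx(p, abs=1e-12)
        assert res.n_perm == 120

    def test_deterministic_under_seed(self, small_dataset):
        cohort, _, _, profiles, _ = small_dataset
        from alongtract.io import trim_end_nodes

        ps = trim_end_nodes(next(iter(profiles.values())))
        contrast = enr.deep_superficial_contrast()
        r1 = enr.nest_test(ps, cohort, contrast, n_perm=50, seed=11)
        r2 = enr.nest_test(ps, cohort, contrast, n_perm=50, seed=11)
        assert r1.es_observed == r2.es_observed
        assert r1.p_perm == r2.p_perm

    def test_p_floor(self, small_dataset):
        cohort, _, _, profiles, _ = small_dataset
        from alongtract.io import trim_end_nodes

        ps = trim_end_nodes(next(iter(profiles.values())))
        contrast = enr.deep_superficial_contrast()
        res = enr.nest_test(ps, cohort, contrast, n_perm=49, seed=1)
        assert res.p_perm >= 1.0 / 50

    def test_monotone_gradient_positive_es_at_every_bin_size(self):
        # strict deep-to-superficial amplitude gradient at low noise; with
        # exactly zero noise every node has identical delta-R2 (the
        # statistic is scale invariant), so the gradient must show
        # through signal-to-noise, not raw amplitude
        cfg = SimulationConfig(n_subjects=250, n_tracts=2, seed=3)
        cohort = generate_cohort(cfg)
        ages = cohort["age"].to_numpy()
        nodes = np.arange(100)
        amp = 0.02 + 0.08 * ((nodes - 49.5) / 49.5) ** 2
        rng = np.random.default_rng(3)
        values = (
            0.8
            + amp[None, :] * np.exp(-(ages[:, None] - 8) / 3)
            + 0.02 * rng.normal(size=(len(cohort), 100))
        )
        ps = profiles_from(
            values, node_ids=nodes, subjects=list(cohort["participant_id"])
        )
        from alongtract.io import trim_end_nodes

        ps = trim_end_nodes(ps)
        table = enr.bin_sensitivity(ps, cohort, bin_sizes=(3, 5, 7, 10), n_perm=9, seed=4)
        assert (table["es"] > 0).all()

    def test_bin_size_5_row_reproduces_default(self, small_dataset):
        cohort, _, _, profiles, _ = small_dataset
        from alongtract.io import trim_end_nodes

        ps = trim_end_nodes(next(iter(profiles.values())))
        table = enr.bin_sensitivity(ps, cohort, bin_sizes=(5,), n_perm=30, seed=9)
        res = enr.nest_test(
            ps, cohort, enr.deep_superficial_contrast(), n_perm=30, seed=9
        )
        assert table.loc[0, "es"] == res.es_observed
        assert table.loc[0, "p_perm"] == res.p_perm


class TestEndpointContrast:
    def test_swapping_ends_flips_score_sign(self, small_dataset):
        cohort, _, _, profiles, _ = small_dataset
        from alongtract.io import trim_end_nodes

        ps = trim_end_nodes(next(iter(profiles.values())))
        res = enr.endpoint_contrast(ps, cohort, n_perm=19, seed=5)
        flipped = TractProfileSet(
            ps.tract_id,
            ps.subjects,
            ps.node_ids,
            ps.values[:, ::-1],
            ps.metric_name,
            trimmed=True,
            n_nodes_original=ps.n_nodes_original,
        )
        res_flip = enr.endpoint_contrast(flipped, cohort, n_perm=19, seed=5)
        assert res_flip.es_observed == pytest.approx(-res.es_observed, abs=1e-12)

    def test_overlapping_end_sets_rejected(self):
        cohort = make_cohort(30, seed=6)
        ps = profiles_from(0.8 + np.zeros((30, 8)))
        with pytest.raises(ContractError, match="overlap"):
            enr.endpoint_contrast(ps, cohort, n_superficial=5, n_perm=9)

    def test_bilateral_pooling_uses_both_hemispheres(self, small_dataset):
        cohort, _, _, profiles, _ = small_dataset
        from alongtract.io import trim_end_nodes

        tracts = [trim_end_nodes(p) for p in list(profiles.values())[:2]]
        res = enr.endpoint_contrast(tracts, cohort, n_perm=19, seed=7)
        assert res.tail == "two-sided"
        assert -1.0 <= res.es_observed <= 1.0


class TestFdrAcrossTracts:
    def test_bh_applied_to_tract_pvalues(self):
        results = {
            t: enr.EnrichmentResult(1.0, p, 100, "greater", "x")
            for t, p in zip("abcd", [0.01, 0.02, 0.03, 0.04])
        }
        enr.fdr_across_tracts(results)
        assert all(results[t].q == pytest.approx(0.04) for t in "abcd")
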