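"""Simulation experiments validating the analysis pipeline end to end.

Each function runs a self-contained study on synthetic cohorts with
known ground truth — recovery of the deep-to-superficial age-effect
gradient, calibration and power of the enrichment permutation test,
maturation-age recovery, simultaneous-band coverage, hierarchy-alignment
recovery with spin nulls, ΔAge/ΔS-A contrasts and the end-vs-end
dichotomy — and returns a dict of summary metrics. All randomness is
derived from the single ``seed`` argument via named substreams.

Problem sizes are chosen so the full battery runs in minutes on one CPU;
the methods note documents the sizes and what each experiment does and
does not establish.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from . import endpoints as ep
from . import enrichment as enr
from . import gam, spin
from ._rng import substream
from .io import trim_end_nodes
from .synthetic import SimulationConfig, generate_dataset

SUPERFICIAL_NODES = list(range(5, 10)) + list(range(90, 95))


def _fit_superficial(profiles, cohort, truth, n_draws=2000, seed=0):
    """Per-tract fits; returns (node_results, est ages, true ages, flags)."""
    tables = []
    est, true, est_flag, true_flag = [], [], [], []
    for tid, ps in profiles.items():
        pst = trim_end_nodes(ps)
        res = gam.fit_tract(pst, cohort, n_draws=n_draws, seed=seed)
        tables.append(res.table)
        tab = res.table.set_index("node").loc[SUPERFICIAL_NODES]
        est.append(tab["maturation_age"].to_numpy())
        est_flag.append(tab["matured"].to_numpy())
        true.append(truth.maturation_age[tid][SUPERFICIAL_NODES])
        true_flag.append(truth.matured[tid][SUPERFICIAL_NODES])
    return (
        pd.concat(tables, ignore_index=True),
        np.concatenate(est),
        np.concatenate(true),
        np.concatenate(est_flag),
        np.concatenate(true_flag),
    )


def deep_superficial_recovery(
    seed: int = 0, n_subjects: int = 250, n_tracts: int = 3
) -> dict:
    """Recovery of the 4:1 deep-to-superficial amplitude gradient.

    The node-wise age-effect profile (delta adjusted R^2) should
    correlate with the true amplitude profile within every tract, and the
    superficial-bin mean should exceed the deep-bin mean.
    """
    cfg = SimulationConfig(n_subjects=n_subjects, n_tracts=n_tracts, seed=seed)
    cohort, _, _, profiles, truth = generate_dataset(cfg)
    contrast = enr.deep_superficial_contrast()
    deep = sorted(contrast.background_nodes - contrast.set_nodes)
    sup = sorted(contrast.set_nodes)
    corrs, sup_means, deep_means = [], [], []
    for tid, ps in profiles.items():
        pst = trim_end_nodes(ps)
        res = gam.fit_tract(pst, cohort, compute_bands=False)
        table = res.table.set_index("node")
        r = scipy.stats.pearsonr(
            table["delta_r2_adj"].to_numpy(),
            truth.amplitude[tid][pst.node_ids],
        ).statistic
        corrs.append(float(r))
        sup_means.append(float(table.loc[sup, "delta_r2_adj"].mean()))
        deep_means.append(float(table.loc[deep, "delta_r2_adj"].mean()))
    return {
        "n_subjects": n_subjects,
        "n_tracts": n_tracts,
        "profile_correlations": corrs,
        "min_profile_correlation": min(corrs),
        "superficial_means": sup_means,
        "deep_means": deep_means,
        "all_superficial_exceed_deep": all(
            s > d for s, d in zip(sup_means, deep_means)
        ),
    }


def _one_tract_config(seed, flat, n_subjects):
    # the calibration null is the exchangeable one: a flat (zero) amplitude
    # profile with constant timescale, so age carries no information at any
    # node and permuting it is exact
    if flat:
        return SimulationConfig(
            n_subjects=n_subjects,
            n_tracts=2,
            amplitude_deep=0.0,
            amplitude_superficial=0.0,
            tau_fast=3.0,
            tau_slow=3.0,
            seed=seed,
        )
    return SimulationConfig(n_subjects=n_subjects, n_tracts=2, seed=seed)


def enrichment_calibration(
    seed: int = 0,
    n_reps: int = 300,
    n_perm: int = 199,
    n_subjects: int = 250,
    alpha: float = 0.05,
    flat: bool = True,
) -> dict:
    """Type-I error (flat-amplitude null) or power (4:1 gradient) of the
    deep-vs-superficial enrichment permutation test."""
    rng = substream(seed, "enrichment_reps")
    contrast = enr.deep_superficial_contrast()
    rejections = 0
    for _ in range(n_reps):
        rep_seed = int(rng.integers(2**31 - 1))
        cfg = _one_tract_config(rep_seed, flat, n_subjects)
        cohort, _, _, profiles, _ = generate_dataset(cfg)
        ps = trim_end_nodes(next(iter(profiles.values())))
        res = enr.nest_test(ps, cohort, contrast, n_perm=n_perm, seed=rep_seed)
        rejections += res.p_perm < alpha
    return {
        "n_reps": n_reps,
        "n_perm": n_perm,
        "n_subjects": n_subjects,
        "rejection_rate": rejections / n_reps,
    }


def maturation_recovery_config(seed: int = 0) -> SimulationConfig:
    """Low-noise cohort whose true superficial plateau ages span ~12-22 y."""
    return SimulationConfig(
        n_subjects=400,
        n_tracts=6,
        noise_sd=0.015,
        tau_fast=0.8,
        tau_slow=6.0,
        seed=seed,
    )


def maturation_recovery(seed: int = 0, n_draws: int = 4000) -> dict:
    """Recovery of analytic maturation ages at superficial nodes."""
    cfg = maturation_recovery_config(seed)
    cohort, _, _, profiles, truth = generate_dataset(cfg)
    _, est, true, est_flag, true_flag = _fit_superficial(
        profiles, cohort, truth, n_draws=n_draws, seed=seed
    )
    ceiling = ~true_flag
    return {
        "n_subjects": cfg.n_subjects,
        "n_nodes": est.size,
        "true_age_min": float(true.min()),
        "true_age_max": float(true.max()),
        "mae_years": float(np.abs(est - true).mean()),
        "spearman": float(scipy.stats.spearmanr(est, true).statistic),
        "n_true_ceiling": int(ceiling.sum()),
        "ceiling_flags_correct": bool((est_flag[ceiling] == true_flag[ceiling]).all()),
    }


def band_coverage(
    seed: int = 0,
    n_reps: int = 500,
    n_subjects: int = 200,
    slope: float = -0.004,
    noise_sd: float = 0.02,
    n_draws: int = 3000,
    level: float = 0.95,
) -> dict:
    """Simultaneous coverage of the derivative band for an in-span truth.

    The generating trajectory is linear in age (inside the smooth basis
    span, so the band targets the true derivative without smoothing
    bias); coverage counts replicates whose band contains the true
    constant derivative at every grid age.
    """
    rng = substream(seed, "coverage")
    covered = 0
    for rep in range(n_reps):
        ages = rng.uniform(8, 23, n_subjects)
        sex = rng.integers(0, 2, n_subjects)
        motion = rng.uniform(0.05, 0.5, n_subjects)
        y = (
            0.85
            + slope * ages
            + 0.01 * sex
            + 0.02 * motion
            + noise_sd * rng.normal(size=n_subjects)
        )
        cohort = pd.DataFrame(
            {
                "participant_id": [f"s{i}" for i in range(n_subjects)],
                "age": ages,
                "sex": sex,
                "motion": motion,
            }
        )
        full, _ = gam.fit_node(y, cohort)
        band = gam.derivative_band(
            full, n_draws=n_draws, level=level, seed=int(rng.integers(2**31 - 1))
        )
        covered += bool(np.all((band.lower <= slope) & (slope <= band.upper)))
    return {"n_reps": n_reps, "n_subjects": n_subjects, "coverage": covered / n_reps}


def _alignment_one(cfg, seed, n_spins, n_draws):
    cohort, atlas, endpoint_table, profiles, truth = generate_dataset(cfg)
    node_results, est, true, _, _ = _fit_superficial(
        profiles, cohort, truth, n_draws=n_draws, seed=seed
    )
    endpoint_sets = {
        (t, e): frozenset(sub["parcel_id"])
        for (t, e), sub in endpoint_table.groupby(["tract_id", "end_label"])
    }
    summaries = ep.summarize_endpoints(node_results, endpoint_sets, atlas)
    spins = spin.build_spins(atlas, n_spins=n_spins, seed=seed)
    r_obs, used = ep.sa_alignment(summaries, include_unmatured=True)
    res = spin.spin_correlation_endpoints(
        used["mean_maturation_age"].to_numpy(float),
        list(used["parcel_ids"]),
        atlas,
        spins,
    )
    # design-truth alignment for reference
    true_ages = {}
    for tid in profiles:
        true_ages[(tid, "end_A")] = truth.maturation_age[tid][SUPERFICIAL_NODES[:5]].mean()
        true_ages[(tid, "end_B")] = truth.maturation_age[tid][SUPERFICIAL_NODES[5:]].mean()
    r_true = scipy.stats.pearsonr(
        summaries["mean_sa_rank"].to_numpy(float),
        np.array([
            true_ages[(row.tract_id, row.end_label)] for row in summaries.itertuples()
        ]),
    ).statistic
    return summaries, atlas, spins, r_obs, res.p_spin, float(r_true)


def alignment_recovery(
    seed: int = 0,
    n_reps: int = 50,
    n_subjects: int = 400,
    n_tracts: int = 10,
    n_spins: int = 1000,
    n_draws: int = 2000,
) -> dict:
    """Endpoint-level alignment of maturation age with hierarchy rank.

    The generator ties maturation timescale to endpoint rank; success is
    a recovered Pearson r >= 0.6 with spin p < 0.05.
    """
    rng = substream(seed, "alignment_reps")
    hits, rs, r_trues = 0, [], []
    for _ in range(n_reps):
        rep_seed = int(rng.integers(2**31 - 1))
        cfg = SimulationConfig(
            n_subjects=n_subjects, n_tracts=n_tracts, seed=rep_seed
        )
        _, _, _, r_obs, p_spin, r_true = _alignment_one(
            cfg, rep_seed, n_spins, n_draws
        )
        rs.append(r_obs)
        r_trues.append(r_true)
        hits += (r_obs >= 0.6) and (p_spin < 0.05)
    return {
        "n_reps": n_reps,
        "n_subjects": n_subjects,
        "success_rate": hits / n_reps,
        "mean_recovered_r": float(np.mean(rs)),
        "mean_design_r": float(np.mean(r_trues)),
    }


def alignment_null_pvalues(
    seed: int = 0,
    n_reps: int = 200,
    n_subjects: int = 150,
    n_tracts: int = 6,
    n_spins: int = 500,
    n_draws: int = 500,
) -> dict:
    """Spin p-values under a rank-independent null (constant timescale)."""
    rng = substream(seed, "alignment_null")
    pvals = []
    for _ in range(n_reps):
        rep_seed = int(rng.integers(2**31 - 1))
        cfg = SimulationConfig(
            n_subjects=n_subjects,
            n_tracts=n_tracts,
            tau_fast=3.0,
            tau_slow=3.0,
            seed=rep_seed,
        )
        _, _, _, _, p_spin, _ = _alignment_one(cfg, rep_seed, n_spins, n_draws)
        pvals.append(p_spin)
    ks = scipy.stats.kstest(pvals, "uniform")
    return {
        "n_reps": n_reps,
        "ks_pvalue": float(ks.pvalue),
        "rejection_rate_at_05": float(np.mean(np.array(pvals) < 0.05)),
    }


def _delta_age_one(cfg, seed, n_spins, n_draws, sa_split=None):
    cohort, atlas, endpoint_table, profiles, truth = generate_dataset(cfg)
    node_results, *_ = _fit_superficial(profiles, cohort, truth, n_draws=n_draws, seed=seed)
    endpoint_sets = {
        (t, e): frozenset(sub["parcel_id"])
        for (t, e), sub in endpoint_table.groupby(["tract_id", "end_label"])
    }
    summaries = ep.summarize_endpoints(node_results, endpoint_sets, atlas)
    if sa_split is None:
        ranks = atlas["sa_rank"].to_numpy(float)
        sa_split = float((ranks.max() - ranks.min()) / 2.0)
    deltas, t_obs = ep.delta_analysis(summaries, sa_split)
    age_map = ep.aggregate_maturation_map(summaries, atlas, include_unmatured=True)
    tract_end_parcels = {
        tract: (
            list(sub[sub["end_label"] == "end_A"].iloc[0]["parcel_ids"]),
            list(sub[sub["end_label"] == "end_B"].iloc[0]["parcel_ids"]),
        )
        for tract, sub in summaries.groupby("tract_id")
    }
    groups = dict(zip(deltas["tract_id"], deltas["group"]))
    spins = spin.build_spins(atlas, n_spins=n_spins, seed=seed)
    res = spin.spin_delta_age_test(
        age_map["mean_age"].to_numpy(float),
        tract_end_parcels,
        groups,
        spins,
        observed_t=t_obs,
    )
    return deltas, res


def delta_age_contrast(
    seed: int = 0,
    n_reps: int = 50,
    n_subjects: int = 400,
    n_tracts: int = 8,
    n_spins: int = 500,
    n_draws: int = 1000,
    null: bool = False,
) -> dict:
    """Power (or calibration, with ``null=True``) of the one-tailed
    ΔAge-by-ΔS-A-group spin t-test on constructed homotopic/heterotopic
    tracts."""
    rng = substream(seed, "delta_age")
    hits = 0
    delta_large, delta_small = [], []
    for _ in range(n_reps):
        rep_seed = int(rng.integers(2**31 - 1))
        if null:
            cfg = SimulationConfig(
                n_subjects=n_subjects,
                n_tracts=n_tracts,
                tau_fast=3.0,
                tau_slow=3.0,
                noise_sd=0.02,
                seed=rep_seed,
            )
        else:
            cfg = SimulationConfig(
                n_subjects=n_subjects,
                n_tracts=n_tracts,
                tau_fast=0.8,
                tau_slow=8.0,
                noise_sd=0.01,
                seed=rep_seed,
            )
        deltas, res = _delta_age_one(cfg, rep_seed, n_spins, n_draws)
        hits += res.p_spin < 0.05
        delta_large.append(deltas.loc[deltas["group"] == "large", "delta_age"].mean())
        delta_small.append(deltas.loc[deltas["group"] == "small", "delta_age"].mean())
    return {
        "n_reps": n_reps,
        "n_subjects": n_subjects,
        "rejection_rate": hits / n_reps,
        "mean_delta_age_large": float(np.mean(delta_large)),
        "mean_delta_age_small": float(np.mean(delta_small)),
    }


def endpoint_dichotomy(
    seed: int = 0,
    n_reps: int = 100,
    n_subjects: int = 300,
    n_perm: int = 199,
    n_draws: int = 1000,
    alpha: float = 0.05,
) -> dict:
    """Homotopic vs heterotopic end-contrast dichotomy.

    A homotopic-like tract (equal end timescales) should give a
    non-significant end-vs-end contrast; a heterotopic-like tract (3:1
    timescale ratio across ends) a significant one, with the low-rank end
    maturing earlier. Timescales 1 and 3 years keep a meaningful share of
    each end's developmental change inside the sampled age window, which
    is what the end contrast can detect.
    """
    rng = substream(seed, "dichotomy")
    homo_ns, hetero_sig, direction_ok, concordant = 0, 0, 0, 0
    for _ in range(n_reps):
        rep_seed = int(rng.integers(2**31 - 1))
        cfg = SimulationConfig(
            n_subjects=n_subjects,
            n_tracts=2,
            tau_fast=1.0,
            tau_slow=3.0,
            noise_sd=0.02,
            seed=rep_seed,
        )
        cohort, atlas, endpoint_table, profiles, truth = generate_dataset(cfg)
        homo = trim_end_nodes(profiles["tract00_homotopic"])
        hetero = trim_end_nodes(profiles["tract01_heterotopic"])
        p_homo = enr.endpoint_contrast(
            homo, cohort, n_perm=n_perm, seed=rep_seed
        ).p_perm
        p_hetero = enr.endpoint_contrast(
            hetero, cohort, n_perm=n_perm, seed=rep_seed
        ).p_perm
        res = gam.fit_tract(hetero, cohort, n_draws=n_draws, seed=rep_seed)
        tab = res.table.set_index("node")
        est_a = tab.loc[SUPERFICIAL_NODES[:5], "maturation_age"].mean()
        est_b = tab.loc[SUPERFICIAL_NODES[5:], "maturation_age"].mean()
        true_a = truth.maturation_age["tract01_heterotopic"][SUPERFICIAL_NODES[:5]].mean()
        true_b = truth.maturation_age["tract01_heterotopic"][SUPERFICIAL_NODES[5:]].mean()
        low_first = (est_a < est_b) == (true_a < true_b)
        homo_ns += p_homo >= alpha
        hetero_sig += p_hetero < alpha
        direction_ok += low_first
        concordant += (p_homo >= alpha) and (p_hetero < alpha) and low_first
    return {
        "n_reps": n_reps,
        "n_subjects": n_subjects,
        "homotopic_nonsignificant_rate": homo_ns / n_reps,
        "heterotopic_significant_rate": hetero_sig / n_reps,
        "direction_rate": direction_ok / n_reps,
        "concordance_rate": concordant / n_reps,
    }
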