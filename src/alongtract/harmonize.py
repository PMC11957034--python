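"""Multi-site mean harmonization of tract profiles.

A ComBat-style location/scale correction fitted node-by-node with the
age effect preserved as a smooth term: the pooled model regresses the
metric on an unpenalized thin-plate age smooth (same basis as the
node-wise developmental models), sex, motion, and site indicators. Site
location shifts come from the site coefficients (centered to the pooled,
subject-weighted mean) and site scales from residual-SD ratios; per-node
site parameters are shrunk toward their across-node mean with the
standard empirical-Bayes ComBat priors (normal on shifts, inverse-gamma
on squared scales, moment-matched across nodes within tract).

Only the mean/scale stage is implemented; covariance-stage batch
correction is out of scope. With a single site the stage is the identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ShapeError, ValidationError
from .gam import SmoothSpec, TPRSBasis
from .io import TractProfileSet

DEFAULT_COVARIATES = ("sex", "motion")


@dataclass
class HarmonizationModel:
    """Per-node, per-site location/scale correction with preserved covariates."""

    tract_id: str
    node_ids: np.ndarray
    sites: tuple[str, ...]
    shift: np.ndarray  # (n_sites, n_nodes)
    scale: np.ndarray  # (n_sites, n_nodes)
    subjects: tuple[str, ...]
    site_index: np.ndarray  # (n_subjects,) index into `sites`
    preserved: np.ndarray  # (n_subjects, n_nodes) covariate-attributable prediction
    single_site: bool = False

    def to_frame(self) -> pd.DataFrame:
        """Audit table: one row per (node, site) with shift and scale."""
        n_sites, n_nodes = self.shift.shape
        return pd.DataFrame(
            {
                "node": np.tile(self.node_ids, n_sites),
                "site": np.repeat(self.sites, n_nodes),
                "shift": self.shift.ravel(),
                "scale": self.scale.ravel(),
            }
        )


def _shrink_shifts(shift_hat: np.ndarray, sampling_var: np.ndarray) -> np.ndarray:
    """Normal-prior EB shrinkage of per-node shifts toward the across-node mean.

    Prior variance is moment-matched: across-node variance of the raw
    estimates minus the mean sampling variance (floored at zero).
    """
    out = shift_hat.copy()
    for s in range(shift_hat.shape[0]):
        est = shift_hat[s]
        v = sampling_var[s]
        m = est.mean()
        tau2 = max(est.var(ddof=0) - v.mean(), 0.0)
        denom = tau2 + v
        nonzero = denom > 0
        out[s, nonzero] = (tau2 * est[nonzero] + v[nonzero] * m) / denom[nonzero]
    return out


def _shrink_scales(sum_z2: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Inverse-gamma EB shrinkage of per-node squared scales.

    ``sum_z2[s, v]`` is the sum of squared standardized residuals of site s
    at node v. Moment-matching across nodes provides the prior; the
    posterior-mode style update is the standard ComBat one.
    """
    n_sites, n_nodes = sum_z2.shape
    delta2_hat = sum_z2 / np.maximum(counts[:, None] - 1, 1)
    out = delta2_hat.copy()
    for s in range(n_sites):
        d2 = delta2_hat[s]
        m, v = d2.mean(), d2.var(ddof=0)
        if v < 1e-12 or n_nodes < 2:
            continue
        alpha = m * m / v + 2.0
        beta = m * (alpha - 1.0)
        out[s] = (2.0 * beta + sum_z2[s]) / (counts[s] + 2.0 * alpha - 2.0)
    return out


def fit_mean_harmonization(
    profiles: TractProfileSet,
    cohort: pd.DataFrame,
    spec: SmoothSpec | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    min_per_site: int = 20,
    shrink: bool = True,
) -> HarmonizationModel:
    """Fit the per-node site location/scale model with age preserved."""
    if list(profiles.subjects) != list(cohort["participant_id"]):
        raise ShapeError(
            f"tract {profiles.tract_id}: profile subjects do not match cohort order"
        )
    sites = tuple(sorted(cohort["site"].unique()))
    site_index = cohort["site"].map({s: i for i, s in enumerate(sites)}).to_numpy()
    Y = profiles.values
    n, n_nodes = Y.shape

    if len(sites) == 1:
        warnings.warn(
            "single-site cohort: harmonization is a no-op", UserWarning, stacklevel=2
        )
        return HarmonizationModel(
            tract_id=profiles.tract_id,
            node_ids=profiles.node_ids.copy(),
            sites=sites,
            shift=np.zeros((1, n_nodes)),
            scale=np.ones((1, n_nodes)),
            subjects=tuple(profiles.subjects),
            site_index=site_index,
            preserved=np.zeros_like(Y),
            single_site=True,
        )

    counts = np.bincount(site_index, minlength=len(sites))
    small = [s for s, c in zip(sites, counts) if c < min_per_site]
    if small:
        raise ValidationError(
            f"sites below the {min_per_site}-subject floor: {small} (counts "
            f"{[int(counts[sites.index(s)]) for s in small]})"
        )

    spec = spec or SmoothSpec()
    ages = cohort["age"].to_numpy(float)
    basis = TPRSBasis(ages, k=spec.k)
    B = basis.design(ages)
    C = cohort[list(covariates)].to_numpy(float)
    dummies = np.zeros((n, len(sites) - 1))
    for j in range(1, len(sites)):
        dummies[site_index == j, j - 1] = 1.0
    X = np.column_stack([np.ones(n), B, C, dummies])
    p = X.shape[1]
    p_pres = 1 + B.shape[1] + C.shape[1]

    G = np.linalg.inv(X.T @ X)
    beta = G @ (X.T @ Y)  # (p, n_nodes)
    resid = Y - X @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / (n - p)

    # site coefficients (reference site = 0) centered to the weighted mean
    gamma = np.vstack([np.zeros(n_nodes), beta[p_pres:, :]])  # (n_sites, n_nodes)
    weighted_mean = (counts[:, None] * gamma).sum(axis=0) / n
    shift_hat = gamma - weighted_mean[None, :]

    # exact sampling variance of each centered shift via the contrast matrix
    A = np.zeros((len(sites), p))
    for s in range(1, len(sites)):
        A[s, p_pres + s - 1] = 1.0
    A -= (counts[:, None] / n * A).sum(axis=0)[None, :]
    contrast_var = np.einsum("sp,pq,sq->s", A, G, A)  # per unit sigma^2
    sampling_var = contrast_var[:, None] * sigma2[None, :]

    sd_pooled = np.sqrt(sigma2)
    z = resid / sd_pooled[None, :]
    sum_z2 = np.zeros((len(sites), n_nodes))
    for s in range(len(sites)):
        rows = site_index == s
        sum_z2[s] = (z[rows] ** 2).sum(axis=0)

    if shrink:
        shift = _shrink_shifts(shift_hat, sampling_var)
        delta2 = _shrink_scales(sum_z2, counts)
    else:
        shift = shift_hat
        delta2 = sum_z2 / np.maximum(counts[:, None] - 1, 1)
    scale = np.sqrt(np.maximum(delta2, 1e-12))

    preserved = X[:, :p_pres] @ beta[:p_pres, :] + weighted_mean[None, :]
    return HarmonizationModel(
        tract_id=profiles.tract_id,
        node_ids=profiles.node_ids.copy(),
        sites=sites,
        shift=shift,
        scale=scale,
        subjects=tuple(profiles.subjects),
        site_index=site_index,
        preserved=preserved,
    )


def apply_harmonization(
    profiles: TractProfileSet, model: HarmonizationModel
) -> TractProfileSet:
    """Remove site location/scale effects while keeping covariate structure.

    value <- (value - site shift - preserved prediction) / site scale
             + preserved prediction
    """
    if not np.array_equal(profiles.node_ids, model.node_ids):
        raise ShapeError(
            f"tract {profiles.tract_id}: node ids do not match the fitted model"
        )
    if tuple(profiles.subjects) != model.subjects:
        raise ShapeError(
            f"tract {profiles.tract_id}: subjects do not match the fitted model"
        )
    if model.single_site:
        return replace(profiles, values=profiles.values.copy())
    shift = model.shift[model.site_index, :]
    scale = model.scale[model.site_index, :]
    adjusted = (profiles.values - shift - model.preserved) / scale + model.preserved
    out = replace(profiles, values=adjusted)
    out.validate()
    return out
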