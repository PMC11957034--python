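"""Spin-based spatial permutation nulls for parcellated cortical maps.

Parcel centroids live on a unit sphere per hemisphere. Each spin applies
one random proper rotation to the right hemisphere and its sagittal
mirror to the left, then re-assigns every original parcel the value of
the nearest rotated parcel centroid within its hemisphere (the
rotate-parcellation convention; many-to-one assignments are accepted).
Spinning one map while holding the other fixed yields a null that
preserves the spatial autocorrelation of cortical maps, and

    p_spin = (1 + #{|stat_null| >= |stat_obs|}) / (1 + n_spins)

(or the one-tailed analogue where a direction is prespecified).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from ._rng import substream
from .errors import InsufficientDataError, ParameterError, ValidationError

_SAGITTAL_MIRROR = np.diag([-1.0, 1.0, 1.0])


@dataclass
class SpinTestResult:
    observed: float
    p_spin: float
    n_spins: int
    tail: str
    n_excluded: int = 0
    null: np.ndarray | None = None


@dataclass
class SpinSet:
    """A reproducible set of spherical rotations and parcel re-assignments."""

    parcel_ids: np.ndarray
    assignment: np.ndarray  # (n_spins, n_parcels): spun value of parcel i is value[assignment[s, i]]
    rotations: np.ndarray  # (n_spins, 3, 3), right-hemisphere rotations
    seed: int

    @property
    def n_spins(self) -> int:
        return self.assignment.shape[0]

    def spin_values(self, values: np.ndarray) -> np.ndarray:
        """All spun versions of a parcel-aligned value vector, (n_spins, n_parcels)."""
        values = np.asarray(values, dtype=float)
        if values.shape[0] != self.assignment.shape[1]:
            raise ParameterError(
                f"value vector length {values.shape[0]} does not match "
                f"{self.assignment.shape[1]} parcels"
            )
        return values[self.assignment]

    def to_frame(self) -> pd.DataFrame:
        n_spins, n_parcels = self.assignment.shape
        return pd.DataFrame(
            {
                "spin": np.repeat(np.arange(n_spins), n_parcels),
                "original_parcel": np.tile(self.parcel_ids, n_spins),
                "spun_parcel": self.parcel_ids[self.assignment.ravel()],
            }
        )


def build_spins(
    atlas: pd.DataFrame,
    n_spins: int = 10000,
    seed: int = 0,
    identity: bool = False,
) -> SpinSet:
    """Generate random rotations and nearest-centroid parcel assignments.

    Rotations are drawn uniformly from SO(3) (QR orthogonalization of
    Gaussian matrices with sign and determinant fixes); the left
    hemisphere uses the right rotation conjugated by the sagittal
    reflection so mirrored atlases spin consistently. ``identity=True``
    is a test hook producing identity assignments.
    """
    centroids = atlas[["x", "y", "z"]].to_numpy(float)
    norms = np.linalg.norm(centroids, axis=1)
    if np.any(np.abs(norms - 1) > 1e-6):
        raise ValidationError("parcel centroids must be unit-norm")
    parcel_ids = atlas["parcel_id"].to_numpy()
    hemis = atlas["hemisphere"].to_numpy()
    present = sorted(set(hemis))
    if len(present) == 1:
        warnings.warn(
            f"single-hemisphere atlas ({present[0]}): spinning without mirroring",
            UserWarning,
            stacklevel=2,
        )

    n_parcels = len(atlas)
    if identity:
        assignment = np.tile(np.arange(n_parcels), (n_spins, 1))
        rotations = np.tile(np.eye(3), (n_spins, 1, 1))
        return SpinSet(parcel_ids, assignment, rotations, seed)

    rng = substream(seed, "spins")
    rotations = scipy.stats.special_ortho_group.rvs(3, size=n_spins, random_state=rng)
    if n_spins == 1:
        rotations = rotations[None, :, :]

    assignment = np.empty((n_spins, n_parcels), dtype=int)
    for hemi in present:
        rows = np.flatnonzero(hemis == hemi)
        C = centroids[rows]
        for s in range(n_spins):
            R = rotations[s]
            if hemi == "L" and len(present) == 2:
                R = _SAGITTAL_MIRROR @ R @ _SAGITTAL_MIRROR
            rotated = C @ R.T
            # nearest rotated centroid (max cosine) to each original centroid
            nearest = np.argmax(C @ rotated.T, axis=1)
            assignment[s, rows] = rows[nearest]
    return SpinSet(parcel_ids, assignment, rotations, seed)


def _pearson_rows(null_rows: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``null_rows`` against ``target`` (vectorized)."""
    x = null_rows - null_rows.mean(axis=1, keepdims=True)
    y = target - target.mean()
    denom = np.sqrt((x**2).sum(axis=1) * (y**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, x @ y / denom, np.nan)


def _tail_p(null: np.ndarray, observed: float, tail: str) -> float:
    null = null[np.isfinite(null)]
    n = null.size
    if tail == "two-sided":
        exceed = np.sum(np.abs(null) >= abs(observed))
    elif tail == "greater":
        exceed = np.sum(null >= observed)
    elif tail == "less":
        exceed = np.sum(null <= observed)
    else:
        raise ParameterError(f"unknown tail {tail!r}")
    return float((1.0 + exceed) / (1.0 + n))


def _endpoint_weights(
    endpoint_parcels: Sequence[Sequence[str]], parcel_ids: np.ndarray
) -> np.ndarray:
    index = {p: i for i, p in enumerate(parcel_ids)}
    W = np.zeros((len(endpoint_parcels), len(parcel_ids)))
    for e, parcels in enumerate(endpoint_parcels):
        if not parcels:
            raise ParameterError(f"endpoint {e} has no parcels")
        for p in parcels:
            W[e, index[p]] += 1.0
    return W / W.sum(axis=1, keepdims=True)


def spin_correlation_p(
    map_a: np.ndarray,
    map_b: np.ndarray,
    spins: SpinSet,
    tail: str = "two-sided",
    store_null: bool = False,
) -> SpinTestResult:
    """Spin p-value for the Pearson correlation of two parcel maps.

    ``map_b`` is spun; parcels absent (NaN) in ``map_a`` are excluded from
    both the observed and every null correlation.
    """
    map_a = np.asarray(map_a, dtype=float)
    map_b = np.asarray(map_b, dtype=float)
    common = np.isfinite(map_a) & np.isfinite(map_b)
    if common.sum() < 3:
        raise InsufficientDataError(
            f"need >= 3 common parcels to correlate, have {int(common.sum())}"
        )
    observed = float(
        scipy.stats.pearsonr(map_a[common], map_b[common]).statistic
    )
    spun_b = spins.spin_values(map_b)[:, common]
    # spun maps may move NaNs into the common mask: mask those per spin
    null = np.empty(spins.n_spins)
    finite_rows = np.isfinite(spun_b).all(axis=1)
    null[:] = np.nan
    if finite_rows.any():
        null[finite_rows] = _pearson_rows(spun_b[finite_rows], map_a[common])
    incomplete = ~finite_rows
    for s in np.flatnonzero(incomplete):
        row = spun_b[s]
        ok = np.isfinite(row)
        if ok.sum() >= 3:
            null[s] = scipy.stats.pearsonr(map_a[common][ok], row[ok]).statistic
    return SpinTestResult(
        observed=observed,
        p_spin=_tail_p(null, observed, tail),
        n_spins=spins.n_spins,
        tail=tail,
        n_excluded=int(np.sum(~np.isfinite(null))),
        null=null if store_null else None,
    )


def spin_correlation_endpoints(
    endpoint_values: np.ndarray,
    endpoint_parcels: Sequence[Sequence[str]],
    atlas: pd.DataFrame,
    spins: SpinSet,
    tail: str = "two-sided",
    store_null: bool = False,
) -> SpinTestResult:
    """Endpoint-level spin test: endpoint mean S-A ranks are recomputed from
    spun parcel ranks each spin and correlated with the endpoint values."""
    endpoint_values = np.asarray(endpoint_values, dtype=float)
    if len(endpoint_values) != len(endpoint_parcels):
        raise ParameterError("one value per endpoint required")
    if len(endpoint_values) < 3:
        raise InsufficientDataError("need >= 3 endpoints")
    ranks = atlas["sa_rank"].to_numpy(float)
    W = _endpoint_weights(endpoint_parcels, spins.parcel_ids)
    observed = float(
        scipy.stats.pearsonr(W @ ranks, endpoint_values).statistic
    )
    null = _pearson_rows(spins.spin_values(ranks) @ W.T, endpoint_values)
    return SpinTestResult(
        observed=observed,
        p_spin=_tail_p(null, observed, tail),
        n_spins=spins.n_spins,
        tail=tail,
        null=null if store_null else None,
    )


def _welch_t_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch t statistic of a (rows x n_a) vs b (rows x n_b)."""
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1) / na
    vb = b.var(axis=1, ddof=1) / nb
    denom = np.sqrt(va + vb)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (a.mean(axis=1) - b.mean(axis=1)) / denom, np.nan)


def spin_t_test(
    endpoint_parcels: Sequence[Sequence[str]],
    group_labels: Sequence[bool],
    atlas: pd.DataFrame,
    spins: SpinSet,
    tail: str = "greater",
    store_null: bool = False,
) -> SpinTestResult:
    """Spin p-value for a Welch t contrast of endpoint mean S-A ranks.

    ``group_labels`` marks the group hypothesized to have the greater
    ranks (e.g. still-developing endpoints); labels stay fixed while the
    rank map spins.
    """
    groups = np.asarray(group_labels, dtype=bool)
    if groups.sum() < 2 or (~groups).sum() < 2:
        raise InsufficientDataError(
            "need >= 2 endpoints per group for a t contrast "
            f"(have {int(groups.sum())} vs {int((~groups).sum())})"
        )
    ranks = atlas["sa_rank"].to_numpy(float)
    W = _endpoint_weights(endpoint_parcels, spins.parcel_ids)
    endpoint_ranks = W @ ranks
    observed = float(
        _welch_t_rows(endpoint_ranks[None, groups], endpoint_ranks[None, ~groups])[0]
    )
    spun = spins.spin_values(ranks) @ W.T
    null = _welch_t_rows(spun[:, groups], spun[:, ~groups])
    return SpinTestResult(
        observed=observed,
        p_spin=_tail_p(null, observed, tail),
        n_spins=spins.n_spins,
        tail=tail,
        null=null if store_null else None,
    )


def spin_delta_age_test(
    age_map: np.ndarray,
    tract_end_parcels: Mapping[str, tuple[Sequence[str], Sequence[str]]],
    tract_groups: Mapping[str, str],
    spins: SpinSet,
    observed_t: float | None = None,
    tail: str = "greater",
    store_null: bool = False,
) -> SpinTestResult:
    """Spin null for the ΔAge (large vs small ΔS-A) one-tailed t contrast.

    The parcel-level aggregated maturation-age map is spun; each spin
    recomputes every endpoint's mean age over its member parcels that
    carry a value, each tract's |ΔAge| between ends, and the Welch t of
    large- versus small-ΔS-A groups. Endpoints whose parcels all lose
    their value under a spin are excluded for that spin (counted, not
    imputed). A degenerate observed t (e.g. all ΔAge identical) is
    reported as p = 1.
    """
    age_map = np.asarray(age_map, dtype=float)
    tracts = sorted(tract_end_parcels)
    index = {p: i for i, p in enumerate(spins.parcel_ids)}

    def end_mean(values: np.ndarray, parcels: Sequence[str]) -> float:
        vals = values[[index[p] for p in parcels]]
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else np.nan

    def delta_ages(values: np.ndarray) -> np.ndarray:
        out = np.empty(len(tracts))
        for i, tract in enumerate(tracts):
            pa, pb = tract_end_parcels[tract]
            out[i] = abs(end_mean(values, pa) - end_mean(values, pb))
        return out

    large = np.array([tract_groups[t] == "large" for t in tracts])
    if large.sum() < 2 or (~large).sum() < 2:
        raise InsufficientDataError("need >= 2 tracts per ΔS-A group")

    if observed_t is None:
        d = delta_ages(age_map)
        observed_t = float(_welch_t_rows(d[None, large], d[None, ~large])[0])
    if not np.isfinite(observed_t):
        return SpinTestResult(np.nan, 1.0, spins.n_spins, tail)

    spun = spins.spin_values(age_map)
    null = np.empty(spins.n_spins)
    excluded = 0
    for s in range(spins.n_spins):
        d = delta_ages(spun[s])
        ok = np.isfinite(d)
        if (large & ok).sum() < 2 or (~large & ok).sum() < 2:
            null[s] = np.nan
            excluded += 1
            continue
        excluded += int(np.sum(~ok))
        null[s] = _welch_t_rows(d[None, large & ok], d[None, ~large & ok])[0]
    return SpinTestResult(
        observed=float(observed_t),
        p_spin=_tail_p(null, observed_t, tail),
        n_spins=spins.n_spins,
        tail=tail,
        n_excluded=excluded,
        null=null if store_null else None,
    )
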