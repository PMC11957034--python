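"""Node-wise developmental models.

Each node of each tract gets a generalized additive model with the
microstructure metric as response, age as a smooth term, and sex and
in-scanner motion as linear covariates. The smooth uses an unpenalized
1-D thin-plate regression spline basis with maximum basis dimension
k = 3; an unpenalized fit is exactly ordinary least squares on the
basis-expanded design, so coefficient covariances are the exact OLS
ones rather than penalized approximations.

Derived per-node quantities:

* the age-effect magnitude ``delta_r2_adj`` — absolute difference in
  adjusted R^2 between the full model and a reduced model without the
  age term — with a partial-F (ANOVA) p-value and BH-FDR q-value;
* a fitted age trajectory evaluated at 200 timepoints, with linear
  covariates held at reference values (sample means by default);
* the first derivative of the age smooth by central finite differences,
  with a simultaneous 95% confidence band obtained by simulating from
  the coefficient distribution and using the max-t critical multiplier;
* the age of maturation — the first grid age at which the simultaneous
  derivative band includes zero, ceiling-set to the maximum sampled age
  when the band never does;
* the per-node coefficient of variation across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
from statsmodels.stats.multitest import multipletests

from ._rng import substream
from .errors import (
    ContractError,
    NumericalError,
    ParameterError,
    RankError,
    ShapeError,
)
from .io import TractProfileSet

DEFAULT_COVARIATES = ("sex", "motion")


@dataclass(frozen=True)
class SmoothSpec:
    """Age-smooth specification: unpenalized 1-D thin-plate spline basis."""

    k: int = 3
    basis: str = "tp"
    penalized: bool = False

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ParameterError(f"smooth basis dimension k must be >= 3, got k={self.k}")
        if self.basis != "tp":
            raise ParameterError(f"only the thin-plate ('tp') basis is supported, got {self.basis!r}")
        if self.penalized:
            raise ParameterError("penalized smooths are not supported (unpenalized fits only)")


class TPRSBasis:
    """1-D thin-plate regression spline basis of rank ``k``.

    Radial basis |a - a*|^3 at knots placed at the unique data ages,
    eigen-truncated to the ``k`` leading eigenvectors, with the constraint
    null space {1, age} absorbed: beyond the intercept the design carries
    a centered linear-age column plus k - 2 "wiggly" columns, i.e. k - 1
    smooth columns in total. Metadata suffices to evaluate the basis at
    arbitrary new ages.
    """

    def __init__(self, ages: np.ndarray, k: int = 3, max_knots: int = 200):
        ages = np.asarray(ages, dtype=float)
        knots = np.unique(ages)
        if knots.size < k:
            raise RankError(
                f"need at least k={k} distinct ages to build the smooth, got {knots.size}"
            )
        if knots.size > max_knots:
            qs = np.linspace(0, 1, max_knots)
            knots = np.unique(np.quantile(knots, qs))
        self.k = k
        self.knots = knots

        r = np.abs(knots[:, None] - knots[None, :])
        E = r**3
        T = np.column_stack([np.ones_like(knots), knots])
        eigval, eigvec = np.linalg.eigh(E)
        order = np.argsort(-np.abs(eigval))[:k]
        Uk = eigvec[:, order]
        # absorb the constraint T' delta = 0 into the parameterization
        _, _, vt = np.linalg.svd(T.T @ Uk)
        Z = vt[2:].T  # k x (k - 2)
        self._M = Uk @ Z  # knots x (k - 2)

        raw = self._raw(ages)
        self._centers = raw.mean(axis=0)
        sd = raw.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        self._scales = sd

    @property
    def n_columns(self) -> int:
        """Smooth columns beyond the intercept (linear age + wiggly)."""
        return self.k - 1

    def _raw(self, ages: np.ndarray) -> np.ndarray:
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        wiggly = (np.abs(ages[:, None] - self.knots[None, :]) ** 3) @ self._M
        return np.column_stack([ages, wiggly])

    def design(self, ages: np.ndarray) -> np.ndarray:
        """Evaluate the centered, scaled smooth columns at the given ages."""
        return (self._raw(ages) - self._centers) / self._scales


@dataclass
class NodeFit:
    """One OLS fit (full or reduced) of a node-wise developmental model."""

    beta: np.ndarray
    cov: np.ndarray
    column_names: tuple[str, ...]
    n: int
    rss: float
    r2: float
    r2_adj: float
    sigma2: float
    basis: TPRSBasis | None
    age_min: float
    age_max: float
    covariate_ref: dict[str, float]
    smooth_slice: slice | None

    @property
    def p(self) -> int:
        return len(self.column_names)

    @property
    def df_resid(self) -> int:
        return self.n - self.p

    def design_row(self, ages: np.ndarray) -> np.ndarray:
        """Design matrix at new ages with covariates held at reference."""
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        cols = [np.ones_like(ages)]
        if self.basis is not None:
            cols.append(self.basis.design(ages))
        for name in self.column_names:
            if name in self.covariate_ref:
                cols.append(np.full_like(ages, self.covariate_ref[name]))
        return np.column_stack(cols)

    def predict(self, ages: np.ndarray) -> np.ndarray:
        return self.design_row(ages) @ self.beta

    def derivative_design(self, ages: np.ndarray, h: float) -> np.ndarray:
        """Central-difference derivative of the design w.r.t. age.

        Covariate and intercept columns are constant in age, so only the
        smooth columns contribute.
        """
        if self.basis is None:
            raise ContractError("reduced fit has no age smooth to differentiate")
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        D = np.zeros((ages.size, self.p))
        D[:, self.smooth_slice] = (self.basis.design(ages + h) - self.basis.design(ages - h)) / (
            2.0 * h
        )
        return D


@dataclass
class DerivativeBand:
    """Simultaneous confidence band for the age derivative on a grid."""

    ages: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    crit: float
    level: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "deriv": self.estimate,
                "deriv_lo": self.lower,
                "deriv_hi": self.upper,
            }
        )


def _check_design_rank(X: np.ndarray, names: Sequence[str]) -> None:
    R = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [names[i] for i in np.flatnonzero(diag <= tol)]
    if bad:
        raise RankError(f"rank-deficient design; collinear column(s): {bad}")


def _ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Least squares of each column of Y on X.

    Returns (beta, rss, r2, r2_adj) with Y of shape (n, m).
    """
    n, p = X.shape
    Q, R = np.linalg.qr(X)
    qty = Q.T @ Y
    beta = scipy.linalg.solve_triangular(R, qty)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    centered = Y - Y.mean(axis=0)
    tss = np.einsum("ij,ij->j", centered, centered)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(tss > 0, 1.0 - rss / tss, 0.0)
    df_resid = n - p
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / df_resid
    return beta, rss, r2, r2_adj


def build_design(
    cohort: pd.DataFrame,
    spec: SmoothSpec | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    basis: TPRSBasis | None = None,
) -> tuple[np.ndarray, np.ndarray, TPRSBasis, tuple[str, ...], tuple[str, ...]]:
    """Full and reduced design matrices for the node models.

    Full: intercept + smooth-age columns + linear covariates.
    Reduced: the same without any age column.
    """
    spec = spec or SmoothSpec()
    ages = cohort["age"].to_numpy(float)
    if basis is None:
        basis = TPRSBasis(ages, k=spec.k)
    B = basis.design(ages)
    C = cohort[list(covariates)].to_numpy(float) if covariates else np.empty((len(cohort), 0))
    ones = np.ones((len(cohort), 1))
    X_full = np.column_stack([ones, B, C])
    X_red = np.column_stack([ones, C])
    smooth_names = tuple(f"s(age).{j}" for j in range(B.shape[1]))
    full_names = ("intercept", *smooth_names, *covariates)
    red_names = ("intercept", *covariates)
    return X_full, X_red, basis, full_names, red_names


def fit_node(
    y: np.ndarray,
    cohort: pd.DataFrame,
    spec: SmoothSpec | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    basis: TPRSBasis | None = None,
) -> tuple[NodeFit, NodeFit]:
    """Fit the full (with age smooth) and reduced (no age) models by OLS."""
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size != len(cohort):
        raise ShapeError(f"response length {y.size} does not match cohort size {len(cohort)}")
    if np.any(~np.isfinite(y)):
        raise ShapeError("response contains missing values")
    X_full, X_red, basis, full_names, red_names = build_design(cohort, spec, covariates, basis)
    ages = cohort["age"].to_numpy(float)
    ref = {name: float(cohort[name].mean()) for name in covariates}
    fits = []
    for X, names, b in ((X_full, full_names, basis), (X_red, red_names, None)):
        _check_design_rank(X, names)
        beta, rss, r2, r2_adj = _ols(X, y[:, None])
        n, p = X.shape
        sigma2 = float(rss[0]) / (n - p)
        G = np.linalg.inv(X.T @ X)
        fits.append(
            NodeFit(
                beta=beta[:, 0],
                cov=sigma2 * G,
                column_names=names,
                n=n,
                rss=float(rss[0]),
                r2=float(r2[0]),
                r2_adj=float(r2_adj[0]),
                sigma2=sigma2,
                basis=b,
                age_min=float(ages.min()),
                age_max=float(ages.max()),
                covariate_ref=ref,
                smooth_slice=slice(1, 1 + basis.n_columns) if b is not None else None,
            )
        )
    return fits[0], fits[1]


def age_effect(full: NodeFit, reduced: NodeFit) -> tuple[float, float]:
    """Age-effect magnitude and significance.

    delta_r2_adj = |R2_adj(full) - R2_adj(reduced)|; the p-value is the
    partial F-test (ANOVA) comparing the nested OLS models.
    """
    if not set(reduced.column_names) <= set(full.column_names):
        raise ContractError(
            f"models are not nested: {reduced.column_names} vs {full.column_names}"
        )
    if full.n != reduced.n:
        raise ContractError("full and reduced fits use different sample sizes")
    delta = abs(full.r2_adj - reduced.r2_adj)
    df1 = full.p - reduced.p
    df2 = full.df_resid
    if df1 == 0:
        return delta, 1.0
    num = (reduced.rss - full.rss) / df1
    den = full.rss / df2
    if den == 0.0:
        p = 1.0 if num <= 0 else 0.0
    else:
        f_stat = num / den
        p = float(scipy.stats.f.sf(f_stat, df1, df2)) if f_stat > 0 else 1.0
    return delta, p


def partial_f_pvalues(
    rss_full: np.ndarray, rss_red: np.ndarray, df1: int, df2: int
) -> np.ndarray:
    """Vectorized partial-F p-values from residual sums of squares."""
    rss_full = np.asarray(rss_full, float)
    rss_red = np.asarray(rss_red, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = ((rss_red - rss_full) / df1) / (rss_full / df2)
    p = np.ones_like(f_stat)
    pos = np.isfinite(f_stat) & (f_stat > 0)
    p[pos] = scipy.stats.f.sf(f_stat[pos], df1, df2)
    p[np.isinf(f_stat)] = 0.0
    return p


def fdr_correct(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals < 0) | (pvals > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def fitted_trajectory(fit: NodeFit, n_points: int = 200) -> pd.DataFrame:
    """Fitted metric values on an age grid, covariates at reference values."""
    grid = np.linspace(fit.age_min, fit.age_max, n_points)
    return pd.DataFrame({"age": grid, "fitted": fit.predict(grid)})


def _cov_sqrt(cov: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        eigval, eigvec = np.linalg.eigh(cov)
        floor = -1e-8 * max(eigval.max(), 1.0)
        if eigval.min() < floor:
            raise NumericalError(
                f"coefficient covariance is not PSD (min eigenvalue {eigval.min():.3e}, "
                f"max {eigval.max():.3e})"
            )
        return eigvec * np.sqrt(np.clip(eigval, 0, None))


def derivative_band(
    fit: NodeFit,
    grid: np.ndarray | None = None,
    n_points: int = 200,
    n_draws: int = 10000,
    level: float = 0.95,
    seed: int = 0,
    h: float | None = None,
) -> DerivativeBand:
    """Simultaneous confidence band for the first derivative of the age smooth.

    The derivative is estimated by central finite differences of the fitted
    smooth at step ``h`` (default 1e-3 of the age range). The band simulates
    coefficient draws from N(beta_hat, V_beta) — exact for these unpenalized
    fits — and uses the ``level`` quantile of the grid-wise max standardized
    deviation as the critical multiplier on pointwise standard errors.
    """
    if grid is None:
        grid = np.linspace(fit.age_min, fit.age_max, n_points)
    grid = np.asarray(grid, dtype=float)
    if h is None:
        h = 1e-3 * (fit.age_max - fit.age_min)
    D = fit.derivative_design(grid, h)
    est = D @ fit.beta
    band_cov = D @ fit.cov @ D.T
    se = np.sqrt(np.clip(np.diag(band_cov), 0, None))
    if fit.sigma2 == 0 or np.all(se == 0):
        return DerivativeBand(grid, est, est.copy(), est.copy(), 0.0, level)
    L = _cov_sqrt(fit.cov)
    z = substream(seed, "derivative_band").standard_normal((fit.p, n_draws))
    dev = D @ (L @ z)
    ok = se > 0
    t_max = np.max(np.abs(dev[ok]) / se[ok, None], axis=0)
    crit = float(np.quantile(t_max, level))
    return DerivativeBand(grid, est, est - crit * se, est + crit * se, crit, level)


def age_of_maturation(band: DerivativeBand, age_max: float) -> tuple[float, bool]:
    """First grid age at which the simultaneous derivative band includes zero.

    If the band excludes zero on the whole grid, the node is still
    developing at the end of the window and the maturation age is
    ceiling-set to ``age_max`` with ``matured = False``.
    """
    if np.any(np.diff(band.ages) <= 0):
        raise ParameterError("derivative band grid must be strictly increasing")
    inside = (band.lower <= 0) & (band.upper >= 0)
    idx = np.flatnonzero(inside)
    if idx.size:
        return float(band.ages[idx[0]]), True
    return float(age_max), False


def coefficient_of_variation(
    profiles: TractProfileSet,
    deep_nodes: Sequence[int] | None = None,
    superficial_nodes: Sequence[int] | None = None,
) -> tuple[pd.Series, dict[str, float]]:
    """Per-node CV (sd/mean over subjects) plus deep/superficial bin means."""
    means = profiles.values.mean(axis=0)
    if np.any(means == 0):
        raise NumericalError("zero mean metric value; CV undefined")
    cv = profiles.values.std(axis=0, ddof=1) / means
    series = pd.Series(cv, index=pd.Index(profiles.node_ids, name="node"), name="cv")
    bins: dict[str, float] = {}
    if deep_nodes is not None:
        bins["deep"] = float(series.loc[list(deep_nodes)].mean())
    if superficial_nodes is not None:
        bins["superficial"] = float(series.loc[list(superficial_nodes)].mean())
    return series, bins


@dataclass
class TractFitResult:
    """Batched node-wise results for one tract."""

    table: pd.DataFrame
    fitted: pd.DataFrame
    bands: pd.DataFrame
    basis: TPRSBasis
    grid: np.ndarray
    crit: float


def fit_tract(
    profiles: TractProfileSet,
    cohort: pd.DataFrame,
    spec: SmoothSpec | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    n_points: int = 200,
    n_draws: int = 10000,
    level: float = 0.95,
    seed: int = 0,
    compute_bands: bool = True,
) -> TractFitResult:
    """Fit every node of a tract and assemble tidy per-node results.

    All nodes share one design, so the fits are batched through a single QR
    factorization, and — because the standardized max-t statistic does not
    depend on the node's residual variance — one simulated critical
    multiplier serves every node's simultaneous derivative band exactly.
    """
    if list(profiles.subjects) != list(cohort["participant_id"]):
        raise ShapeError(
            f"tract {profiles.tract_id}: subjects do not match cohort order"
        )
    X_full, X_red, basis, full_names, red_names = build_design(cohort, spec, covariates)
    _check_design_rank(X_full, full_names)
    Y = profiles.values
    n, p_full = X_full.shape
    p_red = X_red.shape[1]
    beta_f, rss_f, _, r2a_f = _ols(X_full, Y)
    _, rss_r, _, r2a_r = _ols(X_red, Y)
    delta = np.abs(r2a_f - r2a_r)
    pvals = partial_f_pvalues(rss_f, rss_r, p_full - p_red, n - p_full)
    qvals = fdr_correct(pvals)
    sigma2 = rss_f / (n - p_full)

    ages = cohort["age"].to_numpy(float)
    age_min, age_max = float(ages.min()), float(ages.max())
    grid = np.linspace(age_min, age_max, n_points)
    ref = {name: float(cohort[name].mean()) for name in covariates}

    # fitted trajectories at reference covariates
    B_grid = basis.design(grid)
    X_grid = np.column_stack(
        [np.ones_like(grid), B_grid, *(np.full_like(grid, ref[c]) for c in covariates)]
    )
    fitted_vals = X_grid @ beta_f  # (n_points, n_nodes)

    cv_series, _ = coefficient_of_variation(profiles)

    mat_age = np.full(Y.shape[1], age_max)
    matured = np.zeros(Y.shape[1], dtype=bool)
    crit = float("nan")
    bands_frame = pd.DataFrame()
    if compute_bands:
        h = 1e-3 * (age_max - age_min)
        D_smooth = (basis.design(grid + h) - basis.design(grid - h)) / (2 * h)
        D = np.zeros((n_points, p_full))
        D[:, 1 : 1 + basis.n_columns] = D_smooth
        G = np.linalg.inv(X_full.T @ X_full)
        unit_cov = D @ G @ D.T
        unit_se = np.sqrt(np.clip(np.diag(unit_cov), 0, None))
        L = _cov_sqrt(G)
        z = substream(seed, f"band/{profiles.tract_id}").standard_normal((p_full, n_draws))
        dev = D @ (L @ z)
        ok = unit_se > 0
        t_max = np.max(np.abs(dev[ok]) / unit_se[ok, None], axis=0)
        crit = float(np.quantile(t_max, level))

        deriv = D @ beta_f  # (n_points, n_nodes)
        half_width = crit * unit_se[:, None] * np.sqrt(sigma2)[None, :]
        inside = np.abs(deriv) <= half_width
        for j in range(Y.shape[1]):
            idx = np.flatnonzero(inside[:, j])
            if idx.size:
                mat_age[j] = grid[idx[0]]
                matured[j] = True
        bands_frame = pd.DataFrame(
            {
                "tract_id": profiles.tract_id,
                "node": np.repeat(profiles.node_ids, n_points),
                "age": np.tile(grid, Y.shape[1]),
                "fitted": fitted_vals.T.ravel(),
                "deriv": deriv.T.ravel(),
                "deriv_lo": (deriv - half_width).T.ravel(),
                "deriv_hi": (deriv + half_width).T.ravel(),
            }
        )

    table = pd.DataFrame(
        {
            "tract_id": profiles.tract_id,
            "node": profiles.node_ids,
            "delta_r2_adj": delta,
            "p_age": pvals,
            "q_age": qvals,
            "maturation_age": mat_age,
            "matured": matured,
            "cv": cv_series.to_numpy(),
        }
    )
    fitted_frame = pd.DataFrame(
        {
            "tract_id": profiles.tract_id,
            "node": np.repeat(profiles.node_ids, n_points),
            "age": np.tile(grid, Y.shape[1]),
            "fitted": fitted_vals.T.ravel(),
        }
    )
    return TractFitResult(table, fitted_frame, bands_frame, basis, grid, crit)
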