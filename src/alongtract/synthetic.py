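"""Synthetic cohorts, tract geometries and tract profiles with known truth.

The generator emulates the statistical structure that the along-tract
developmental analysis assumes: a metric (mean-diffusivity-like, in units
of 1e-3 mm^2/s) that decays exponentially with age at every node,

    m(s, v) = asym_v + A_v * exp(-(age_s - age_min) / tau_v)
              + b_sex * sex_s + b_mot * motion_s + site offset + noise,

with a deep-to-superficial amplitude gradient (A_v smallest at the tract
midpoint, largest at the ends), maturation timescales tau_v at superficial
nodes tied to the hierarchy rank of the adjacent cortical endpoint
(low-rank ends mature fast, high-rank ends slowly), additive site offsets
with site-specific noise scaling, and homoscedastic Gaussian noise.

Ground truth is analytic: the true age of maturation of node v is the age
at which the noiseless derivative magnitude A_v/tau_v * exp(-(a-age_min)/tau_v)
falls below a detectability-scaled slope criterion (see
:meth:`SimulationConfig.criterion`), clamped to the sampled age window.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ._rng import substream
from .errors import ConfigError, GenerationError, ShapeError, ValidationError
from .io import (
    TractProfileSet,
    write_endpoint_table,
    write_parcel_table,
    write_participants,
    write_tract_profiles,
)


def detectable_slope(
    n_subjects: int,
    age_min: float,
    age_max: float,
    noise_sd: float,
    k: int = 3,
    n_points: int = 200,
    level: float = 0.95,
) -> float:
    """Median half-width of the simultaneous derivative band on an
    idealized design: uniform age quantiles, unpenalized thin-plate age
    smooth of rank ``k``, residual SD ``noise_sd``.

    The critical multiplier uses the chi-square bound for the rank-(k-1)
    coefficient deviation process, sqrt(chi2_{k-1}(level)), a tight upper
    bound on the max-t multiplier over any grid.
    """
    from scipy.stats import chi2

    from .gam import TPRSBasis

    m = max(int(n_subjects), 50)  # design evaluated on a stable grid, scaled to n
    ages = age_min + (age_max - age_min) * (np.arange(m) + 0.5) / m
    basis = TPRSBasis(ages, k=k)
    X = np.column_stack([np.ones_like(ages), basis.design(ages)])
    G = np.linalg.inv(X.T @ X) * (m / n_subjects)
    grid = np.linspace(age_min, age_max, n_points)
    h = 1e-3 * (age_max - age_min)
    D = np.zeros((n_points, X.shape[1]))
    D[:, 1:] = (basis.design(grid + h) - basis.design(grid - h)) / (2 * h)
    unit_se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", D, G, D), 0, None))
    crit = float(np.sqrt(chi2.ppf(level, k - 1)))
    return crit * noise_sd * float(np.median(unit_se))


@dataclass(frozen=True)
class Site:
    """One acquisition site: additive metric offset and noise-scale multiplier."""

    label: str
    offset: float = 0.0
    noise_scale: float = 1.0


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror a single-site developmental cohort sampled over ages
    8-23 years with a 4:1 superficial:deep amplitude gradient and
    maturation timescales between 2 and 6 years across the hierarchy.
    """

    n_subjects: int = 250
    age_min: float = 8.0
    age_max: float = 23.0
    n_tracts: int = 6
    n_nodes: int = 100
    parcels_per_hemisphere: int = 30
    sites: tuple[Site, ...] = (Site("siteA"),)
    amplitude_deep: float = 0.025
    amplitude_superficial: float = 0.10
    tau_fast: float = 2.0
    tau_slow: float = 6.0
    noise_sd: float = 0.03
    sex_effect: float = 0.01
    motion_effect: float = 0.02
    derivative_criterion: float | None = None
    metric_name: str = "dki_md"
    seed: int = 0

    def __post_init__(self) -> None:
        self.sites = tuple(
            Site(**s) if isinstance(s, dict) else s for s in self.sites
        )
        self.validate()

    def validate(self) -> None:
        checks = [
            (self.n_subjects >= 1, "n_subjects must be >= 1"),
            (self.age_min < self.age_max, "age_min must be < age_max"),
            (self.n_tracts >= 1, "n_tracts must be >= 1"),
            (self.n_nodes >= 20, "n_nodes must be >= 20"),
            (self.parcels_per_hemisphere >= 8, "parcels_per_hemisphere must be >= 8"),
            (len(self.sites) >= 1, "sites must be nonempty"),
            (
                0 <= self.amplitude_deep <= self.amplitude_superficial,
                "amplitude_superficial must be >= amplitude_deep >= 0",
            ),
            (0 < self.tau_fast <= self.tau_slow, "tau_slow must be >= tau_fast > 0"),
            (self.noise_sd > 0, "noise_sd must be > 0"),
            (
                self.derivative_criterion is None or self.derivative_criterion > 0,
                "derivative_criterion must be > 0 when given",
            ),
        ]
        for ok, message in checks:
            if not ok:
                raise ConfigError(message)
        if any(s.noise_scale <= 0 for s in self.sites):
            raise ConfigError("sites: noise_scale must be > 0")

    @property
    def age_range(self) -> float:
        return self.age_max - self.age_min

    @property
    def criterion(self) -> float:
        """Slope magnitude below which a node counts as matured.

        Default is the slope the fitted simultaneous derivative band is
        expected to resolve under this config's noise level and sample
        size: the median half-width of the 95% simultaneous band of the
        age-smooth derivative, computed analytically on an idealized
        design (uniform age quantiles, same spline basis as the node
        models). A node's true maturation age is where the noiseless
        derivative magnitude falls below this detectability threshold,
        which makes "the confidence band includes zero" recoverable in
        simulation.
        """
        if self.derivative_criterion is not None:
            return self.derivative_criterion
        return detectable_slope(
            self.n_subjects, self.age_min, self.age_max, self.noise_sd
        )

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["sites"] = [dataclasses.asdict(s) for s in self.sites]
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        data["sites"] = tuple(Site(**s) for s in data.get("sites", [{"label": "siteA"}]))
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class GroundTruth:
    """Analytic truth of one simulated dataset, keyed by tract id."""

    amplitude: dict[str, np.ndarray]
    tau: dict[str, np.ndarray]
    asymptote: dict[str, np.ndarray]
    maturation_age: dict[str, np.ndarray]
    matured: dict[str, np.ndarray]
    endpoint_rank: dict[tuple[str, str], float]
    criterion: float


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw the participant table: uniform ages, 0/1 sex, truncated-lognormal
    head motion in (0, 1] mm, sites assigned round-robin."""
    config.validate()
    rng = substream(config.seed, "cohort")
    n = config.n_subjects
    ages = rng.uniform(config.age_min, config.age_max, size=n)
    sex = rng.integers(0, 2, size=n)
    motion = rng.lognormal(mean=-1.7, sigma=0.5, size=n)
    for _ in range(100):
        bad = motion > 1.0
        if not bad.any():
            break
        motion[bad] = rng.lognormal(mean=-1.7, sigma=0.5, size=int(bad.sum()))
    motion = np.clip(motion, None, 1.0)
    labels = [s.label for s in config.sites]
    return pd.DataFrame(
        {
            "participant_id": [f"sub-{i:05d}" for i in range(n)],
            "age": ages,
            "sex": sex,
            "motion": motion,
            "site": [labels[i % len(labels)] for i in range(n)],
        }
    )


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Near-uniform unit-sphere lattice (golden-spiral construction)."""
    i = np.arange(n, dtype=float)
    golden = (1 + np.sqrt(5)) / 2
    z = 1 - (2 * i + 1) / n
    theta = 2 * np.pi * i / golden
    r = np.sqrt(np.clip(1 - z**2, 0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _block(sorted_idx: np.ndarray, pos: int, size: int) -> np.ndarray:
    pos = int(np.clip(pos, 0, len(sorted_idx) - size))
    return sorted_idx[pos : pos + size]


def generate_geometry(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the parcel atlas and tract-to-parcel endpoint table.

    Parcels sit on a Fibonacci lattice per unit hemisphere-sphere (left =
    sagittal mirror of right). Hierarchy rank is the rank order of a smooth
    field (one sphere axis plus low-amplitude smooth noise). Each tract gets
    two disjoint endpoint parcel blocks; tract ids carry a ``_homotopic`` /
    ``_heterotopic`` suffix describing whether the two ends sit at similar
    hierarchy ranks or span more than half the rank range.
    """
    config.validate()
    rng = substream(config.seed, "geometry")
    pph = config.parcels_per_hemisphere
    right = _fibonacci_sphere(pph)
    left = right * np.array([-1.0, 1.0, 1.0])
    centroids = np.vstack([left, right])
    hemis = ["L"] * pph + ["R"] * pph
    n_parcels = 2 * pph

    # Smooth scalar hierarchy field on the sphere: a weak principal axis
    # plus several localized (von Mises-Fisher-like) bumps of alternating
    # sign. The bumps matter: the real sensorimotor-association axis is
    # spatially multi-peaked on the inflated sphere (sensorimotor and
    # visual poles are far apart, association cortex in between), and a
    # purely axial field would make every rotation of the sphere carry
    # the same low-to-high arrangement, degenerating spin-based nulls.
    field_vals = 0.3 * centroids[:, 2]
    for i in range(4):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        sign = 1.0 if i % 2 == 0 else -1.0
        field_vals += sign * np.exp(5.0 * (centroids @ direction - 1.0))
    ranks = field_vals.argsort().argsort() + 1  # 1..n_parcels

    atlas = pd.DataFrame(
        {
            "parcel_id": [f"parcel_{i:03d}" for i in range(n_parcels)],
            "hemisphere": hemis,
            "sa_rank": ranks,
            "x": centroids[:, 0],
            "y": centroids[:, 1],
            "z": centroids[:, 2],
        }
    )

    by_rank = np.argsort(ranks)
    size = 3
    placements: list[tuple[str, np.ndarray, np.ndarray]] = []

    def homotopic_id(t: int) -> str:
        return f"tract{t:02d}_homotopic"

    def heterotopic_id(t: int) -> str:
        return f"tract{t:02d}_heterotopic"

    # tract 0: homotopic-like (adjacent rank blocks); tract 1: heterotopic-like
    c0 = int(0.40 * (n_parcels - 2 * size))
    placements.append((homotopic_id(0), _block(by_rank, c0, size), _block(by_rank, c0 + size, size)))
    placements.append((heterotopic_id(1), _block(by_rank, 0, size), _block(by_rank, n_parcels - size, size)))
    m = config.n_tracts - 2
    for i in range(m):
        u = (i + 0.5) / m
        t = i + 2
        if i % 2 == 0:
            pos = int((0.05 + 0.75 * u) * (n_parcels - 2 * size))
            placements.append(
                (homotopic_id(t), _block(by_rank, pos, size), _block(by_rank, pos + size, size))
            )
        else:
            lo = int(0.25 * u * (n_parcels - size))
            hi = int((1 - 0.25 * u) * (n_parcels - size))
            placements.append(
                (heterotopic_id(t), _block(by_rank, lo, size), _block(by_rank, hi, size))
            )

    rows = []
    for tract_id, block_a, block_b in placements[: config.n_tracts]:
        if set(block_a) & set(block_b):
            raise GenerationError(
                f"{tract_id}: too few parcels to place disjoint endpoint blocks "
                f"(parcels_per_hemisphere={pph}, n_tracts={config.n_tracts})"
            )
        for end, block in (("end_A", block_a), ("end_B", block_b)):
            for idx in block:
                rows.append(
                    {
                        "tract_id": tract_id,
                        "end_label": end,
                        "parcel_id": atlas["parcel_id"].iloc[idx],
                        "probability": float(rng.uniform(0.4, 1.0)),
                    }
                )
    endpoint_table = pd.DataFrame(rows)
    return atlas, endpoint_table


def _u_shape(n_nodes: int) -> np.ndarray:
    """Smooth profile equal to 1 at the tract ends and 0 at the midpoint."""
    t = np.linspace(0.0, 1.0, n_nodes)
    return (2 * t - 1) ** 2


def endpoint_mean_ranks(
    atlas: pd.DataFrame, endpoint_table: pd.DataFrame
) -> dict[tuple[str, str], float]:
    rank_of = dict(zip(atlas["parcel_id"], atlas["sa_rank"].astype(float)))
    out: dict[tuple[str, str], float] = {}
    for (tract, end), sub in endpoint_table.groupby(["tract_id", "end_label"]):
        out[(str(tract), str(end))] = float(
            np.mean([rank_of[p] for p in sub["parcel_id"]])
        )
    return out


def true_maturation_age(
    amplitude: np.ndarray,
    tau: np.ndarray,
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic age where |dm/dage| first drops below the slope criterion.

    |dm/da| = A/tau * exp(-(a - age_min)/tau) = c  =>
    a* = age_min + tau * log(A / (tau * c)), clamped to the age window.
    """
    c = config.criterion
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = amplitude / (tau * c)
        age = config.age_min + tau * np.log(np.maximum(ratio, 1.0))
    matured = age < config.age_max
    return np.clip(age, config.age_min, config.age_max), matured


def simulate_profiles(
    cohort: pd.DataFrame,
    geometry: tuple[pd.DataFrame, pd.DataFrame],
    config: SimulationConfig,
) -> tuple[dict[str, TractProfileSet], GroundTruth]:
    """Simulate per-tract profile matrices plus their analytic ground truth."""
    if len(cohort) == 0:
        raise ValidationError("cohort is empty")
    atlas, endpoint_table = geometry
    tract_ids = sorted(endpoint_table["tract_id"].unique())
    if len(tract_ids) != config.n_tracts:
        raise ShapeError(
            f"geometry has {len(tract_ids)} tracts but config.n_tracts={config.n_tracts}"
        )
    ranks = endpoint_mean_ranks(atlas, endpoint_table)
    n_parcels = len(atlas)
    ages = cohort["age"].to_numpy(float)
    sex = cohort["sex"].to_numpy(float)
    motion = cohort["motion"].to_numpy(float)
    site_spec = {s.label: s for s in config.sites}
    unknown = set(cohort["site"]) - set(site_spec)
    if unknown:
        raise ValidationError(f"cohort sites not in config: {sorted(unknown)}")
    offsets = cohort["site"].map({k: s.offset for k, s in site_spec.items()}).to_numpy(float)
    scales = cohort["site"].map({k: s.noise_scale for k, s in site_spec.items()}).to_numpy(float)

    n_nodes = config.n_nodes
    shape = _u_shape(n_nodes)
    amp = config.amplitude_deep + (config.amplitude_superficial - config.amplitude_deep) * shape
    asym = 0.75 + 0.05 * shape

    def norm_rank(r: float) -> float:
        return (r - 1.0) / max(n_parcels - 1.0, 1.0)

    profiles: dict[str, TractProfileSet] = {}
    truth = GroundTruth({}, {}, {}, {}, {}, ranks, config.criterion)
    half = n_nodes / 2.0
    covar = config.sex_effect * sex + config.motion_effect * motion + offsets
    for tract_id in tract_ids:
        tau_a = config.tau_fast + norm_rank(ranks[(tract_id, "end_A")]) * (
            config.tau_slow - config.tau_fast
        )
        tau_b = config.tau_fast + norm_rank(ranks[(tract_id, "end_B")]) * (
            config.tau_slow - config.tau_fast
        )
        tau_end = np.where(np.arange(n_nodes) < half, tau_a, tau_b)
        tau = config.tau_fast + shape * (tau_end - config.tau_fast)

        decay = np.exp(-(ages[:, None] - config.age_min) / tau[None, :])
        noise = substream(config.seed, f"profiles/{tract_id}").normal(
            size=(len(cohort), n_nodes)
        )
        values = (
            asym[None, :]
            + amp[None, :] * decay
            + covar[:, None]
            + config.noise_sd * scales[:, None] * noise
        )
        ps = TractProfileSet(
            tract_id=tract_id,
            subjects=list(cohort["participant_id"].astype(str)),
            node_ids=np.arange(n_nodes),
            values=values,
            metric_name=config.metric_name,
        )
        profiles[tract_id] = ps
        mat_age, matured = true_maturation_age(amp, tau, config)
        truth.amplitude[tract_id] = amp.copy()
        truth.tau[tract_id] = tau
        truth.asymptote[tract_id] = asym.copy()
        truth.maturation_age[tract_id] = mat_age
        truth.matured[tract_id] = matured
    return profiles, truth


def generate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, TractProfileSet], GroundTruth]:
    """Convenience wrapper: cohort + geometry + profiles + ground truth."""
    cohort = generate_cohort(config)
    atlas, endpoint_table = generate_geometry(config)
    profiles, truth = simulate_profiles(cohort, (atlas, endpoint_table), config)
    return cohort, atlas, endpoint_table, profiles, truth


def write_dataset(outdir: str | Path, config: SimulationConfig) -> dict[str, Path]:
    """Generate a dataset and write it in the formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort, atlas, endpoint_table, profiles, _ = generate_dataset(config)
    paths = {
        "participants": outdir / "participants.tsv",
        "profiles": outdir / "tract_profiles.csv",
        "parcels": outdir / "parcels.csv",
        "endpoints": outdir / "endpoint_probabilities.csv",
        "config": outdir / "simulation_config.yaml",
    }
    write_participants(cohort, paths["participants"])
    write_tract_profiles(profiles.values(), paths["profiles"])
    write_parcel_table(atlas, paths["parcels"])
    write_endpoint_table(endpoint_table, paths["endpoints"])
    config.to_yaml(paths["config"])
    return paths
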