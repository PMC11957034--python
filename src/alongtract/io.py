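"""Tabular input/output for tract-profile analyses.

Canonical on-disk formats (all plain text, stable column order):

* tract profiles — long/tidy CSV with columns ``subjectID, tractID,
  nodeID, <metric>`` (pyAFQ export dialect); wide subject × node
  matrices are an internal representation only.
* participants — TSV/CSV with ``participant_id, age, sex, motion``
  and optional ``site`` (BIDS participants.tsv dialect).
* parcel table — CSV with ``parcel_id, hemisphere, sa_rank, x, y, z``
  where (x, y, z) is a unit-sphere centroid.
* endpoint probabilities — CSV with ``tract_id, end_label, parcel_id,
  probability``.

Node ids are 0-based throughout (nodes of a 100-node profile are
numbered 0–99). Readers reject invalid input rather than imputing;
every writer/reader pair round-trips values bitwise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, ShapeError, ValidationError

PROFILE_COLUMNS = ("subjectID", "tractID", "nodeID")
PARTICIPANT_COLUMNS = ("participant_id", "age", "sex", "motion")
PARCEL_COLUMNS = ("parcel_id", "hemisphere", "sa_rank", "x", "y", "z")
ENDPOINT_COLUMNS = ("tract_id", "end_label", "parcel_id", "probability")
END_LABELS = ("end_A", "end_B")

_SEX_CODES = {
    "0": 0, "1": 1, "m": 0, "f": 1, "male": 0, "female": 1,
}


@dataclass
class TractProfileSet:
    """Subjects × nodes matrix of one microstructure metric for one tract.

    ``node_ids`` keep their original 0-based numbering even after end-node
    trimming; ``n_nodes_original`` records the pre-trim node count so that
    trimming is idempotent.
    """

    tract_id: str
    subjects: list[str]
    node_ids: np.ndarray
    values: np.ndarray
    metric_name: str = "dki_md"
    trimmed: bool = False
    n_nodes_original: int | None = None

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.n_nodes_original is None:
            self.n_nodes_original = int(self.node_ids.max()) + 1 if self.node_ids.size else 0

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        if self.values.shape != (len(self.subjects), len(self.node_ids)):
            raise ShapeError(
                f"tract {self.tract_id}: values shape {self.values.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.node_ids)} nodes"
            )
        if len(set(self.subjects)) != len(self.subjects):
            raise ValidationError(f"tract {self.tract_id}: duplicate subject ids")
        if np.any(~np.isfinite(self.values)):
            raise ValidationError(f"tract {self.tract_id}: non-finite metric values")
        if not self.trimmed and self.node_ids.size:
            expected = np.arange(self.node_ids[0], self.node_ids[0] + self.node_ids.size)
            if not np.array_equal(self.node_ids, expected):
                raise ValidationError(f"tract {self.tract_id}: node ids not contiguous")
        if "md" in self.metric_name.lower() and np.any(self.values <= 0):
            raise ValidationError(
                f"tract {self.tract_id}: mean-diffusivity values must be strictly positive"
            )

    def subset_subjects(self, keep: Sequence[str]) -> "TractProfileSet":
        index = {s: i for i, s in enumerate(self.subjects)}
        rows = [index[s] for s in keep]
        return dataclasses.replace(self, subjects=list(keep), values=self.values[rows])

    def node_index(self, node_ids: Sequence[int]) -> np.ndarray:
        """Positions of the given original node ids in the current matrix."""
        index = {int(n): i for i, n in enumerate(self.node_ids)}
        try:
            return np.array([index[int(n)] for n in node_ids], dtype=int)
        except KeyError as exc:
            raise ValidationError(
                f"tract {self.tract_id}: node {exc.args[0]} not present (trimmed?)"
            ) from None


def read_tract_profiles(path: str | Path, metric: str = "dki_md") -> list[TractProfileSet]:
    """Read a tidy pyAFQ-style profile CSV into one set per tract."""
    path = Path(path)
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in (*PROFILE_COLUMNS, metric) if c not in table.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    dupes = table.duplicated(subset=["subjectID", "tractID", "nodeID"])
    if dupes.any():
        first = table.loc[dupes, ["subjectID", "tractID", "nodeID"]].iloc[0]
        raise FormatError(
            f"{path.name}: duplicate (subject, tract, node) rows, e.g. "
            f"({first.subjectID}, {first.tractID}, {first.nodeID})"
        )
    out: list[TractProfileSet] = []
    for tract_id, sub in table.groupby("tractID", sort=True):
        nodes = np.sort(sub["nodeID"].unique())
        wide = sub.pivot(index="subjectID", columns="nodeID", values=metric)
        wide = wide.reindex(columns=nodes)
        if wide.isna().any().any():
            offenders = [
                f"subject {s} node {int(n)}"
                for s, row in wide.iterrows()
                for n in wide.columns[row.isna()]
            ]
            raise ValidationError(
                f"tract {tract_id}: missing nodes for some subjects: "
                + "; ".join(offenders[:10])
                + ("..." if len(offenders) > 10 else "")
            )
        ps = TractProfileSet(
            tract_id=str(tract_id),
            subjects=[str(s) for s in wide.index],
            node_ids=nodes,
            values=wide.to_numpy(),
            metric_name=metric,
        )
        ps.validate()
        out.append(ps)
    return out


def write_tract_profiles(profiles: Iterable[TractProfileSet], path: str | Path) -> None:
    frames = []
    for ps in profiles:
        long = pd.DataFrame(
            {
                "subjectID": np.repeat(ps.subjects, ps.n_nodes),
                "tractID": ps.tract_id,
                "nodeID": np.tile(ps.node_ids, ps.n_subjects),
                ps.metric_name: ps.values.ravel(),
            }
        )
        frames.append(long)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def trim_end_nodes(profiles: TractProfileSet, n_trim: int = 5) -> TractProfileSet:
    """Drop the ``n_trim`` end-most nodes at each end of the tract.

    Node ids are preserved (not renumbered); trimming by original node id
    makes the operation idempotent for a fixed ``n_trim``.
    """
    if n_trim < 0:
        raise ParameterError(f"n_trim must be >= 0, got {n_trim}")
    n_orig = profiles.n_nodes_original
    if 2 * n_trim >= n_orig:
        raise ParameterError(
            f"n_trim={n_trim} would remove all {n_orig} nodes of tract {profiles.tract_id}"
        )
    if n_trim == 0:
        return dataclasses.replace(profiles)
    keep = (profiles.node_ids >= n_trim) & (profiles.node_ids < n_orig - n_trim)
    return dataclasses.replace(
        profiles,
        node_ids=profiles.node_ids[keep],
        values=profiles.values[:, keep],
        trimmed=True,
    )


def define_endpoints(
    table: pd.DataFrame,
    default_threshold: float = 0.30,
    overrides: Mapping[str, float] | None = None,
) -> dict[tuple[str, str], frozenset]:
    """Threshold endpoint probabilities into per-(tract, end) parcel sets.

    Parcels with termination probability >= the threshold are retained
    (default 30%; per-tract overrides support lower thresholds for hard-to-
    segment tracts such as a 5% rule). Empty endpoint sets are reported via
    a warning, not an error.
    """
    overrides = dict(overrides or {})
    for name, thr in [("default_threshold", default_threshold), *overrides.items()]:
        if not 0 < thr <= 1:
            raise ParameterError(f"threshold {name} must be in (0, 1], got {thr}")
    missing = [c for c in ENDPOINT_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"endpoint table: missing required column(s) {missing}")
    bad = set(table["end_label"]) - set(END_LABELS)
    if bad:
        raise FormatError(f"endpoint table: unknown end labels {sorted(bad)}")
    result: dict[tuple[str, str], frozenset] = {}
    empties = []
    for (tract, end), sub in table.groupby(["tract_id", "end_label"], sort=True):
        thr = overrides.get(str(tract), default_threshold)
        kept = frozenset(sub.loc[sub["probability"] >= thr, "parcel_id"])
        result[(str(tract), str(end))] = kept
        if not kept:
            empties.append((str(tract), str(end)))
    if empties:
        warnings.warn(
            f"empty endpoint sets at threshold: {empties}", UserWarning, stacklevel=2
        )
    return result


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_participants(path: str | Path) -> pd.DataFrame:
    """Read the participant covariate table (cohort table).

    Returns a DataFrame with ``participant_id`` (str), ``age`` (years),
    ``sex`` (0/1), ``motion`` (mean framewise displacement, mm) and
    ``site`` (label; single pseudo-site if absent). Unknown columns are
    preserved as passthrough.
    """
    path = Path(path)
    table = _read_table(path)
    missing = [c for c in PARTICIPANT_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    table = table.copy()
    table["participant_id"] = table["participant_id"].astype(str)
    if table["participant_id"].duplicated().any():
        raise ValidationError(f"{path.name}: duplicate participant ids")

    raw_sex = table["sex"]
    coded = raw_sex.astype(str).str.strip().str.lower().map(_SEX_CODES)
    if coded.isna().any():
        bad = sorted(raw_sex[coded.isna()].astype(str).unique())
        raise FormatError(f"{path.name}: unmappable sex labels {bad}")
    table["sex"] = coded.astype(int)
    table["age"] = table["age"].astype(float)
    table["motion"] = table["motion"].astype(float)
    if table[["age", "motion"]].isna().any().any():
        raise ValidationError(f"{path.name}: missing age/motion values")
    if "site" not in table.columns:
        table["site"] = "site0"
    table["site"] = table["site"].astype(str)
    return table


def write_participants(cohort: pd.DataFrame, path: str | Path) -> None:
    cols = [*PARTICIPANT_COLUMNS, "site"]
    extra = [c for c in cohort.columns if c not in cols]
    cohort[cols + extra].to_csv(path, sep="\t", index=False)


def read_parcel_table(path: str | Path) -> pd.DataFrame:
    """Read the parcel atlas table (id, hemisphere, hierarchy rank, centroid)."""
    path = Path(path)
    table = _read_table(path)
    missing = [c for c in PARCEL_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    table = table.copy()
    bad_hemi = set(table["hemisphere"]) - {"L", "R"}
    if bad_hemi:
        raise ValidationError(f"{path.name}: hemisphere labels must be L/R, got {sorted(bad_hemi)}")
    norms = np.linalg.norm(table[["x", "y", "z"]].to_numpy(float), axis=1)
    off = np.abs(norms - 1.0) > 1e-6
    if off.any():
        bad_ids = table.loc[off, "parcel_id"].tolist()[:5]
        raise ValidationError(f"{path.name}: non-unit centroids for parcels {bad_ids}")
    if table["parcel_id"].duplicated().any():
        raise ValidationError(f"{path.name}: duplicate parcel ids")
    return table


def write_parcel_table(atlas: pd.DataFrame, path: str | Path) -> None:
    extra = [c for c in atlas.columns if c not in PARCEL_COLUMNS]
    atlas[list(PARCEL_COLUMNS) + extra].to_csv(path, index=False)


def read_endpoint_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    table = _read_table(path)
    missing = [c for c in ENDPOINT_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    if ((table["probability"] < 0) | (table["probability"] > 1)).any():
        raise ValidationError(f"{path.name}: probabilities outside [0, 1]")
    per_tract = table.groupby("tract_id")["end_label"].nunique()
    incomplete = per_tract[per_tract != 2]
    if len(incomplete):
        raise ValidationError(
            f"{path.name}: tracts without exactly two end labels: {list(incomplete.index)}"
        )
    return table


def write_endpoint_table(table: pd.DataFrame, path: str | Path) -> None:
    table[list(ENDPOINT_COLUMNS)].to_csv(path, index=False)


def config_hash(payload) -> str:
    """Stable short hash of a JSON-serializable configuration payload."""
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(path: str | Path, record: Mapping) -> None:
    """Write a sidecar provenance log (inputs, config hash, seeds, versions)."""
    import alongtract

    full = {"alongtract_version": alongtract.__version__, **record}
    Path(path).write_text(json.dumps(full, indent=2, sort_keys=True, default=str) + "\n")
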