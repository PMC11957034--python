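"""Mapping superficial tract development onto cortical endpoints.

Developmental measures at the five most superficial retained nodes per
tract end are averaged and assigned to that end's cortical endpoint
parcels. Each endpoint gets a mean hierarchy (S-A) rank — the unweighted
mean of its constituent parcels' ranks — allowing tract development to be
related to the cortical hierarchy: endpoint-level alignment correlations,
per-tract differences between ends in maturation age (ΔAge) versus
hierarchy rank (ΔS-A rank), and parcel-level maps aggregating maturation
ages across all tracts. Significance for all of these is delegated to the
spin-based spatial nulls in :mod:`alongtract.spin`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ContractError, GroupingError, InsufficientDataError
from .io import END_LABELS

SUMMARY_COLUMNS = (
    "tract_id",
    "end_label",
    "parcel_ids",
    "mean_sa_rank",
    "mean_delta_r2",
    "mean_maturation_age",
    "matured",
)


def superficial_node_ids(node_ids: np.ndarray, end_label: str, n_superficial: int = 5) -> np.ndarray:
    """The ``n_superficial`` most-superficial retained node ids for one end.

    End A is the low-id end of the profile, end B the high-id end; with the
    default 5-node trim of a 100-node tract these are nodes 5-9 and 90-94.
    """
    node_ids = np.sort(np.asarray(node_ids))
    if end_label == "end_A":
        return node_ids[:n_superficial]
    if end_label == "end_B":
        return node_ids[-n_superficial:]
    raise ContractError(f"unknown end label {end_label!r}; expected one of {END_LABELS}")


def summarize_endpoints(
    node_results: pd.DataFrame,
    endpoint_sets: Mapping[tuple[str, str], frozenset],
    atlas: pd.DataFrame,
    n_superficial: int = 5,
    probability_weights: Mapping[tuple[str, str, str], float] | None = None,
) -> pd.DataFrame:
    """Average superficial-node developmental measures per (tract, end).

    ``node_results`` is the tidy per-node table (columns ``tract_id, node,
    delta_r2_adj, maturation_age, matured``). Each endpoint's mean S-A rank
    is the unweighted mean of its parcels' ranks unless termination
    probabilities are supplied as weights. The ``matured`` flag is True only
    if every constituent superficial node matured within the age window.
    """
    rank_of = dict(zip(atlas["parcel_id"], atlas["sa_rank"].astype(float)))
    rows = []
    for (tract, end), parcels in sorted(endpoint_sets.items()):
        if not parcels:
            continue
        sub = node_results[node_results["tract_id"] == tract]
        if sub.empty:
            raise ContractError(f"no node results for tract {tract}")
        wanted = superficial_node_ids(sub["node"].to_numpy(), end, n_superficial)
        picked = sub.set_index("node").loc[wanted]
        if picked["delta_r2_adj"].isna().any():
            raise ContractError(f"missing node results for tract {tract} nodes {list(wanted)}")
        parcel_list = sorted(parcels)
        ranks = np.array([rank_of[p] for p in parcel_list], dtype=float)
        if probability_weights is not None:
            w = np.array([probability_weights[(tract, end, p)] for p in parcel_list])
            mean_rank = float(np.average(ranks, weights=w))
        else:
            mean_rank = float(ranks.mean())
        rows.append(
            {
                "tract_id": tract,
                "end_label": end,
                "parcel_ids": tuple(parcel_list),
                "mean_sa_rank": mean_rank,
                "mean_delta_r2": float(picked["delta_r2_adj"].mean()),
                "mean_maturation_age": float(picked["maturation_age"].mean()),
                "matured": bool(picked["matured"].all()),
            }
        )
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))


def sa_alignment(
    summaries: pd.DataFrame, include_unmatured: bool = True
) -> tuple[float, pd.DataFrame]:
    """Pearson correlation of endpoint maturation age with mean S-A rank.

    With ``include_unmatured=False``, ceiling-flagged endpoints (those that
    did not mature within the age window) are excluded before correlating.
    Significance is delegated to the spin-based spatial null.
    """
    table = summaries if include_unmatured else summaries[summaries["matured"]]
    if len(table) < 3:
        raise InsufficientDataError(
            f"need >= 3 endpoints to correlate, have {len(table)}"
        )
    r = scipy.stats.pearsonr(
        table["mean_sa_rank"].to_numpy(float),
        table["mean_maturation_age"].to_numpy(float),
    ).statistic
    return float(r), table.reset_index(drop=True)


def tract_deltas(summaries: pd.DataFrame, sa_split_threshold: float = 100.0) -> pd.DataFrame:
    """Per-tract |ΔAge| and |ΔS-A rank| between the two ends, with grouping."""
    rows = []
    for tract, sub in summaries.groupby("tract_id", sort=True):
        if set(sub["end_label"]) != set(END_LABELS):
            raise ContractError(f"tract {tract}: needs summaries for both ends")
        a = sub[sub["end_label"] == "end_A"].iloc[0]
        b = sub[sub["end_label"] == "end_B"].iloc[0]
        delta_sa = abs(a["mean_sa_rank"] - b["mean_sa_rank"])
        rows.append(
            {
                "tract_id": tract,
                "delta_age": abs(a["mean_maturation_age"] - b["mean_maturation_age"]),
                "delta_sa": delta_sa,
                "group": "large" if delta_sa >= sa_split_threshold else "small",
            }
        )
    return pd.DataFrame(rows)


def delta_analysis(
    summaries: pd.DataFrame, sa_split_threshold: float = 100.0
) -> tuple[pd.DataFrame, float]:
    """One-tailed Welch t contrast of ΔAge between large- and small-ΔS-A tracts.

    Returns the per-tract delta table and the observed t statistic (large >
    small); the spin-based null supplies the p-value.
    """
    deltas = tract_deltas(summaries, sa_split_threshold)
    large = deltas.loc[deltas["group"] == "large", "delta_age"].to_numpy(float)
    small = deltas.loc[deltas["group"] == "small", "delta_age"].to_numpy(float)
    if len(large) < 2 or len(small) < 2:
        raise GroupingError(
            f"need >= 2 tracts per ΔS-A group (have {len(large)} large / {len(small)} "
            f"small at threshold {sa_split_threshold}); adjust sa_split_threshold"
        )
    t = scipy.stats.ttest_ind(large, small, equal_var=False, alternative="greater").statistic
    return deltas, float(t)


def aggregate_maturation_map(
    summaries: pd.DataFrame,
    atlas: pd.DataFrame,
    include_unmatured: bool = True,
) -> pd.DataFrame:
    """Across-tract mean maturation age assigned to each endpoint parcel.

    Every parcel touched by at least one (included) endpoint receives the
    mean of those endpoints' mean maturation ages; parcels with no tract
    termination are flagged absent (age NaN), never zero-filled. A parcel
    serving both ends of one tract contributes both endpoint values.
    """
    table = summaries if include_unmatured else summaries[summaries["matured"]]
    contributions: dict[str, list[float]] = {}
    for _, row in table.iterrows():
        for parcel in row["parcel_ids"]:
            contributions.setdefault(parcel, []).append(row["mean_maturation_age"])
    records = []
    for parcel in atlas["parcel_id"]:
        ages = contributions.get(parcel, [])
        records.append(
            {
                "parcel_id": parcel,
                "mean_age": float(np.mean(ages)) if ages else np.nan,
                "n_contributing": len(ages),
                "absent": not ages,
            }
        )
    return pd.DataFrame(records)
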