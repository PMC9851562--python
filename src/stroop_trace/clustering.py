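"""Partial-error detection by hierarchical clustering of trajectories.

Space-normalized trajectories (100 points) are concatenated into
200-dimensional (x..., y...) vectors and clustered agglomeratively (Ward
linkage on Euclidean distance by default, k = 8). Clusters whose mean path
crosses materially onto the incorrect-response side — minimum mean x below
``-x_threshold`` — are labelled partial-error clusters; every trial assigned
to such a cluster counts as a partial error. Partial-error rates are then the
percentage of kept trials per participant x condition falling in those
clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .conditions import CONDITIONS
from .errors import DataError
from .preprocess import SpaceNormalizedTrajectory
from .trial import RawTrial

DEFAULT_K = 8
DEFAULT_X_THRESHOLD = 0.05


@dataclass
class ClusterModel:
    """Fitted trajectory clustering with partial-error labels."""

    k: int
    linkage_method: str
    distance: str
    keys: list[tuple[str, int]]
    assignments: np.ndarray  # cluster id in 1..k per trajectory
    cluster_mean_paths: np.ndarray  # (k, n_points, 2)
    partial_error_cluster_ids: set[int] = field(default_factory=set)

    def assignment_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": [k[0] for k in self.keys],
                "trial_index": [k[1] for k in self.keys],
                "cluster": self.assignments,
                "is_partial_error": [
                    int(c) in self.partial_error_cluster_ids for c in self.assignments
                ],
            }
        )

    def mean_paths_frame(self) -> pd.DataFrame:
        k, n_points, _ = self.cluster_mean_paths.shape
        return pd.DataFrame(
            {
                "cluster": np.repeat(np.arange(1, k + 1), n_points),
                "point": np.tile(np.arange(1, n_points + 1), k),
                "x": self.cluster_mean_paths[:, :, 0].ravel(),
                "y": self.cluster_mean_paths[:, :, 1].ravel(),
            }
        )


def cluster_trajectories(
    trajectories: Mapping[tuple[str, int], SpaceNormalizedTrajectory],
    k: int = DEFAULT_K,
    linkage_method: str = "ward",
    distance: str = "euclidean",
) -> ClusterModel:
    """Agglomerative clustering of space-normalized trajectories.

    Deterministic given inputs; raises DataError with fewer trajectories
    than clusters.
    """
    keys = list(trajectories)
    if len(keys) < k:
        raise DataError(f"need at least k={k} trajectories, got {len(keys)}")
    lengths = {len(trajectories[key]) for key in keys}
    if len(lengths) != 1:
        raise DataError(f"trajectories must share a length, got {sorted(lengths)}")
    features = np.stack(
        [np.concatenate([trajectories[key].x, trajectories[key].y]) for key in keys]
    )
    z = linkage(features, method=linkage_method, metric=distance)
    assignments = fcluster(z, t=k, criterion="maxclust")
    n_points = lengths.pop()
    means = np.zeros((k, n_points, 2))
    for c in range(1, k + 1):
        members = features[assignments == c]
        if members.size:
            means[c - 1, :, 0] = members[:, :n_points].mean(axis=0)
            means[c - 1, :, 1] = members[:, n_points:].mean(axis=0)
    return ClusterModel(
        k=k,
        linkage_method=linkage_method,
        distance=distance,
        keys=keys,
        assignments=assignments,
        cluster_mean_paths=means,
    )


def label_partial_error_clusters(
    model: ClusterModel, x_threshold: float = DEFAULT_X_THRESHOLD
) -> set[int]:
    """Clusters whose mean path crosses beyond ``-x_threshold`` on x.

    The published analysis identified partial-error clusters by visual
    inspection; this rule makes the call reproducible: a cluster is a
    partial-error cluster iff its mean movement materially enters the
    incorrect-response side. The label set is stored on the model and
    returned. Raising the threshold can only shrink the set.
    """
    ids = {
        c + 1
        for c in range(model.k)
        if float(model.cluster_mean_paths[c, :, 0].min()) < -x_threshold
    }
    model.partial_error_cluster_ids = ids
    return ids


def pe_rates(model: ClusterModel, trials: Sequence[RawTrial]) -> pd.DataFrame:
    """Percentage of kept trials in partial-error clusters per cell.

    Returns a long DataFrame with columns participant_id, condition,
    n_trials, n_partial_errors, pe_rate (percent; NaN for empty cells).
    """
    assigned = dict(zip(model.keys, model.assignments))
    missing = [t.key for t in trials if t.key not in assigned]
    if missing:
        raise DataError(f"trials without cluster assignment: {missing[:5]}")
    pe_ids = model.partial_error_cluster_ids
    df = pd.DataFrame(
        {
            "participant_id": [t.participant_id for t in trials],
            "condition": [t.condition for t in trials],
            "is_pe": [int(assigned[t.key]) in pe_ids for t in trials],
        }
    )
    participants = sorted(df["participant_id"].unique())
    grid = pd.MultiIndex.from_product(
        [participants, CONDITIONS], names=["participant_id", "condition"]
    )
    agg = (
        df.groupby(["participant_id", "condition"])["is_pe"]
        .agg(n_trials="size", n_partial_errors="sum")
        .reindex(grid)
    )
    agg["n_trials"] = agg["n_trials"].fillna(0).astype(int)
    agg["n_partial_errors"] = agg["n_partial_errors"].fillna(0).astype(int)
    agg["pe_rate"] = np.where(
        agg["n_trials"] > 0, 100.0 * agg["n_partial_errors"] / agg["n_trials"].clip(lower=1), np.nan
    )
    return agg.reset_index()
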