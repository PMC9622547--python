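"""Intact vs impaired goal-directed action subgrouping.

Subjects are classified by agglomerative hierarchical clustering (Ward's
method on squared Euclidean distance) of two z-scored devaluation features:
the preference ratio (response bias toward the valued action) and the
valued-action response rate.  The two-cluster cut is labelled by mean bias
— the higher-bias cluster is "intact" — and the empirical boundary is the
interval between the maximum impaired-cluster bias and the minimum
intact-cluster bias.

z-scores use the sample standard deviation (ddof=1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = ["ClusterResult", "zscore_features", "ward_cluster", "classify_goal_directed"]


def zscore_features(matrix: np.ndarray) -> np.ndarray:
    """Column-wise z-scores with sample sd (ddof=1); rejects zero-variance
    columns rather than silently producing NaNs."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 subjects")
    sd = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance feature column(s): {bad.tolist()}")
    return (X - X.mean(axis=0)) / sd


def ward_cluster(features: np.ndarray, k: int = 2) -> np.ndarray:
    """Ward-linkage agglomerative clustering cut at k clusters.

    Ward's objective is the increase in within-cluster sum of squared
    Euclidean distances; scipy's implementation breaks merge ties by lowest
    cluster index, so the result is deterministic for a given row order.
    Returns integer labels 0..k-1 in order of first appearance.
    """
    X = np.asarray(features, dtype=float)
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} observations, got {X.shape[0]}")
    Z = linkage(X, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # relabel to 0..k-1 by first appearance for order-stability of the API
    mapping: dict[int, int] = {}
    labels = np.empty(len(raw), dtype=int)
    for i, r in enumerate(raw):
        labels[i] = mapping.setdefault(r, len(mapping))
    return labels


@dataclass
class ClusterResult:
    labels: pd.DataFrame  # subject_id, group, bias, valued_rate, cluster_label
    boundary_low: float  # max bias in the impaired cluster
    boundary_high: float  # min bias in the intact cluster
    linkage_matrix: np.ndarray
    features_z: np.ndarray
    excluded: list[str] = field(default_factory=list)  # undefined-bias subjects

    @property
    def n_intact(self) -> int:
        return int((self.labels["cluster_label"] == "intact").sum())

    @property
    def n_impaired(self) -> int:
        return int((self.labels["cluster_label"] == "impaired").sum())


def classify_goal_directed(metrics: pd.DataFrame) -> ClusterResult:
    """Cluster a cohort's devaluation metrics into intact/impaired.

    ``metrics`` needs columns ``subject_id``, ``preference_ratio`` and
    ``valued_rate`` (a ``group`` column is carried through if present).
    Subjects with undefined bias (no responses) are excluded and listed.
    The whole cohort is pooled — groups are not clustered separately.
    """
    required = {"subject_id", "preference_ratio", "valued_rate"}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table missing column(s): {sorted(missing)}")
    df = metrics.copy()
    excluded = df.loc[df["preference_ratio"].isna(), "subject_id"].astype(str).tolist()
    df = df.dropna(subset=["preference_ratio", "valued_rate"]).reset_index(drop=True)
    if len(df) < 2:
        raise ValueError("need at least 2 subjects with defined bias")
    X = df[["preference_ratio", "valued_rate"]].to_numpy(dtype=float)
    Xz = zscore_features(X)
    Z = linkage(Xz, method="ward")
    raw = fcluster(Z, t=2, criterion="maxclust")
    bias = df["preference_ratio"].to_numpy(dtype=float)
    mean1 = bias[raw == 1].mean()
    mean2 = bias[raw == 2].mean()
    if mean1 == mean2:
        raise ValueError("degenerate cohort: clusters have identical mean bias")
    intact_raw = 1 if mean1 > mean2 else 2
    labels = np.where(raw == intact_raw, "intact", "impaired")
    out = pd.DataFrame(
        {
            "subject_id": df["subject_id"].astype(str),
            "group": df["group"] if "group" in df.columns else "",
            "preference_ratio": bias,
            "valued_rate": df["valued_rate"].to_numpy(dtype=float),
            "cluster_label": labels,
        }
    )
    return ClusterResult(
        labels=out,
        boundary_low=float(bias[labels == "impaired"].max()),
        boundary_high=float(bias[labels == "intact"].min()),
        linkage_matrix=Z,
        features_z=Xz,
        excluded=excluded,
    )
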