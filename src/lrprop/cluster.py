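"""Module discovery: hierarchical co-clustering on a proportionality distance.

The workflow mirrors unsupervised co-expression analysis: turn the symmetric
metric matrix into a distance (``1 - |rho|``, or ``phi_s`` used directly),
cluster it agglomeratively, cut the dendrogram, and call two features
*co-clustered* when they land in the same branch.  Clusters are then ranked
by how loudly their highly proportional pairs vary — a differentially
expressed module is expected to combine a low log-ratio variance (tight
proportionality) with a high sum of individual feature variances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .metrics import ProportionalityResult

__all__ = ["ClusterAssignment", "proportionality_distance", "cocluster",
           "label_pairs", "prioritize_coclusters"]


@dataclass(frozen=True)
class ClusterAssignment:
    """A partition of features into 1-based, size-ordered clusters.

    Cluster 1 is always the largest cluster (ties broken by the lowest
    participating feature index), so narrative references to "co-cluster 1"
    are reproducible.
    """

    labels: dict  # feature_id -> cluster index (1-based, contiguous)
    linkage: str
    cut: dict  # {"k": int} or {"height": float}
    distance: str  # description of the distance used

    @property
    def feature_ids(self) -> tuple:
        return tuple(self.labels)

    @property
    def n_clusters(self) -> int:
        return max(self.labels.values())

    def members(self, cluster: int) -> list:
        return [f for f, c in self.labels.items() if c == cluster]

    def same_cluster(self, a, b) -> Optional[int]:
        """The shared cluster index of two features, or None."""
        ca, cb = self.labels.get(str(a)), self.labels.get(str(b))
        return ca if ca is not None and ca == cb else None


def proportionality_distance(result: ProportionalityResult) -> pd.DataFrame:
    """Distance matrix for co-clustering: ``1 - |rho|``, or ``phi_s`` directly.

    Under the modulus, perfectly anti-proportional pairs (rho = -1) sit at
    distance zero and co-cluster with proportional ones.  The asymmetric phi
    is not a distance and is rejected.
    """
    if result.metric == "rho":
        d = 1.0 - np.abs(result.matrix.to_numpy())
    elif result.metric == "phi_s":
        d = result.matrix.to_numpy().copy()
    else:
        raise ValueError(
            f"metric {result.metric!r} is asymmetric and cannot serve as a distance; "
            "use rho or phi_s"
        )
    if np.isnan(d).any():
        # degenerate phi_s pairs: maximally distant rather than silently close
        d = np.where(np.isnan(d), np.nanmax(d) if np.isfinite(np.nanmax(d)) else 1.0, d)
    d = (d + d.T) / 2.0  # enforce exact symmetry against float asymmetry
    np.clip(d, 0.0, None, out=d)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=result.matrix.index, columns=result.matrix.columns)


def _relabel_by_size(raw: np.ndarray) -> np.ndarray:
    """Map arbitrary cluster codes to 1..k in decreasing size order.

    Ties in size are broken by the lowest member feature index, so the
    relabelling is deterministic under feature permutation of the input.
    """
    codes = np.unique(raw)
    order = sorted(
        codes, key=lambda c: (-int((raw == c).sum()), int(np.flatnonzero(raw == c)[0]))
    )
    mapping = {c: i + 1 for i, c in enumerate(order)}
    return np.array([mapping[c] for c in raw])


def cocluster(
    distance: pd.DataFrame,
    linkage: str = "complete",
    k: Optional[int] = None,
    height: Optional[float] = None,
) -> ClusterAssignment:
    """Agglomerative clustering of a feature distance matrix, dendrogram cut.

    Exactly one of ``k`` (number of clusters) or ``height`` (cut level) must
    be given.  The result is deterministic for a given input; see
    :class:`ClusterAssignment` for the index convention.
    """
    if (k is None) == (height is None):
        raise ValueError("specify exactly one of k or height")
    m = distance.shape[0]
    if k is not None and not (1 <= k <= m):
        raise ValueError(f"k must be between 1 and {m}, got {k}")
    d = distance.to_numpy()
    condensed = squareform((d + d.T) / 2.0, checks=False)
    tree = scipy_linkage(condensed, method=linkage)
    if k is not None:
        raw = fcluster(tree, t=k, criterion="maxclust")
        cut = {"k": int(k)}
    else:
        raw = fcluster(tree, t=height, criterion="distance")
        cut = {"height": float(height)}
    labels = _relabel_by_size(raw)
    return ClusterAssignment(
        labels=dict(zip(map(str, distance.columns), map(int, labels))),
        linkage=linkage,
        cut=cut,
        distance="1-|rho|",
    )


def label_pairs(pairs: pd.DataFrame, clusters: ClusterAssignment) -> pd.DataFrame:
    """Attach cluster labels to a pair table.

    ``cluster_i`` / ``cluster_j`` get each feature's cluster; an added
    ``cocluster`` column holds the shared cluster index when both features
    agree and 0 when the pair spans clusters (the "unco-clustered" colour
    code).
    """
    out = pairs.copy()
    ci = [clusters.labels.get(str(f), pd.NA) for f in out["feature_i"]]
    cj = [clusters.labels.get(str(f), pd.NA) for f in out["feature_j"]]
    out["cluster_i"] = pd.array(ci, dtype="Int64")
    out["cluster_j"] = pd.array(cj, dtype="Int64")
    out["cocluster"] = [
        a if (a is not pd.NA and a == b) else 0 for a, b in zip(ci, cj)
    ]
    out["cocluster"] = out["cocluster"].astype(int)
    return out


def prioritize_coclusters(
    pairs: pd.DataFrame, clusters: ClusterAssignment
) -> pd.DataFrame:
    """Rank co-clusters as candidate differentially expressed modules.

    Restricted to the (highly proportional) pairs in the table whose two
    features share a cluster, reports per cluster the pair count and median
    VLR / VLS, ranked by median VLS descending: among tightly proportional
    pairs, the module whose member features vary most across samples is the
    best candidate for condition-driven expression change.
    """
    labelled = label_pairs(pairs, clusters)
    within = labelled[labelled["cocluster"] > 0]
    if within.empty:
        return pd.DataFrame(
            columns=["cluster", "n_pairs", "median_vlr", "median_vls", "rank"]
        )
    summary = (
        within.groupby("cocluster")
        .agg(n_pairs=("metric_value", "size"),
             median_vlr=("vlr", "median"),
             median_vls=("vls", "median"))
        .reset_index()
        .rename(columns={"cocluster": "cluster"})
    )
    summary = summary.sort_values(
        ["median_vls", "cluster"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    summary["rank"] = np.arange(1, len(summary) + 1)
    return summary
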