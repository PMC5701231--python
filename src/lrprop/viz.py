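"""Figure data preparation and rendering for proportionality analysis.

Four views of a fitted result are supported, mirroring the standard workflow:

* **smear** — log-ratio abundances of every highly proportional pair
  overplotted; truly proportional pairs trace straight lines parallel to
  ``y = x``.
* **prism** — every pair among the participating features scattered across
  the two variance axes VLR (tightness of proportionality) and VLS (how
  loudly the two features vary), coloured by co-cluster.
* **lr_pca** — samples projected on the first two principal components of
  the log-ratio data, a compositionally valid ordination.
* **network** — the highly proportional pairs within one co-cluster as a
  graph, nodes optionally coloured by an external differential-expression
  direction.

Each ``*_data`` function is pure and returns a plain table (or graph); the
``plot_*`` / :func:`render` layer is the only place with matplotlib side
effects, and nothing here is ever pixel-tested.
"""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from .cluster import ClusterAssignment, label_pairs
from .metrics import feature_variances
from .transforms import LogRatioMatrix

__all__ = [
    "smear_data",
    "prism_data",
    "lr_pca",
    "build_network",
    "export_network",
    "plot_smear",
    "plot_prism",
    "plot_pca",
    "plot_network",
    "render",
]


def smear_data(A: LogRatioMatrix, pairs: pd.DataFrame) -> pd.DataFrame:
    """Coordinates for the smear plot: one row per (pair, sample).

    Columns: ``pair`` (running index into the pair table), ``feature_i``,
    ``feature_j``, ``sample``, ``x`` (= A_i), ``y`` (= A_j).  For an exactly
    proportional pair the N points fall on a slope-1 line offset by the log
    proportionality constant.
    """
    known = set(A.feature_ids)
    frames = []
    for idx, row in pairs.reset_index(drop=True).iterrows():
        fi, fj = str(row["feature_i"]), str(row["feature_j"])
        missing = {fi, fj} - known
        if missing:
            raise KeyError(f"pair references unknown feature(s): {sorted(missing)}")
        frames.append(
            pd.DataFrame(
                {
                    "pair": idx,
                    "feature_i": fi,
                    "feature_j": fj,
                    "sample": list(A.sample_ids),
                    "x": A.column(fi),
                    "y": A.column(fj),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["pair", "feature_i", "feature_j", "sample", "x", "y"])
    return pd.concat(frames, ignore_index=True)


def prism_data(
    pairs: pd.DataFrame, clusters: ClusterAssignment, A: LogRatioMatrix
) -> pd.DataFrame:
    """Per-pair (VLR, VLS, co-cluster) table for the prism plot.

    The pair universe is *expanded*: starting from the features that
    participate in at least one passing pair, every pair among them is
    included — not only the passing ones — so the plot shows where the
    highly proportional pairs sit against their full neighbourhood.
    Pairs spanning two clusters carry co-cluster label 0.
    """
    participants = sorted(
        set(map(str, pairs["feature_i"])) | set(map(str, pairs["feature_j"])),
        key=list(A.feature_ids).index,
    )
    if not participants:
        return pd.DataFrame(columns=["feature_i", "feature_j", "vlr", "vls", "cocluster"])
    sub = A.select_features(participants)
    from .metrics import vlr_matrix  # local import to avoid a cycle at module load

    vlr = vlr_matrix(sub)
    v = feature_variances(sub)
    iu, ju = np.triu_indices(len(participants), k=1)
    table = pd.DataFrame(
        {
            "feature_i": [participants[i] for i in iu],
            "feature_j": [participants[j] for j in ju],
            "vlr": vlr[iu, ju],
            "vls": v[iu] + v[ju],
        }
    )
    labelled = label_pairs(table, clusters)
    table["cocluster"] = labelled["cocluster"]
    return table


def lr_pca(
    A: LogRatioMatrix,
    groups=None,
    features=None,
    n_components: int = 2,
):
    """PCA of the (column-centred, unscaled) log-ratio matrix.

    Returns ``(scores, explained)``: an N x 2 DataFrame of sample scores and
    the per-component fraction of variance explained (all components, summing
    to 1).  Columns are centred but not rescaled — clr values already share a
    log scale.  The sign of each component is fixed so its largest-magnitude
    loading is positive, making scores reproducible across BLAS builds.

    ``features`` optionally restricts the decomposition to a subset (e.g. one
    co-cluster); ``groups`` is carried through to the ``group`` column for
    plotting.
    """
    if A.n_samples < 3:
        raise ValueError("PCA needs at least 3 samples")
    sub = A.select_features(features) if features is not None else A
    x = sub.values - sub.values.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for comp in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[comp]))
        if vt[comp, pivot] < 0:
            vt[comp] *= -1.0
            u[:, comp] *= -1.0
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else var
    scores = u[:, :n_components] * s[:n_components]
    out = pd.DataFrame(
        scores,
        index=list(sub.sample_ids),
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    if groups is not None:
        out["group"] = list(groups)
    return out, explained


def build_network(
    pairs: pd.DataFrame,
    clusters: ClusterAssignment,
    cluster_id: int,
    annotations: Optional[pd.DataFrame] = None,
) -> nx.Graph:
    """Graph of the passing pairs whose two features share ``cluster_id``.

    Node attribute ``direction`` comes from the annotation table
    (``increased`` / ``decreased`` / ``none``, defaulting to ``none``); edges
    carry the pair's metric value.
    """
    if cluster_id not in set(clusters.labels.values()):
        raise ValueError(f"cluster {cluster_id} does not exist")
    direction = {}
    if annotations is not None:
        direction = dict(zip(annotations["feature_id"].astype(str), annotations["direction"]))
    labelled = label_pairs(pairs, clusters)
    graph = nx.Graph()
    for _, row in labelled[labelled["cocluster"] == cluster_id].iterrows():
        fi, fj = str(row["feature_i"]), str(row["feature_j"])
        for f in (fi, fj):
            if f not in graph:
                graph.add_node(f, direction=direction.get(f, "none"))
        graph.add_edge(fi, fj, metric_value=float(row["metric_value"]))
    return graph


def export_network(
    pairs: pd.DataFrame,
    clusters: ClusterAssignment,
    cluster_id: int,
    path,
    annotations: Optional[pd.DataFrame] = None,
    format: str = "edge_list_tsv",
) -> nx.Graph:
    """Write the co-cluster graph for external viewers; returns the graph.

    ``edge_list_tsv`` is a three-column table (feature_i, feature_j,
    metric_value) plus a companion ``<path>.nodes.tsv`` with node directions;
    ``graphml`` is a single self-contained file round-trippable by generic
    graph tools.
    """
    graph = build_network(pairs, clusters, cluster_id, annotations)
    if format == "edge_list_tsv":
        pd.DataFrame(
            [
                {"feature_i": a, "feature_j": b, "metric_value": d["metric_value"]}
                for a, b, d in graph.edges(data=True)
            ],
            columns=["feature_i", "feature_j", "metric_value"],
        ).to_csv(path, sep="\t", index=False)
        pd.DataFrame(
            [{"feature_id": n, "direction": d["direction"]} for n, d in graph.nodes(data=True)],
            columns=["feature_id", "direction"],
        ).to_csv(f"{path}.nodes.tsv", sep="\t", index=False)
    elif format == "graphml":
        nx.write_graphml(graph, path)
    else:
        raise ValueError(f"unknown format {format!r}; use edge_list_tsv or graphml")
    return graph


# ---------------------------------------------------------------------------
# rendering

def plot_smear(data: pd.DataFrame, ax=None):
    ax = ax or plt.figure(figsize=(6, 6)).add_subplot()
    for _, grp in data.groupby("pair"):
        ax.plot(grp["x"], grp["y"], "-o", ms=2, lw=0.5, alpha=0.5)
    if len(data):
        lo = min(data["x"].min(), data["y"].min())
        hi = max(data["x"].max(), data["y"].max())
        ax.plot([lo, hi], [lo, hi], "k--", lw=1, label="y = x")
        ax.legend()
    ax.set_xlabel("log-ratio abundance, feature i")
    ax.set_ylabel("log-ratio abundance, feature j")
    ax.set_title("Highly proportional pairs")
    return ax


def plot_prism(data: pd.DataFrame, ax=None):
    ax = ax or plt.figure(figsize=(6, 5)).add_subplot()
    if len(data):
        scatter = ax.scatter(
            data["vlr"], data["vls"], c=data["cocluster"], cmap="tab10", s=12
        )
        ax.figure.colorbar(scatter, ax=ax, label="co-cluster (0 = spanning)")
    ax.set_xlabel("VLR  var(A_i − A_j)")
    ax.set_ylabel("VLS  var(A_i) + var(A_j)")
    ax.set_title("Pair variance prism")
    return ax


def plot_pca(scores: pd.DataFrame, explained, ax=None):
    ax = ax or plt.figure(figsize=(6, 5)).add_subplot()
    if "group" in scores.columns:
        for name, grp in scores.groupby("group"):
            ax.scatter(grp["PC1"], grp["PC2"], label=str(name), s=25)
        ax.legend(title="group")
    else:
        ax.scatter(scores["PC1"], scores["PC2"], s=25)
    ax.set_xlabel(f"PC1 ({100 * explained[0]:.1f}% of variance)")
    ax.set_ylabel(f"PC2 ({100 * explained[1]:.1f}% of variance)")
    ax.set_title("Log-ratio PCA")
    return ax


_NODE_COLOURS = {"increased": "tab:red", "decreased": "tab:blue", "none": "white"}


def plot_network(graph: nx.Graph, ax=None, seed: int = 0):
    """2D force-directed convenience rendering; layout is presentation only."""
    ax = ax or plt.figure(figsize=(6, 6)).add_subplot()
    if graph.number_of_nodes():
        pos = nx.spring_layout(graph, seed=seed)
        colours = [_NODE_COLOURS[d.get("direction", "none")] for _, d in graph.nodes(data=True)]
        nx.draw_networkx(graph, pos=pos, ax=ax, node_color=colours, edgecolors="black",
                         node_size=120, font_size=6)
    ax.set_axis_off()
    return ax


def render(ax, path, format: Optional[str] = None) -> None:
    """Save a prepared axes to ``path`` (png / svg / pdf by extension)."""
    fig = ax.figure
    fig.tight_layout()
    fig.savefig(path, format=format)
    plt.close(fig)
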