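"""Node-level graph measures and per-subject feature assembly.

Seven measures are computed for every node of the thresholded connectivity
graph: degree centrality, betweenness centrality, average path length,
clustering coefficient, cost, local efficiency and global efficiency.  A
subject's feature vector concatenates the measures of all atlas ROIs, all
network nodes, and one global aggregate per measure (the mean over the
network nodes), giving (n_roi + n_net + 1) * 7 named features — 1155 for
the standard configuration of 132 atlas regions and 32 network nodes.

Conventions for disconnected graphs keep every quantity finite: the average
path length from a node ignores unreachable nodes (0 if it is isolated) and
efficiencies count unreachable pairs as contributing 0 (1/infinity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .connectivity import BrainGraph

__all__ = [
    "MEASURES",
    "AtlasConfig",
    "FeatureTable",
    "default_atlas",
    "degree_centrality",
    "betweenness_centrality",
    "average_path_length",
    "clustering_coefficient",
    "cost",
    "local_efficiency",
    "global_efficiency",
    "compute_measure_set",
    "assemble_features",
    "extract_feature_table",
]

#: Canonical measure order used everywhere (tables, feature names).
MEASURES = (
    "degree_centrality",
    "betweenness_centrality",
    "average_path_length",
    "clustering_coefficient",
    "cost",
    "local_efficiency",
    "global_efficiency",
)

GLOBAL_LABEL = "GLOBAL"
FEATURE_SEP = "::"

# The eight canonical resting-state networks and their 32 nodes, as used in
# standard connectivity toolboxes.
_DEFAULT_NETWORKS: dict[str, tuple[str, ...]] = {
    "DefaultMode": ("DefaultMode.MPFC", "DefaultMode.LP_L", "DefaultMode.LP_R", "DefaultMode.PCC"),
    "SensoriMotor": ("SensoriMotor.Lateral_L", "SensoriMotor.Lateral_R", "SensoriMotor.Superior"),
    "Visual": ("Visual.Medial", "Visual.Occipital", "Visual.Lateral_L", "Visual.Lateral_R"),
    "Salience": (
        "Salience.ACC",
        "Salience.AInsula_L",
        "Salience.AInsula_R",
        "Salience.RPFC_L",
        "Salience.RPFC_R",
        "Salience.SMG_L",
        "Salience.SMG_R",
    ),
    "DorsalAttention": (
        "DorsalAttention.FEF_L",
        "DorsalAttention.FEF_R",
        "DorsalAttention.IPS_L",
        "DorsalAttention.IPS_R",
    ),
    "FrontoParietal": (
        "FrontoParietal.LPFC_L",
        "FrontoParietal.LPFC_R",
        "FrontoParietal.PPC_L",
        "FrontoParietal.PPC_R",
    ),
    "Language": ("Language.IFG_L", "Language.IFG_R", "Language.pSTG_L", "Language.pSTG_R"),
    "Cerebellar": ("Cerebellar.Anterior", "Cerebellar.Posterior"),
}


@dataclass
class AtlasConfig:
    """Which nodes enter the feature vector, and in what roles.

    ``atlas_roi_labels`` are the anatomical parcellation regions (132 in the
    standard setup); ``networks`` maps each named resting-state network to
    its node labels (8 networks, 32 nodes).  ``include_global`` appends one
    aggregate value per measure.  ``global_over`` chooses whether that
    aggregate averages the network nodes (default) or all nodes.
    """

    atlas_roi_labels: Sequence[str]
    networks: Mapping[str, Sequence[str]] = field(default_factory=dict)
    include_global: bool = True
    global_over: str = "network"  # "network" | "all"

    def __post_init__(self) -> None:
        self.atlas_roi_labels = list(self.atlas_roi_labels)
        self.networks = {k: list(v) for k, v in self.networks.items()}
        net_nodes = self.network_node_labels
        all_labels = self.atlas_roi_labels + net_nodes
        if len(set(all_labels)) != len(all_labels):
            raise ValueError("atlas and network labels must be disjoint and unique")
        if self.global_over not in ("network", "all"):
            raise ValueError("global_over must be 'network' or 'all'")
        if self.include_global and self.global_over == "network" and not net_nodes:
            raise ValueError("global aggregate over network nodes requires network nodes")

    @property
    def network_node_labels(self) -> list[str]:
        return [lab for nodes in self.networks.values() for lab in nodes]

    @property
    def all_labels(self) -> list[str]:
        return self.atlas_roi_labels + self.network_node_labels

    @property
    def n_features(self) -> int:
        n_nodes = len(self.atlas_roi_labels) + len(self.network_node_labels)
        return (n_nodes + int(self.include_global)) * len(MEASURES)

    def feature_names(self) -> list[str]:
        names = [f"{lab}{FEATURE_SEP}{m}" for lab in self.all_labels for m in MEASURES]
        if self.include_global:
            names += [f"{GLOBAL_LABEL}{FEATURE_SEP}{m}" for m in MEASURES]
        return names


def default_atlas() -> AtlasConfig:
    """Standard configuration: 132 parcellation ROIs + 8 networks (32 nodes) + global."""
    rois = [f"ROI_{i:03d}" for i in range(1, 133)]
    return AtlasConfig(atlas_roi_labels=rois, networks=_DEFAULT_NETWORKS, include_global=True)


# ---------------------------------------------------------------------------
# measures


def _node_index(g: BrainGraph, v: str) -> int:
    try:
        return g.roi_labels.index(v)
    except ValueError:
        raise KeyError(f"node {v!r} not in graph") from None


def _distances(a: np.ndarray) -> np.ndarray:
    if a.shape[0] == 0:
        return np.zeros((0, 0))
    return shortest_path(a.astype(float), method="D", unweighted=True)


def degree_centrality(g: BrainGraph, v: str) -> int:
    """Number of edges incident to ``v``."""
    return int(g.adjacency[_node_index(g, v)].sum())


def betweenness_centrality(g: BrainGraph, v: str) -> float:
    """Fraction of shortest paths between other node pairs passing through ``v``.

    Normalized by the (N-1)(N-2)/2 pairs not involving ``v``; pairs with no
    connecting path contribute 0.  Defined as 0 for graphs with N < 3.
    """
    _node_index(g, v)
    if g.n_nodes < 3:
        return 0.0
    return _betweenness_all(g)[_node_index(g, v)]


def _betweenness_all(g: BrainGraph) -> np.ndarray:
    gx = nx.from_numpy_array(g.adjacency)
    bc = nx.betweenness_centrality(gx, normalized=g.n_nodes >= 3)
    return np.array([bc[i] for i in range(g.n_nodes)])


def average_path_length(g: BrainGraph, v: str) -> float:
    """Mean shortest-path length from ``v`` to the nodes reachable from it."""
    i = _node_index(g, v)
    d = _distances(g.adjacency)[i]
    mask = np.isfinite(d)
    mask[i] = False
    if not mask.any():
        return 0.0
    return float(d[mask].mean())


def clustering_coefficient(g: BrainGraph, v: str) -> float:
    """Fraction of pairs of neighbours of ``v`` that are themselves connected."""
    i = _node_index(g, v)
    nbrs = np.flatnonzero(g.adjacency[i])
    k = nbrs.size
    if k < 2:
        return 0.0
    sub = g.adjacency[np.ix_(nbrs, nbrs)]
    return float(sub.sum() / (k * (k - 1)))


def cost(g: BrainGraph, v: str) -> float:
    """Node-level edge density: deg(v) / (N - 1)."""
    i = _node_index(g, v)
    if g.n_nodes < 2:
        raise ValueError("cost requires at least 2 nodes")
    return float(g.adjacency[i].sum() / (g.n_nodes - 1))


def global_efficiency(g: BrainGraph, v: str) -> float:
    """Mean inverse shortest-path length from ``v`` to every other node."""
    i = _node_index(g, v)
    if g.n_nodes < 2:
        return 0.0
    d = _distances(g.adjacency)[i]
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    inv[i] = 0.0
    return float(inv.sum() / (g.n_nodes - 1))


def local_efficiency(g: BrainGraph, v: str) -> float:
    """Efficiency of the subgraph induced on the neighbours of ``v``.

    This is the mean inverse shortest-path distance over pairs of
    neighbours, computed within the neighbour subgraph; 0 when ``v`` has
    fewer than two neighbours.
    """
    i = _node_index(g, v)
    nbrs = np.flatnonzero(g.adjacency[i])
    k = nbrs.size
    if k < 2:
        return 0.0
    sub = g.adjacency[np.ix_(nbrs, nbrs)]
    d = _distances(sub)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (k * (k - 1)))


def compute_measure_set(g: BrainGraph) -> pd.DataFrame:
    """All seven measures for every node, as a node x measure DataFrame.

    Vectorized over a single all-pairs shortest-path computation; agrees
    exactly with the single-node operations above.
    """
    a = g.adjacency.astype(float)
    n = g.n_nodes
    deg = a.sum(axis=1)
    d = _distances(a)

    finite = np.isfinite(d)
    np.fill_diagonal(finite, False)
    reach_counts = finite.sum(axis=1)
    d_finite = np.where(finite, d, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        apl = np.where(reach_counts > 0, d_finite.sum(axis=1) / np.maximum(reach_counts, 1), 0.0)

    with np.errstate(divide="ignore"):
        inv = np.where(finite, 1.0 / np.where(finite, d, 1.0), 0.0)
    geff = inv.sum(axis=1) / max(n - 1, 1)

    tri = np.diag(a @ a @ a)
    denom = deg * (deg - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = np.where(denom > 0, tri / np.where(denom > 0, denom, 1), 0.0)

    leff = np.array([local_efficiency(g, lab) for lab in g.roi_labels])
    bc = _betweenness_all(g)

    if n < 2:
        raise ValueError("graph must have at least 2 nodes")
    data = {
        "degree_centrality": deg,
        "betweenness_centrality": bc,
        "average_path_length": apl,
        "clustering_coefficient": cc,
        "cost": deg / (n - 1),
        "local_efficiency": leff,
        "global_efficiency": geff,
    }
    return pd.DataFrame(data, index=list(g.roi_labels), columns=list(MEASURES))


# ---------------------------------------------------------------------------
# feature assembly


@dataclass
class FeatureTable:
    """Subjects x features matrix with structured names and binary labels."""

    data: np.ndarray
    feature_names: Sequence[str]
    labels: np.ndarray
    subject_ids: Sequence[str] | None = None
    group_names: tuple[str, str] = ("group0", "group1")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.feature_names = list(self.feature_names)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (subjects x features)")
        n, f = self.data.shape
        if len(self.feature_names) != f:
            raise ValueError("feature_names length must match data width")
        if self.labels.shape != (n,):
            raise ValueError("labels length must match number of subjects")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")
        if not (np.any(self.labels == 0) and np.any(self.labels == 1)):
            raise ValueError("both groups must be non-empty")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("feature values must be finite")
        if self.subject_ids is None:
            self.subject_ids = [f"sub-{i + 1:03d}" for i in range(n)]
        else:
            self.subject_ids = list(self.subject_ids)
            if len(self.subject_ids) != n:
                raise ValueError("subject_ids length must match number of subjects")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=list(self.feature_names))
        df.insert(0, "group", [self.group_names[l] for l in self.labels])
        df.insert(0, "subject_id", list(self.subject_ids))
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, group_names: tuple[str, str] | None = None) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t")
        if "subject_id" not in df.columns or "group" not in df.columns:
            raise ValueError("feature table needs 'subject_id' and 'group' columns")
        groups = list(dict.fromkeys(df["group"]))
        if group_names is None:
            if len(groups) != 2:
                raise ValueError(f"expected exactly two groups, found {groups}")
            group_names = (groups[0], groups[1])
        labels = df["group"].map({group_names[0]: 0, group_names[1]: 1})
        if labels.isna().any():
            raise ValueError("group column contains values outside group_names")
        feats = [c for c in df.columns if c not in ("subject_id", "group")]
        return cls(
            data=df[feats].to_numpy(float),
            feature_names=feats,
            labels=labels.to_numpy(int),
            subject_ids=list(df["subject_id"].astype(str)),
            group_names=group_names,
        )


def assemble_features(
    roi_measures: pd.DataFrame,
    network_measures: pd.DataFrame,
    atlas: AtlasConfig,
) -> tuple[np.ndarray, list[str]]:
    """Concatenate node measures into one ordered, named feature row.

    Order: atlas-ROI measures, then network-node measures, then (if
    configured) one global value per measure, the mean over the network
    nodes (or over all nodes when ``atlas.global_over == 'all'``).
    """
    missing = [lab for lab in atlas.atlas_roi_labels if lab not in roi_measures.index]
    missing += [lab for lab in atlas.network_node_labels if lab not in network_measures.index]
    if missing:
        raise KeyError(f"measure sets missing nodes: {missing}")

    roi_block = roi_measures.loc[atlas.atlas_roi_labels, list(MEASURES)].to_numpy(float)
    net_labels = atlas.network_node_labels
    net_block = (
        network_measures.loc[net_labels, list(MEASURES)].to_numpy(float)
        if net_labels
        else np.zeros((0, len(MEASURES)))
    )
    parts = [roi_block.ravel(), net_block.ravel()]
    if atlas.include_global:
        if atlas.global_over == "network":
            glob = net_block.mean(axis=0)
        else:
            glob = np.vstack([roi_block, net_block]).mean(axis=0)
        parts.append(glob)
    values = np.concatenate(parts)
    names = atlas.feature_names()
    assert values.size == len(names) == atlas.n_features
    return values, names


def extract_feature_table(
    cohort,  # sequence of RoiTimeSeries covering all atlas labels
    labels,
    atlas: AtlasConfig,
    spec,
    band: tuple[float, float] | None = (0.01, 0.1),
    group_names: tuple[str, str] = ("group0", "group1"),
) -> FeatureTable:
    """Full extraction pipeline: time series -> graph -> feature table.

    One graph is built per subject over the union of atlas ROIs and network
    nodes from a single connectivity matrix; network-node measures are read
    from that same graph.
    """
    from .connectivity import bandpass_filter, fisher_z, roi_correlation, threshold_adjacency

    all_labels = atlas.all_labels
    rows = []
    names: list[str] | None = None
    ids = []
    for ts in cohort:
        sub = ts.select(all_labels)
        if band is not None:
            sub = bandpass_filter(sub, *band)
        z = fisher_z(roi_correlation(sub))
        g = threshold_adjacency(z, spec)
        measures = compute_measure_set(g)
        values, names = assemble_features(measures, measures, atlas)
        rows.append(values)
        ids.append(ts.subject_id)
    return FeatureTable(
        data=np.vstack(rows),
        feature_names=names,
        labels=np.asarray(labels, dtype=int),
        subject_ids=ids,
        group_names=group_names,
    )
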