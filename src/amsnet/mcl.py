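"""Markov Cluster (MCL) algorithm, implemented from scratch.

MCL partitions a weighted undirected graph by simulating stochastic flow:
the column-stochastic transition matrix is alternately *expanded* (raised
to a matrix power, letting flow spread along paths) and *inflated*
(raised to an entrywise power and column-renormalised, strengthening
strong currents and demoting weak ones) until the flow stabilises.  In the
limit matrix, flow collects on a few *attractor* nodes; each attractor's
row spells out the membership of its cluster.  The inflation exponent
controls granularity: larger values fragment the graph into more, smaller
clusters.

The implementation is dense (numpy); the questionnaire networks this
package targets have at most a few thousand nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .records import VAS_COLUMNS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MCLParams:
    """MCL tuning parameters.

    inflation:
        Granularity exponent (> 1); 1.4 is the shipped analysis value.
    expansion:
        Matrix-power for the expansion step (integer >= 2; 2 is standard).
    self_loop:
        Self-loop scheme applied before normalisation: ``"unit"`` (weight-1
        loops; guarantees aperiodicity and is the conventional choice),
        ``"max_weight"`` (loop weight = node's largest incident weight) or
        ``"none"``.
    prune_below:
        Entries smaller than this are zeroed (then columns renormalised)
        after each inflation; purely a stability/efficiency device.
    tol:
        Convergence tolerance on the maximum absolute entry change.
    max_iters:
        Iteration cap; non-convergence is flagged, not fatal.
    min_cluster_size:
        Clusters smaller than this are reported as unclustered.
    """

    inflation: float = 1.4
    expansion: int = 2
    self_loop: str = "unit"
    prune_below: float = 1e-6
    tol: float = 1e-8
    max_iters: int = 200
    min_cluster_size: int = 30

    def __post_init__(self) -> None:
        if self.inflation <= 1.0:
            raise ValueError("inflation must be > 1")
        if int(self.expansion) != self.expansion or self.expansion < 2:
            raise ValueError("expansion must be an integer >= 2")
        if self.self_loop not in ("none", "unit", "max_weight"):
            raise ValueError(f"unknown self_loop scheme {self.self_loop!r}")
        if self.prune_below < 0:
            raise ValueError("prune_below must be >= 0")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


@dataclass
class ClusterResult:
    """Outcome of one MCL run.

    ``clusters`` holds only the clusters meeting ``min_cluster_size``,
    ordered by decreasing size (ties: smallest member label first);
    ``assignment`` maps every network node to its cluster index or ``None``
    for unclustered nodes.  ``raw_clusters`` retains the unfiltered
    partition for diagnostics.
    """

    assignment: dict[Hashable, int | None]
    clusters: list[list[Hashable]]
    sizes: list[int]
    raw_clusters: list[list[Hashable]]
    converged: bool
    n_iterations: int
    median_profiles: pd.DataFrame | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_unclustered(self) -> int:
        return sum(1 for c in self.assignment.values() if c is None)


# ---------------------------------------------------------------------------
# matrix iteration
# ---------------------------------------------------------------------------

def add_self_loops(adj: np.ndarray, scheme: str) -> np.ndarray:
    out = adj.astype(float).copy()
    if scheme == "unit":
        np.fill_diagonal(out, 1.0)
    elif scheme == "max_weight":
        np.fill_diagonal(out, 0.0)
        np.fill_diagonal(out, np.maximum(out.max(axis=0), 1e-12))
    return out


def normalize_columns(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=0)
    if (sums <= 0).any():
        raise ValueError("matrix has a zero column; graph has an isolated node")
    return m / sums


def _inflate(m: np.ndarray, inflation: float) -> np.ndarray:
    return normalize_columns(np.power(m, inflation))


def _prune(m: np.ndarray, threshold: float) -> np.ndarray:
    if threshold <= 0:
        return m
    m = np.where(m < threshold, 0.0, m)
    return normalize_columns(m)


def mcl_iterate(
    adj: np.ndarray, params: MCLParams
) -> tuple[np.ndarray, bool, int]:
    """Run the expansion/inflation loop on a weighted adjacency matrix.

    Returns ``(limit_matrix, converged, n_iterations)``.  The limit matrix
    is column-stochastic throughout (sum 1 per column to ~1e-9).
    """
    m = normalize_columns(add_self_loops(adj, params.self_loop))
    for it in range(1, params.max_iters + 1):
        expanded = np.linalg.matrix_power(m, params.expansion)
        nxt = _prune(_inflate(expanded, params.inflation), params.prune_below)
        delta = float(np.abs(nxt - m).max())
        m = nxt
        if delta < params.tol:
            return m, True, it
    logger.warning("MCL did not converge within %d iterations", params.max_iters)
    return m, False, params.max_iters


# ---------------------------------------------------------------------------
# cluster extraction
# ---------------------------------------------------------------------------

def extract_clusters(limit: np.ndarray) -> list[list[int]]:
    """Read the hard partition off a (near-)idempotent MCL limit matrix.

    Attractors are nodes with positive self-flow.  Attractors whose rows
    overlap (either reaches the other) form one attractor system; every
    node joins the system receiving most of its column mass.  Residual ties
    are broken toward the larger system, then the system containing the
    smallest attractor index, so extraction is deterministic.
    """
    n = limit.shape[0]
    attractors = np.flatnonzero(np.diag(limit) > 0)
    if len(attractors) == 0:
        # pathological (non-converged); treat the whole graph as one cluster
        return [list(range(n))]

    # group attractors into systems via connectivity among attractor rows
    sub = limit[np.ix_(attractors, attractors)]
    sys_graph = nx.Graph()
    sys_graph.add_nodes_from(range(len(attractors)))
    for a in range(len(attractors)):
        for b in range(a + 1, len(attractors)):
            if sub[a, b] > 0 or sub[b, a] > 0:
                sys_graph.add_edge(a, b)
    systems = [sorted(attractors[list(c)]) for c in nx.connected_components(sys_graph)]
    systems.sort(key=lambda s: s[0])

    # column mass received by each system, per node
    mass = np.vstack([limit[s, :].sum(axis=0) for s in systems])  # (n_sys, n)
    support = np.vstack([(limit[s, :] > 0).any(axis=0) for s in systems])
    sys_size = support.sum(axis=1)  # provisional membership counts for tie-breaks

    members: list[list[int]] = [[] for _ in systems]
    for j in range(n):
        col = mass[:, j]
        if col.max() <= 0.0:
            # no flow onto any attractor (non-converged residue): fall back to
            # the system of the row receiving most of this column's mass
            row = int(np.argmax(limit[:, j]))
            k = next(
                (s_i for s_i, s in enumerate(systems) if row in s), None
            )
            if k is None:
                members.append([j])
                systems.append([j])
                continue
        else:
            best = np.flatnonzero(col == col.max())
            if len(best) > 1:
                best = best[sys_size[best] == sys_size[best].max()]
            k = int(best[0])  # systems sorted by smallest attractor id
        members[k].append(j)
    return [sorted(c) for c in members if c]


def mcl_cluster(
    network: nx.Graph,
    params: MCLParams = MCLParams(),
    records: pd.DataFrame | None = None,
) -> ClusterResult:
    """Cluster a questionnaire network with MCL.

    Node order is canonicalised (sorted labels) so the result is independent
    of graph construction order.  If ``records`` is given, per-cluster
    per-item median profiles are attached.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty network")
    nodes = sorted(network.nodes)
    adj = nx.to_numpy_array(network, nodelist=nodes, weight="weight")
    limit, converged, n_iter = mcl_iterate(adj, params)
    raw = extract_clusters(limit)

    raw_nodes = [[nodes[i] for i in cluster] for cluster in raw]
    kept = [c for c in raw_nodes if len(c) >= params.min_cluster_size]
    kept.sort(key=lambda c: (-len(c), c[0] if c else None))

    assignment: dict[Hashable, int | None] = {node: None for node in nodes}
    for cid, cluster in enumerate(kept):
        for node in cluster:
            assignment[node] = cid

    result = ClusterResult(
        assignment=assignment,
        clusters=kept,
        sizes=[len(c) for c in kept],
        raw_clusters=raw_nodes,
        converged=converged,
        n_iterations=n_iter,
    )
    if records is not None:
        result.median_profiles = cluster_median_profiles(kept, records)
    return result


def cluster_median_profiles(
    clusters: Sequence[Sequence[Hashable]], records: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster per-item medians (mm) over member questionnaires.

    Clusters index ``records`` by its DataFrame index labels.  Even-sized
    clusters take the midpoint of the central pair (ordinary sample median).
    """
    rows = {}
    for cid, cluster in enumerate(clusters):
        if len(cluster) == 0:
            raise ValueError(f"cluster {cid} is empty")
        member_items = records.loc[list(cluster), list(VAS_COLUMNS)]
        rows[cid] = member_items.median(axis=0)
    return pd.DataFrame(rows).T.rename_axis("cluster_id")


def write_clusters_csv(result: ClusterResult, path) -> None:
    """clusters.csv: node_id, cluster_id (or 'unclustered'), cluster_size."""
    size_of = {cid: size for cid, size in enumerate(result.sizes)}
    rows = [
        {
            "node_id": node,
            "cluster_id": "unclustered" if cid is None else cid,
            "cluster_size": size_of.get(cid, 0) if cid is not None else 0,
        }
        for node, cid in sorted(result.assignment.items(), key=lambda kv: str(kv[0]))
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
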