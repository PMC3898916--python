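"""Questionnaire-questionnaire correlation network.

Each QC-passing questionnaire is a node; an undirected weighted edge joins
two questionnaires whose item profiles have Pearson correlation at or above
the threshold (default r = 0.95, chosen to restrict the graph to very
similar profiles).  Questionnaires with no supra-threshold neighbour are
absent from the network, and profiles with zero variance across items never
form edges (their correlation is undefined).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .records import SYMPTOMS, VAS_COLUMNS, symptom_profile_frame

logger = logging.getLogger(__name__)

NODE_ATTRS = ("subject_id", "expedition", "day", "treatment", "sex", "age_band")


@dataclass(frozen=True)
class NetworkParams:
    """Correlation-network construction parameters.

    ``profile_mode`` selects the vector correlated between questionnaires:
    all seven instrument items (default) or the five averaged symptom
    composites (sensitivity mode).
    """

    r_threshold: float = 0.95
    profile_mode: str = "seven_item"

    def __post_init__(self) -> None:
        if not -1.0 < self.r_threshold < 1.0:
            raise ValueError("r_threshold must lie strictly inside (-1, 1)")
        if self.profile_mode not in ("seven_item", "five_symptom"):
            raise ValueError(f"unknown profile_mode {self.profile_mode!r}")


def profile_matrix(records: pd.DataFrame, profile_mode: str = "seven_item") -> pd.DataFrame:
    """Per-questionnaire profile vectors as an (n_records x n_items) table."""
    if profile_mode == "seven_item":
        return records[list(VAS_COLUMNS)].astype(float)
    return symptom_profile_frame(records)[list(SYMPTOMS)]


def profile_correlation(a: Sequence[float], b: Sequence[float]) -> float:
    """Pearson correlation between two questionnaire profiles.

    Returns ``nan`` (undefined, hence no edge) when either profile has zero
    variance across its items.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"profile length mismatch: {a.shape} vs {b.shape}")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def correlation_matrix(profiles: pd.DataFrame) -> np.ndarray:
    """Full pairwise Pearson matrix; rows with zero variance give nan."""
    x = profiles.to_numpy(dtype=float)
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r[sd == 0.0, :] = np.nan
    r[:, sd == 0.0] = np.nan
    return r


def build_network(records: pd.DataFrame, params: NetworkParams = NetworkParams()) -> nx.Graph:
    """Build the thresholded questionnaire network.

    Nodes are the DataFrame index labels of records retaining at least one
    edge with r >= ``params.r_threshold`` (inclusive); each node carries the
    questionnaire metadata as attributes and each edge its Pearson r as
    ``weight``.
    """
    if len(records) < 2:
        raise ValueError("need at least two records to build a network")
    profiles = profile_matrix(records, params.profile_mode)
    r = correlation_matrix(profiles)
    n_degenerate = int(np.isnan(np.diag(r)).sum())
    if n_degenerate:
        logger.info("%d zero-variance profile(s) excluded from the network", n_degenerate)

    idx = records.index.to_numpy()
    with np.errstate(invalid="ignore"):
        adj = r >= params.r_threshold
    np.fill_diagonal(adj, False)

    graph = nx.Graph()
    ii, jj = np.nonzero(np.triu(adj, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        graph.add_edge(idx[i], idx[j], weight=float(r[i, j]))
    for node in graph.nodes:
        row = records.loc[node]
        for attr in NODE_ATTRS:
            if attr in records.columns:
                v = row[attr]
                if pd.isna(v):
                    v = None
                elif hasattr(v, "item"):  # native Python scalars for exporters
                    v = v.item()
                graph.nodes[node][attr] = v
    return graph


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_graphml(graph: nx.Graph, path) -> None:
    """GraphML export (None-valued attributes stringified for the writer)."""
    g = graph.copy()
    for _, attrs in g.nodes(data=True):
        for k, v in list(attrs.items()):
            if v is None:
                attrs[k] = ""
    nx.write_graphml(g, path)


def write_edge_list(graph: nx.Graph, path) -> None:
    """Weighted edge list CSV: node_a, node_b, r."""
    rows = [
        {"node_a": a, "node_b": b, "r": d["weight"]}
        for a, b, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "r"]).to_csv(path, index=False)


def node_table(graph: nx.Graph, assignment: dict | None = None) -> pd.DataFrame:
    """Node attribute table (cluster id filled from ``assignment`` if given)."""
    rows = []
    for node, attrs in graph.nodes(data=True):
        row = {"node_id": node, **{k: attrs.get(k) for k in NODE_ATTRS}}
        if assignment is not None:
            cluster = assignment.get(node)
            row["cluster_id"] = "unclustered" if cluster is None else cluster
        rows.append(row)
    return pd.DataFrame(rows).sort_values("node_id").reset_index(drop=True)
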