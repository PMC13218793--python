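"""Per-gene activity measures on a pair of condition-specific networks.

For a gene j in the network of condition g the measures are

* regulatory effect  R_j = xbar_j * sum_l |beta_{jl}|  (mean expression
  times total outgoing coefficient magnitude);
* hubness  H_j^g = |N_j^g| / |N_j^Q u N_j^C|, the fraction of the gene's
  combined two-condition neighborhood realized in condition g (neighbor
  sets are direction-agnostic: a gene directly linked by an edge in either
  direction is a neighbor);
* betweenness B_j: shortest-path betweenness centrality of j on the
  directed unweighted skeleton, normalized by (|V|-1)(|V|-2) over ordered
  pairs, so B in [0, 1];
* activity  A_j = R_j * (H_j + B_j) / 2.

Unreachable pairs contribute 0 to betweenness; a gene isolated in both
networks has hubness 0 in both (0/0 guarded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .grn import GeneNetwork


@dataclass
class ActivityProfile:
    """R, H, B, A per gene for a query/control network comparison."""

    genes: list[str]
    R: np.ndarray  # shape (p, 2): columns Q, C
    H: np.ndarray
    B: np.ndarray
    A: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for name, arr in (("R", self.R), ("H", self.H), ("B", self.B), ("A", self.A)):
            cols[f"{name}_Q"] = arr[:, 0]
            cols[f"{name}_C"] = arr[:, 1]
        return pd.DataFrame(cols, index=self.genes)


def regulatory_effect(net: GeneNetwork, mean_expr: np.ndarray) -> np.ndarray:
    """R_j = mean expression of j times summed |outgoing coefficients|."""
    mean_expr = np.asarray(mean_expr, dtype=float)
    if mean_expr.shape[0] != net.n_genes:
        raise ValueError("mean_expr not aligned to network genes")
    return mean_expr * np.sum(np.abs(net.coef), axis=1)


def hubness(netQ: GeneNetwork, netC: GeneNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (H_Q, H_C) from direction-agnostic neighbor sets."""
    if netQ.genes != netC.genes:
        raise ValueError("networks must share the same gene set")
    NQ, NC = netQ.neighbor_sets(), netC.neighbor_sets()
    p = netQ.n_genes
    hq, hc = np.zeros(p), np.zeros(p)
    for j in range(p):
        union = len(NQ[j] | NC[j])
        if union:
            hq[j] = len(NQ[j]) / union
            hc[j] = len(NC[j]) / union
    return hq, hc


def betweenness(net: GeneNetwork, directed: bool = True) -> np.ndarray:
    """Normalized shortest-path betweenness on the unweighted skeleton.

    Path length ignores edge weights (paths are counted, not weighed).
    With fewer than 3 nodes the normalization degenerates; all zeros are
    returned with a warning.
    """
    p = net.n_genes
    if p < 3:
        warnings.warn("betweenness undefined for networks with < 3 genes; all 0")
        return np.zeros(p)
    G: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    G.add_nodes_from(range(p))
    rows, cols = np.nonzero(net.coef)
    G.add_edges_from(zip(rows.tolist(), cols.tolist()))
    bc = nx.betweenness_centrality(G, normalized=True)
    return np.array([bc[j] for j in range(p)])


def activity_score(R: np.ndarray, H: np.ndarray, B: np.ndarray) -> np.ndarray:
    """A_j = R_j * (H_j + B_j) / 2."""
    R, H, B = (np.asarray(a, dtype=float) for a in (R, H, B))
    if not (R.shape == H.shape == B.shape):
        raise ValueError("R, H, B must be aligned")
    return R * (H + B) / 2.0


def activity_profile(
    netQ: GeneNetwork,
    netC: GeneNetwork,
    mean_exprQ: np.ndarray,
    mean_exprC: np.ndarray,
) -> ActivityProfile:
    """Full R/H/B/A profile for a query vs control network pair."""
    RQ = regulatory_effect(netQ, mean_exprQ)
    RC = regulatory_effect(netC, mean_exprC)
    HQ, HC = hubness(netQ, netC)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        BQ = betweenness(netQ)
        BC = betweenness(netC)
    AQ = activity_score(RQ, HQ, BQ)
    AC = activity_score(RC, HC, BC)
    return ActivityProfile(
        list(netQ.genes),
        np.column_stack([RQ, RC]),
        np.column_stack([HQ, HC]),
        np.column_stack([BQ, BC]),
        np.column_stack([AQ, AC]),
    )
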