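"""Classic essentiality indices for PPI networks.

Eight baselines, the ones usually compared against learned predictors:

* topology-only: degree (DC), betweenness (BC), closeness (CC),
  eigenvector (EC), neighborhood centrality (NC), local average
  connectivity (LAC);
* topology + co-expression: PeC and WDC, which weight each incident edge
  by the edge clustering coefficient (ECC) and/or the Pearson correlation
  (PCC) of the two endpoints' expression profiles.

Definitions used here::

    ECC(u,v) = |N(u) ∩ N(v)| / min(deg(u)-1, deg(v)-1)   (0 if min = 0)
    NC(v)    = Σ_{u∈N(v)} ECC(v,u)
    LAC(v)   = (1/deg v) Σ_{u∈N(v)} deg_{G[N(v)]}(u)
    PeC(v)   = Σ_{u∈N(v)} ECC(v,u) · PCC(v,u)
    WDC(v)   = Σ_{u∈N(v)} [ λ·ECC(v,u) + (1-λ)·PCC(v,u) ],  λ = 0.5

Negative Pearson terms are floored at 0 inside PeC/WDC by default (the
convention of those methods); pass ``clip_negative=False`` to keep signs.
BC is the unnormalized Brandes pair-dependency; CC is
(n_reachable - 1)/Σ distances (0 for isolated nodes); EC is the principal
eigenvector, L2-normalized with non-negative orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .data import ExpressionMatrix, PPINetwork

TOPOLOGY_METHODS = ("DC", "BC", "CC", "EC", "NC", "LAC")
EXPRESSION_METHODS = ("PeC", "WDC")
ALL_METHODS = TOPOLOGY_METHODS + EXPRESSION_METHODS


@dataclass
class ScoreTable:
    """Per-protein real scores under one scoring method."""

    scores: dict[str, float]
    method_name: str

    def __post_init__(self) -> None:
        for key, val in self.scores.items():
            if not np.isfinite(val):
                raise ValueError(f"non-finite score for {key!r}")

    def __getitem__(self, key: str) -> float:
        return self.scores[key]

    def __len__(self) -> int:
        return len(self.scores)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for key in sorted(self.scores):
                fh.write(f"{key}\t{self.scores[key]!r}\n")


def classic_centrality(network: PPINetwork, kind: str) -> ScoreTable:
    """Degree, betweenness, closeness or eigenvector centrality."""
    if network.n_nodes == 0:
        raise ValueError("centrality of an empty network is undefined")
    g = network.to_networkx()
    if kind == "DC":
        scores = {v: float(d) for v, d in g.degree()}
    elif kind == "BC":
        scores = {v: float(x)
                  for v, x in nx.betweenness_centrality(g, normalized=False).items()}
    elif kind == "CC":
        scores = {v: float(x)
                  for v, x in nx.closeness_centrality(g, wf_improved=False).items()}
    elif kind == "EC":
        if network.n_edges == 0:
            raise ValueError("eigenvector centrality needs >=1 edge")
        raw = nx.eigenvector_centrality_numpy(g)
        vec = np.array([raw[v] for v in network.nodes])
        if vec.sum() < 0:
            vec = -vec
        vec = np.abs(vec) if np.all(vec <= 1e-12) else vec
        vec = vec / np.linalg.norm(vec)
        scores = {v: float(x) for v, x in zip(network.nodes, vec)}
    else:
        raise ValueError(f"unknown classic centrality {kind!r}")
    return ScoreTable(scores=scores, method_name=kind)


def edge_clustering_coefficient(network: PPINetwork, u: str, v: str) -> float:
    """Common-neighbor count over min(deg-1); 0 when the min degree is 1."""
    if not network.has_edge(u, v):
        raise ValueError(f"({u!r},{v!r}) is not an edge")
    denom = min(network.degree(u), network.degree(v)) - 1
    if denom <= 0:
        return 0.0
    z = len(set(network.neighbors(u)) & set(network.neighbors(v)))
    return z / denom


def local_centrality(network: PPINetwork, kind: str) -> ScoreTable:
    """NC (sum of incident-edge ECCs) or LAC (mean induced neighbor degree)."""
    if kind not in ("NC", "LAC"):
        raise ValueError(f"unknown local centrality {kind!r}")
    adj = network.adjacency()
    scores: dict[str, float] = {}
    for v in network.nodes:
        nbrs = adj[v]
        if not nbrs:
            scores[v] = 0.0
            continue
        if kind == "NC":
            scores[v] = sum(edge_clustering_coefficient(network, v, u)
                            for u in nbrs)
        else:
            nbr_set = set(nbrs)
            induced_degree_sum = sum(
                sum(1 for w in adj[u] if w in nbr_set) for u in nbrs)
            scores[v] = induced_degree_sum / len(nbrs)
    return ScoreTable(scores=scores, method_name=kind)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; 0 by convention when either input is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.dot(xc, xc))
    sy = np.sqrt(np.dot(yc, yc))
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(np.clip(np.dot(xc, yc) / (sx * sy), -1.0, 1.0))


def expression_weighted_centrality(network: PPINetwork, expr: ExpressionMatrix,
                                   kind: str, lam: float = 0.5,
                                   clip_negative: bool = True) -> ScoreTable:
    """PeC or WDC, combining ECC with expression correlation per edge."""
    if kind not in ("PeC", "WDC"):
        raise ValueError(f"unknown expression-weighted centrality {kind!r}")
    adj = network.adjacency()
    scores: dict[str, float] = {}
    for v in network.nodes:
        total = 0.0
        for u in adj[v]:
            ecc = edge_clustering_coefficient(network, v, u)
            pcc = pearson(expr[v], expr[u])
            if clip_negative and pcc < 0.0:
                pcc = 0.0
            if kind == "PeC":
                total += ecc * pcc
            else:
                total += lam * ecc + (1.0 - lam) * pcc
        scores[v] = total
    return ScoreTable(scores=scores, method_name=kind)


def compute_centrality(network: PPINetwork, kind: str,
                       expr: ExpressionMatrix | None = None,
                       lam: float = 0.5) -> ScoreTable:
    """Dispatch over the eight supported methods."""
    if kind in ("DC", "BC", "CC", "EC"):
        return classic_centrality(network, kind)
    if kind in ("NC", "LAC"):
        return local_centrality(network, kind)
    if kind in ("PeC", "WDC"):
        if expr is None:
            raise ValueError(f"{kind} requires an expression matrix")
        return expression_weighted_centrality(network, expr, kind, lam=lam)
    raise ValueError(f"unknown centrality method {kind!r}")


def rank_candidates(scores: ScoreTable, K: int) -> list[str]:
    """Top-K identifiers by descending score; ties break by ascending id."""
    if K < 1 or K > len(scores.scores):
        raise ValueError(f"K={K} outside [1, {len(scores.scores)}]")
    ordering = sorted(scores.scores, key=lambda v: (-scores.scores[v], v))
    return ordering[:K]
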