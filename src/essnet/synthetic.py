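"""Seeded generator of desk-scale study datasets.

Emulates the structure the predictor assumes about real interactomes:

* a scale-free PPI network (Barabási–Albert preferential attachment),
  because the centrality-lethality observation — hubs tend to be
  essential — needs a hub-dominated degree distribution;
* essentiality labels drawn per node with probability
  ``logistic(base + slope * log(degree))``, planting exactly the
  degree-linked signal a topological predictor should recover;
* periodic expression profiles over 3 cycles x 12 time points:
  ``amplitude * sin(2*pi*t/12 + phase) + Normal(0, noise_sd)``, with
  per-node phases mixed toward the closed-neighborhood mean (weight
  ``coexpr_strength``) so interacting proteins co-express, and essential
  proteins drawn from a narrow phase band so the expression branch carries
  an independent, weaker label signal.

All generators are deterministic for a fixed seed, and the writer emits
the same plain-text formats the readers in :mod:`essnet.data` consume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .data import (AlignedDataset, ExpressionMatrix, LabelSet, PPINetwork,
                   align, write_edge_list, write_expression, write_labels)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study (defaults = the standard fixture)."""

    n_nodes: int = 1000
    attach_m: int = 4
    essential_base: float = -3.2
    essential_slope: float = 1.1
    coexpr_strength: float = 0.3
    noise_sd: float = 0.5
    amplitude: float = 1.0
    essential_phase_sd: float = 0.45
    seed: int = 42

    def __post_init__(self) -> None:
        if not self.n_nodes > self.attach_m >= 1:
            raise ValueError("need n_nodes > attach_m >= 1")
        if not 0.0 <= self.coexpr_strength <= 1.0:
            raise ValueError("coexpr_strength must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _node_name(i: int) -> str:
    return f"P{i:05d}"


def generate_network(spec: SyntheticSpec) -> PPINetwork:
    """Preferential-attachment network; connected, simple, deterministic."""
    g = nx.barabasi_albert_graph(spec.n_nodes, spec.attach_m, seed=spec.seed)
    pairs = [(_node_name(u), _node_name(v)) for u, v in g.edges()]
    names = [_node_name(v) for v in g.nodes()]
    return PPINetwork.from_edges(pairs, extra_nodes=names)


def assign_labels(network: PPINetwork, spec: SyntheticSpec) -> LabelSet:
    """Essential with probability logistic(base + slope * log degree)."""
    rng = np.random.default_rng(spec.seed + 1)
    essential: set[str] = set()
    for v in network.nodes:
        deg = max(network.degree(v), 1)
        logit = spec.essential_base + spec.essential_slope * np.log(deg)
        p = 1.0 / (1.0 + np.exp(-logit))
        if rng.random() < p:
            essential.add(v)
    return LabelSet(essential_ids=frozenset(essential))


def _phases(network: PPINetwork, labels: LabelSet, spec: SyntheticSpec,
            rng: np.random.Generator) -> dict[str, float]:
    """Initial phases (narrow band for essentials), then neighborhood mixing."""
    phi: dict[str, float] = {}
    for v in network.nodes:
        if v in labels:
            phi[v] = float(rng.normal(0.0, spec.essential_phase_sd))
        else:
            phi[v] = float(rng.uniform(0.0, 2.0 * np.pi))
    if spec.coexpr_strength == 0.0:
        return phi
    c = spec.coexpr_strength
    z = {v: np.exp(1j * p) for v, p in phi.items()}
    mixed: dict[str, float] = {}
    for v in network.nodes:
        closed = (v,) + network.neighbors(v)
        mean = np.mean([z[u] for u in closed])
        target = (1.0 - c) * z[v] + c * mean
        if abs(target) < 1e-12:
            mixed[v] = phi[v]
        else:
            mixed[v] = float(np.angle(target))
    return mixed


def generate_expression(network: PPINetwork, labels: LabelSet,
                        spec: SyntheticSpec) -> ExpressionMatrix:
    """3x12 periodic profiles with phase coherence along edges."""
    rng = np.random.default_rng(spec.seed + 2)
    phi = _phases(network, labels, spec, rng)
    t = np.arange(36)
    base = 2.0 * np.pi * (t % 12) / 12.0
    rows: dict[str, np.ndarray] = {}
    for v in network.nodes:
        signal = spec.amplitude * np.sin(base + phi[v])
        noise = rng.normal(0.0, spec.noise_sd, size=36) if spec.noise_sd > 0 \
            else np.zeros(36)
        rows[v] = signal + noise
    return ExpressionMatrix(rows=rows)


def generate_dataset(spec: SyntheticSpec | None = None) -> AlignedDataset:
    """Network + labels + expression, already aligned."""
    spec = spec or SyntheticSpec()
    network = generate_network(spec)
    labels = assign_labels(network, spec)
    expr = generate_expression(network, labels, spec)
    return align(network, expr, labels)


def write_dataset(dataset: AlignedDataset, outdir: str | Path,
                  spec: SyntheticSpec | None = None) -> dict[str, Path]:
    """Emit edge list, expression TSV, label list and a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": outdir / "network.tsv",
        "expression": outdir / "expression.tsv",
        "labels": outdir / "essential.txt",
        "manifest": outdir / "manifest.json",
    }
    write_edge_list(dataset.network, paths["network"])
    write_expression(dataset.expression, paths["expression"])
    write_labels(LabelSet(essential_ids=frozenset(
        v for v, y in dataset.labels.items() if y == 1)), paths["labels"])
    manifest = {
        "n_nodes": dataset.network.n_nodes,
        "n_edges": dataset.network.n_edges,
        "n_essential": sum(dataset.labels.values()),
        "spec": asdict(spec) if spec is not None else None,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths
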