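"""Reading, cleaning and aligning the three input datasets.

A study consists of three plain-text inputs:

* an undirected protein-protein interaction (PPI) network given as a
  two-column edge list of protein identifiers,
* a gene-expression matrix with one row per protein and 36 values per row
  (three successive metabolic cycles of 12 time points each, cycle-major),
* a list of essential-protein identifiers, one per line.

Cleaning removes self-interactions and repeated interactions from the
network.  Alignment restricts everything to the network's node set:
expression rows without a network node are dropped, network nodes without a
measured profile get an all-zero row (and are recorded so callers can
exclude them), and essential identifiers outside the network are dropped
with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

N_TIMEPOINTS = 36  # 3 metabolic cycles x 12 time points, cycle-major


class FormatError(ValueError):
    """A malformed input file (bad line, wrong column count, ...)."""


@dataclass(frozen=True)
class PPINetwork:
    """Undirected simple graph over opaque protein identifiers.

    Invariants: no self-loops, each unordered pair stored once (as a sorted
    tuple), every edge endpoint is a node.
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    @staticmethod
    def from_edges(pairs: Iterable[tuple[str, str]],
                   extra_nodes: Iterable[str] = ()) -> "PPINetwork":
        """Build a clean network: drop self-loops, collapse duplicates."""
        edges: set[tuple[str, str]] = set()
        nodes: set[str] = set(extra_nodes)
        for u, v in pairs:
            if u == v:
                continue
            edges.add((u, v) if u <= v else (v, u))
        for u, v in edges:
            nodes.add(u)
            nodes.add(v)
        return PPINetwork(nodes=tuple(sorted(nodes)), edges=frozenset(edges))

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge ({u!r},{v!r}) endpoint not in node set")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> dict[str, tuple[str, ...]]:
        """Neighbor lists, each sorted, for every node (cached)."""
        cached = getattr(self, "_adj", None)
        if cached is None:
            adj: dict[str, list[str]] = {v: [] for v in self.nodes}
            for u, v in self.edges:
                adj[u].append(v)
                adj[v].append(u)
            cached = {v: tuple(sorted(ns)) for v, ns in adj.items()}
            object.__setattr__(self, "_adj", cached)
        return cached

    def neighbors(self, v: str) -> tuple[str, ...]:
        return self.adjacency()[v]

    def degree(self, v: str) -> int:
        return len(self.adjacency()[v])

    def has_edge(self, u: str, v: str) -> bool:
        return ((u, v) if u <= v else (v, u)) in self.edges

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass
class ExpressionMatrix:
    """Per-protein 36-value expression profiles, cycle-major order."""

    rows: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for key, row in self.rows.items():
            row = np.asarray(row, dtype=float)
            if row.shape != (N_TIMEPOINTS,):
                raise FormatError(
                    f"expression row {key!r} has {row.size} values, "
                    f"expected {N_TIMEPOINTS}")
            if not np.all(np.isfinite(row)):
                raise FormatError(f"expression row {key!r} has non-finite values")
            self.rows[key] = row

    def __contains__(self, key: str) -> bool:
        return key in self.rows

    def __getitem__(self, key: str) -> np.ndarray:
        return self.rows[key]

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class LabelSet:
    """Identifiers of essential (positive-class) proteins."""

    essential_ids: frozenset[str]

    def __contains__(self, key: str) -> bool:
        return key in self.essential_ids

    def __len__(self) -> int:
        return len(self.essential_ids)


@dataclass
class AlignedDataset:
    """Network, expression and labels restricted to a common node set.

    ``labels`` maps every network node to 0/1; nodes without a measured
    profile carry an all-zero row and are listed in ``missing_profile_ids``.
    """

    network: PPINetwork
    expression: ExpressionMatrix
    labels: dict[str, int]
    missing_profile_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        nodes = set(self.network.nodes)
        if set(self.labels) != nodes:
            raise ValueError("label domain must equal the network node set")
        missing = nodes - set(self.expression.rows)
        if missing:
            raise ValueError(f"{len(missing)} nodes lack an expression row")

    @property
    def positive_ids(self) -> list[str]:
        return [v for v in self.network.nodes if self.labels[v] == 1]

    @property
    def negative_ids(self) -> list[str]:
        return [v for v in self.network.nodes if self.labels[v] == 0]

    @property
    def prevalence(self) -> float:
        return sum(self.labels.values()) / len(self.labels)


@dataclass(frozen=True)
class SplitDataset:
    """A stratified train/test partition of the node identifiers."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    split_fraction: float
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test identifier sets overlap")


# ---------------------------------------------------------------------------
# readers / writers


def _detect_delimiter(line: str) -> str | None:
    return "\t" if "\t" in line else None  # None => any whitespace


def read_edge_list(path: str | Path, delimiter: str | None = None) -> PPINetwork:
    """Read a two-column edge list; drop self-loops and duplicate pairs.

    Lines starting with ``#`` are comments; the delimiter is auto-detected
    (tab vs. whitespace) unless given.  Counts of dropped records are logged.
    """
    path = Path(path)
    raw_pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sep = delimiter if delimiter is not None else _detect_delimiter(line)
            fields = line.split(sep)
            fields = [f for f in fields if f]
            if len(fields) < 2:
                raise FormatError(
                    f"{path}:{lineno}: expected >=2 columns, got {len(fields)}")
            raw_pairs.append((fields[0], fields[1]))
    if not raw_pairs:
        raise FormatError(f"{path}: empty edge list")
    net = PPINetwork.from_edges(raw_pairs)
    n_loops = sum(1 for u, v in raw_pairs if u == v)
    n_dupes = len(raw_pairs) - n_loops - net.n_edges
    if n_loops or n_dupes:
        logger.info("%s: dropped %d self-interactions and %d repeated interactions",
                    path.name, n_loops, n_dupes)
    return net


def write_edge_list(network: PPINetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(network.edges):
            fh.write(f"{u}\t{v}\n")


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV of identifier + 36 numeric columns (header optional).

    Duplicate identifiers keep the first row seen (a warning is logged).
    """
    path = Path(path)
    rows: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            key, values = fields[0], fields[1:]
            if lineno == 1:
                try:
                    [float(x) for x in values]
                except ValueError:
                    continue  # header row
            if len(values) != N_TIMEPOINTS:
                raise FormatError(
                    f"{path}:{lineno}: row {key!r} has {len(values)} values, "
                    f"expected {N_TIMEPOINTS}")
            if key in rows:
                logger.warning("%s: duplicate identifier %r, keeping first row",
                               path.name, key)
                continue
            try:
                rows[key] = np.array([float(x) for x in values])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: row {key!r}: {exc}") from exc
    return ExpressionMatrix(rows=rows)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for key in sorted(expr.rows):
            vals = "\t".join(repr(float(x)) for x in expr.rows[key])
            fh.write(f"{key}\t{vals}\n")


def read_labels(path: str | Path) -> LabelSet:
    """Read one identifier per line; duplicates collapse."""
    path = Path(path)
    ids: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line.split()[0])
    if not ids:
        logger.warning("%s: empty essential-protein list", path.name)
    return LabelSet(essential_ids=frozenset(ids))


def write_labels(labels: LabelSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for key in sorted(labels.essential_ids):
            fh.write(f"{key}\n")


# ---------------------------------------------------------------------------
# alignment and splitting


def align(network: PPINetwork, expr: ExpressionMatrix,
          labels: LabelSet) -> AlignedDataset:
    """Restrict expression and labels to the network's node set.

    Nodes with no measured profile get an all-zero 36-vector and are listed
    in ``missing_profile_ids``; label identifiers outside the network are
    dropped with a logged count.
    """
    nodes = set(network.nodes)
    rows = {v: expr.rows[v] for v in network.nodes if v in expr.rows}
    missing = frozenset(nodes - set(rows))
    for v in missing:
        rows[v] = np.zeros(N_TIMEPOINTS)
    dropped_labels = len(labels.essential_ids - nodes)
    if dropped_labels:
        logger.info("dropped %d essential identifiers not in the network",
                    dropped_labels)
    if missing:
        logger.info("%d network nodes lack an expression profile (zero-filled)",
                    len(missing))
    label_map = {v: int(v in labels.essential_ids) for v in network.nodes}
    return AlignedDataset(network=network,
                          expression=ExpressionMatrix(rows=rows),
                          labels=label_map,
                          missing_profile_ids=missing)


def stratified_split(dataset: AlignedDataset, fraction: float = 0.8,
                     seed: int = 0) -> SplitDataset:
    """Shuffle-then-split within each class so prevalence is preserved.

    ``fraction`` is the training share; one integer seed governs the shuffle
    of both classes, so the split is deterministic.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"split fraction must be in (0,1), got {fraction}")
    pos, neg = dataset.positive_ids, dataset.negative_ids
    if not pos or not neg:
        raise ValueError("stratified split needs >=1 positive and >=1 negative")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for group in (pos, neg):
        order = rng.permutation(len(group))
        n_train = int(round(fraction * len(group)))
        n_train = min(max(n_train, 1), len(group) - 1)
        for i, idx in enumerate(order):
            (train if i < n_train else test).append(group[idx])
    return SplitDataset(train_ids=tuple(train), test_ids=tuple(test),
                        split_fraction=fraction, seed=seed)
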