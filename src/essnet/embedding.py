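"""node2vec network representation learning.

Two stages: (i) second-order biased random walks over the PPI network
generate a corpus of node sequences; (ii) a skip-gram model with negative
sampling (SGNS) trained on that corpus yields a dense vector per protein.
The walk bias follows the node2vec scheme: stepping from ``cur`` (having
arrived from ``prev``), a candidate neighbor is weighted 1/p if it equals
``prev``, 1 if it is adjacent to ``prev``, and 1/q otherwise.

The SGNS trainer is a self-contained NumPy implementation using the
standard word2vec conventions: input vectors initialised uniformly in
[-0.5/dim, 0.5/dim), output vectors at zero, a unigram^0.75 noise
distribution, per-position context windows shrunk uniformly at random,
and a linearly decaying learning rate.  Training is single-threaded and
fully deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import PPINetwork

logger = logging.getLogger(__name__)

DEFAULT_DIM = 64


@dataclass(frozen=True)
class WalkConfig:
    """Biased random-walk parameters (node2vec reference defaults)."""

    p: float = 1.0            # return parameter
    q: float = 1.0            # in-out parameter
    walk_length: int = 80
    walks_per_node: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")
        if self.walk_length < 2:
            raise ValueError("walk_length must be >= 2")
        if self.walks_per_node < 1:
            raise ValueError("walks_per_node must be >= 1")


@dataclass(frozen=True)
class SkipGramConfig:
    """Skip-gram/negative-sampling hyperparameters."""

    window: int = 10
    negative_samples: int = 5
    epochs: int = 5
    seed: int = 0
    initial_lr: float = 0.025
    min_lr: float = 1e-4
    batch_size: int = 10_000

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.negative_samples < 0:
            raise ValueError("negative_samples must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class WalkCorpus:
    """A list of node-identifier sequences; consecutive nodes are adjacent."""

    walks: list[list[str]]

    def __len__(self) -> int:
        return len(self.walks)


@dataclass
class EmbeddingTable:
    """One dense vector per protein identifier."""

    vectors: dict[str, np.ndarray]
    dimension: int = DEFAULT_DIM

    def __post_init__(self) -> None:
        for key, vec in self.vectors.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (self.dimension,):
                raise ValueError(
                    f"vector for {key!r} has shape {vec.shape}, "
                    f"expected ({self.dimension},)")
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"vector for {key!r} has non-finite components")
            self.vectors[key] = vec

    def __contains__(self, key: str) -> bool:
        return key in self.vectors

    def __getitem__(self, key: str) -> np.ndarray:
        return self.vectors[key]

    def __len__(self) -> int:
        return len(self.vectors)

    def as_matrix(self, ids: list[str]) -> np.ndarray:
        """Stack vectors for ``ids``; missing ids get a zero vector."""
        out = np.zeros((len(ids), self.dimension))
        for i, key in enumerate(ids):
            if key in self.vectors:
                out[i] = self.vectors[key]
        return out

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key in sorted(self.vectors):
                vals = "\t".join(repr(float(x)) for x in self.vectors[key])
                fh.write(f"{key}\t{vals}\n")

    @staticmethod
    def from_tsv(path: str | Path) -> "EmbeddingTable":
        vectors: dict[str, np.ndarray] = {}
        dim = DEFAULT_DIM
        with open(path) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                vectors[fields[0]] = np.array([float(x) for x in fields[1:]])
                dim = len(fields) - 1
        return EmbeddingTable(vectors=vectors, dimension=dim)

    def to_word2vec(self, path: str | Path) -> None:
        """word2vec text format: 'count dim' header, space-separated rows."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.vectors)} {self.dimension}\n")
            for key in sorted(self.vectors):
                vals = " ".join(repr(float(x)) for x in self.vectors[key])
                fh.write(f"{key} {vals}\n")


# ---------------------------------------------------------------------------
# walks


def transition_distribution(network: PPINetwork, prev: str, cur: str,
                            p: float, q: float) -> dict[str, float]:
    """Second-order transition probabilities out of ``cur`` given ``prev``.

    Returns an empty mapping when ``cur`` has no neighbors (the caller
    terminates the walk).  Probabilities sum to 1 over the neighbors of
    ``cur``.
    """
    if not network.has_edge(prev, cur):
        raise ValueError(f"{prev!r} and {cur!r} are not adjacent")
    neighbors = network.neighbors(cur)
    if not neighbors:
        return {}
    weights = np.empty(len(neighbors))
    for i, nbr in enumerate(neighbors):
        if nbr == prev:
            weights[i] = 1.0 / p
        elif network.has_edge(nbr, prev):
            weights[i] = 1.0
        else:
            weights[i] = 1.0 / q
    weights /= weights.sum()
    return dict(zip(neighbors, weights))


def _csr_adjacency(network: PPINetwork):
    """Index nodes and pack neighbor lists into CSR-style arrays."""
    nodes = list(network.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj = network.adjacency()
    indptr = np.zeros(len(nodes) + 1, dtype=np.int64)
    flat: list[int] = []
    for i, v in enumerate(nodes):
        nbrs = adj[v]
        indptr[i + 1] = indptr[i] + len(nbrs)
        flat.extend(index[u] for u in nbrs)
    return nodes, index, indptr, np.array(flat, dtype=np.int64)


def _uniform_walks(network: PPINetwork, cfg: WalkConfig,
                   rng: np.random.Generator) -> list[list[str]]:
    """Vectorised first-order walks (the p == q == 1 special case)."""
    nodes, _, indptr, indices = _csr_adjacency(network)
    n = len(nodes)
    degrees = np.diff(indptr)
    walks: list[list[str]] = []
    for _ in range(cfg.walks_per_node):
        order = rng.permutation(n)
        paths = np.full((n, cfg.walk_length), -1, dtype=np.int64)
        paths[:, 0] = order
        cur = order.copy()
        alive = degrees[cur] > 0
        for step in range(1, cfg.walk_length):
            if not alive.any():
                break
            live = np.flatnonzero(alive)
            deg = degrees[cur[live]]
            pick = (rng.random(live.size) * deg).astype(np.int64)
            nxt = indices[indptr[cur[live]] + pick]
            cur[live] = nxt
            paths[live, step] = nxt
        for row in paths:
            walks.append([nodes[i] for i in row if i >= 0])
    return walks


def _biased_walks(network: PPINetwork, cfg: WalkConfig,
                  rng: np.random.Generator) -> list[list[str]]:
    """General second-order walks; per-(prev, cur) tables cached lazily."""
    nodes = list(network.nodes)
    adj = network.adjacency()
    cache: dict[tuple[str, str], tuple[tuple[str, ...], np.ndarray]] = {}
    walks: list[list[str]] = []
    for _ in range(cfg.walks_per_node):
        for idx in rng.permutation(len(nodes)):
            start = nodes[idx]
            walk = [start]
            nbrs = adj[start]
            if not nbrs:
                walks.append(walk)
                continue
            walk.append(nbrs[int(rng.integers(len(nbrs)))])
            while len(walk) < cfg.walk_length:
                prev, cur = walk[-2], walk[-1]
                key = (prev, cur)
                if key not in cache:
                    dist = transition_distribution(network, prev, cur,
                                                   cfg.p, cfg.q)
                    if not dist:
                        cache[key] = ((), np.empty(0))
                    else:
                        cache[key] = (tuple(dist), np.cumsum(list(dist.values())))
                support, cum = cache[key]
                if not support:
                    break
                j = int(np.searchsorted(cum, rng.random(), side="right"))
                walk.append(support[min(j, len(support) - 1)])
            walks.append(walk)
    return walks


def generate_walks(network: PPINetwork, cfg: WalkConfig) -> WalkCorpus:
    """Run ``walks_per_node`` rounds of walks, one per node per round.

    Node order is shuffled each round; walks truncate early only when the
    walker reaches a node with no neighbors.  Deterministic per seed.
    """
    if network.n_nodes == 0:
        raise ValueError("cannot walk on an empty network")
    rng = np.random.default_rng(cfg.seed)
    if cfg.p == 1.0 and cfg.q == 1.0:
        walks = _uniform_walks(network, cfg, rng)
    else:
        walks = _biased_walks(network, cfg, rng)
    return WalkCorpus(walks=walks)


# ---------------------------------------------------------------------------
# skip-gram with negative sampling


def _corpus_pairs(token_ids: np.ndarray, walk_ids: np.ndarray, window: int,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(center, context) index pairs with word2vec shrunk windows."""
    n = token_ids.size
    b = rng.integers(1, window + 1, size=n)
    centers, contexts = [], []
    for d in range(1, window + 1):
        ok = b[: n - d] >= d
        same = walk_ids[: n - d] == walk_ids[d:]
        left = np.flatnonzero(ok & same)
        centers.append(left)          # center i, context i+d
        contexts.append(left + d)
        ok_r = b[d:] >= d
        right = np.flatnonzero(ok_r & same) + d
        centers.append(right)         # center i, context i-d
        contexts.append(right - d)
    c = token_ids[np.concatenate(centers)]
    o = token_ids[np.concatenate(contexts)]
    return c.astype(np.int32), o.astype(np.int32)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def train_embedding(corpus: WalkCorpus, dim: int = DEFAULT_DIM,
                    cfg: SkipGramConfig | None = None) -> EmbeddingTable:
    """Train SGNS on the walk corpus; one vector per node in the corpus."""
    if dim < 1:
        raise ValueError("embedding dimension must be >= 1")
    if not corpus.walks or not any(corpus.walks):
        raise ValueError("empty walk corpus")
    cfg = cfg or SkipGramConfig()
    rng = np.random.default_rng(cfg.seed)

    vocab = sorted({v for walk in corpus.walks for v in walk})
    index = {v: i for i, v in enumerate(vocab)}
    token_ids = np.fromiter(
        (index[v] for walk in corpus.walks for v in walk),
        dtype=np.int64)
    walk_ids = np.fromiter(
        (w for w, walk in enumerate(corpus.walks) for _ in walk),
        dtype=np.int64)

    centers, contexts = _corpus_pairs(token_ids, walk_ids, cfg.window, rng)
    n_pairs = centers.size
    if n_pairs == 0:
        # all walks are singletons; emit the random initial vectors
        W = (rng.random((len(vocab), dim)) - 0.5) / dim
        return EmbeddingTable(
            vectors={v: W[i].astype(float) for v, i in index.items()},
            dimension=dim)

    counts = np.bincount(token_ids, minlength=len(vocab)).astype(float)
    noise = counts ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    V = len(vocab)
    W = ((rng.random((V, dim)) - 0.5) / dim).astype(np.float32)
    C = np.zeros((V, dim), dtype=np.float32)
    K = cfg.negative_samples

    total = n_pairs * cfg.epochs
    done = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, cfg.batch_size):
            sel = order[lo: lo + cfg.batch_size]
            lr = max(cfg.min_lr,
                     cfg.initial_lr * (1.0 - done / total))
            c_idx, o_idx = centers[sel], contexts[sel]
            cv = W[c_idx]
            ov = C[o_idx]
            g_pos = (_sigmoid(np.sum(cv * ov, axis=1)) - 1.0) * lr
            grad_c = g_pos[:, None] * ov
            np.add.at(C, o_idx, -(g_pos[:, None] * cv))
            if K > 0:
                neg_idx = np.minimum(
                    np.searchsorted(noise_cdf, rng.random((sel.size, K))),
                    V - 1).astype(np.int32)
                nv = C[neg_idx]
                g_neg = _sigmoid(np.einsum("bkd,bd->bk", nv, cv)) * lr
                grad_c += np.einsum("bk,bkd->bd", g_neg, nv)
                np.add.at(C, neg_idx.ravel(),
                          -(g_neg[..., None] * cv[:, None, :]).reshape(-1, dim))
            np.add.at(W, c_idx, -grad_c)
            done += sel.size

    return EmbeddingTable(
        vectors={v: W[i].astype(float) for v, i in index.items()},
        dimension=dim)


def embed_network(network: PPINetwork,
                  walk_cfg: WalkConfig | None = None,
                  sg_cfg: SkipGramConfig | None = None,
                  dim: int = DEFAULT_DIM) -> EmbeddingTable:
    """Walks + SGNS; nodes absent from every walk get a zero vector."""
    if network.n_nodes == 0:
        return EmbeddingTable(vectors={}, dimension=dim)
    walk_cfg = walk_cfg or WalkConfig()
    sg_cfg = sg_cfg or SkipGramConfig()
    corpus = generate_walks(network, walk_cfg)
    table = train_embedding(corpus, dim=dim, cfg=sg_cfg)
    missing = [v for v in network.nodes if v not in table.vectors]
    if missing:
        logger.warning("%d nodes appear in no walk; assigning zero vectors",
                       len(missing))
        for v in missing:
            table.vectors[v] = np.zeros(dim)
    return table
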