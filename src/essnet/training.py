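"""Balanced epoch-sampling trainer for the imbalanced essentiality task.

Essential proteins (the minority class, M samples) are far outnumbered by
non-essential ones (the majority class, N samples).  Each training epoch
draws M majority samples uniformly without replacement, combines them with
all M minority samples into a balanced subset of size 2M, and runs one
optimisation pass over that subset.  Fresh independent draws across epochs
mean a given majority sample is missed in all k epochs with probability

    p_miss = (1 - M/N) ** k

so the epoch count k is chosen as the smallest integer with p_miss below a
threshold alpha (default 0.001): with high probability every majority
sample is seen at least once, while every individual epoch stays balanced.

Optimisation is Adam (lr 0.001, batch size 32) on the mean cross-entropy,
implemented here in NumPy.  A ``strategy="raw"`` mode trains on the full
(imbalanced) training split for the same number of epochs, for ablation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import AlignedDataset, SplitDataset
from .embedding import EmbeddingTable
from .model import ModelConfig, MultiScaleClassifier, build_images


def miss_probability(M: int, N: int, k: int) -> float:
    """(1 - M/N)^k: chance a given majority sample is never drawn."""
    if not 1 <= M <= N:
        raise ValueError(f"need 1 <= M <= N, got M={M}, N={N}")
    if k < 0:
        raise ValueError("k must be >= 0")
    return (1.0 - M / N) ** k


def solve_epochs(M: int, N: int, alpha: float = 0.001) -> int:
    """Minimal k >= 1 with (1 - M/N)^k < alpha; k = 1 when M = N."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if not 1 <= M <= N:
        raise ValueError(f"need 1 <= M <= N, got M={M}, N={N}")
    if M == N:
        return 1
    base = 1.0 - M / N
    k = max(1, math.ceil(math.log(alpha) / math.log(base)))
    # guard against floating-point edge cases of the closed form
    while miss_probability(M, N, k) >= alpha:
        k += 1
    while k > 1 and miss_probability(M, N, k - 1) < alpha:
        k -= 1
    return k


@dataclass(frozen=True)
class SamplingPlan:
    """Balanced-sampling schedule derived from the training split."""

    M: int
    N: int
    alpha: float = 0.001
    k: int = field(default=0)

    def __post_init__(self) -> None:
        if self.k == 0:
            object.__setattr__(self, "k", solve_epochs(self.M, self.N,
                                                       self.alpha))
        if not 1 <= self.M <= self.N:
            raise ValueError("need 1 <= M <= N")
        if self.M < self.N:
            if miss_probability(self.M, self.N, self.k) >= self.alpha:
                raise ValueError("k too small for alpha")
            if self.k > 1 and miss_probability(self.M, self.N,
                                               self.k - 1) < self.alpha:
                raise ValueError("k not minimal")

    @staticmethod
    def from_counts(n_minority: int, n_majority: int,
                    alpha: float = 0.001) -> "SamplingPlan":
        return SamplingPlan(M=n_minority, N=n_majority, alpha=alpha)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 0.001
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class EpochRecord:
    epoch: int
    sampled_majority_ids: tuple[str, ...]
    mean_loss: float


@dataclass
class TrainingHistory:
    records: list[EpochRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def losses(self) -> list[float]:
        return [r.mean_loss for r in self.records]


def epoch_subset(minority_ids: list[str], majority_ids: list[str],
                 epoch_seed: int) -> list[str]:
    """One balanced epoch subset: all minority ids + M majority ids, shuffled.

    Majority ids are drawn uniformly without replacement; the draw is a
    fresh function of ``epoch_seed`` only, so repeated calls with the same
    seed reproduce the subset and different seeds are independent draws.
    """
    minority_ids = list(minority_ids)
    majority_ids = list(majority_ids)
    M = len(minority_ids)
    if M < 1 or len(majority_ids) < M:
        raise ValueError("need 1 <= |minority| <= |majority|")
    rng = np.random.default_rng(epoch_seed)
    picked = rng.choice(len(majority_ids), size=M, replace=False)
    subset = minority_ids + [majority_ids[i] for i in picked]
    rng.shuffle(subset)
    return subset


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for key, g in grads.items():
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
            params[key] -= self.lr * (self.m[key] / b1t) / (
                np.sqrt(self.v[key] / b2t) + self.eps)


def train(dataset: AlignedDataset, split: SplitDataset,
          embeddings: EmbeddingTable,
          model_cfg: ModelConfig | None = None,
          train_cfg: TrainConfig | None = None,
          plan: SamplingPlan | None = None,
          strategy: str = "balanced",
          features: dict[str, np.ndarray] | None = None,
          ) -> tuple[MultiScaleClassifier, TrainingHistory]:
    """Train the classifier on the training split.

    ``strategy="balanced"`` (default) runs the balanced epoch-sampling
    scheme for ``plan.k`` epochs; ``strategy="raw"`` runs the same number
    of epochs over the full imbalanced training split.  ``features`` may
    override the per-protein embedding vectors (e.g. a centrality scalar
    for ablations); by default vectors come from ``embeddings``.
    Deterministic end-to-end for fixed seeds.
    """
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    if strategy not in ("balanced", "raw"):
        raise ValueError(f"unknown strategy {strategy!r}")

    train_ids = list(split.train_ids)
    minority = [v for v in train_ids if dataset.labels[v] == 1]
    majority = [v for v in train_ids if dataset.labels[v] == 0]
    if not minority:
        raise ValueError("no positive samples in the training split")
    if plan is None:
        plan = SamplingPlan.from_counts(len(minority), len(majority))

    def vectors_for(ids: list[str]) -> np.ndarray:
        if features is not None:
            return np.stack([features[v] for v in ids])
        return embeddings.as_matrix(ids)

    # cache per-protein tensors once
    all_images = build_images(dataset, train_ids)
    all_vectors = vectors_for(train_ids)
    row = {v: i for i, v in enumerate(train_ids)}

    model = MultiScaleClassifier(config=model_cfg, seed=train_cfg.seed)
    opt = _Adam(model.params, lr=train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.seed + 1)
    history = TrainingHistory()

    for epoch in range(1, plan.k + 1):
        if strategy == "balanced":
            epoch_seed = (train_cfg.seed * 1_000_003 + epoch) % (2 ** 31)
            subset = epoch_subset(minority, majority, epoch_seed)
            sampled = tuple(v for v in subset if dataset.labels[v] == 0)
        else:
            subset = list(train_ids)
            rng.shuffle(subset)
            sampled = tuple(v for v in subset if dataset.labels[v] == 0)
        idx = np.array([row[v] for v in subset])
        labels = np.array([dataset.labels[v] for v in subset])
        losses = []
        for lo in range(0, len(subset), train_cfg.batch_size):
            sel = idx[lo: lo + train_cfg.batch_size]
            y = labels[lo: lo + train_cfg.batch_size]
            loss, grads = model.loss_and_grads(
                all_images[sel], all_vectors[sel], y, dropout_rng=rng)
            opt.step(model.params, grads)
            losses.append(loss)
        history.records.append(
            EpochRecord(epoch=epoch, sampled_majority_ids=sampled,
                        mean_loss=float(np.mean(losses))))
    return model, history
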