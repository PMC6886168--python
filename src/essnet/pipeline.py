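"""High-level modelling interface: build, fit, inspect.

`EssentialityModel` wraps an aligned dataset (network + expression +
labels) the way statistical modelling packages wrap a design matrix:
construct it from files or from the synthetic generator, call ``fit()``,
and get back an `EssentialityResults` object carrying the trained
classifier, the held-out scores, the six assessment metrics, the
sampling plan actually used, and a ``summary()`` table.

Typical use::

    from essnet import EssentialityModel, SyntheticSpec

    model = EssentialityModel.from_synthetic(SyntheticSpec())
    res = model.fit(seed=0)
    print(res.summary())

Ablations hang off the same object: ``fit(strategy="raw")`` trains on the
imbalanced split without balanced epoch sampling, and
``fit(features="DC")`` replaces the node2vec vectors with a single
degree-centrality scalar per protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .centrality import ALL_METHODS, ScoreTable, compute_centrality
from .data import (AlignedDataset, SplitDataset, align, read_edge_list,
                   read_expression, read_labels, stratified_split)
from .embedding import (EmbeddingTable, SkipGramConfig, WalkConfig,
                        embed_network)
from .evaluation import MetricsReport, full_report, topk_protocol
from .model import ModelConfig, MultiScaleClassifier
from .synthetic import SyntheticSpec, generate_dataset
from .training import SamplingPlan, TrainConfig, TrainingHistory, train


def centrality_features(dataset: AlignedDataset,
                        kind: str = "DC") -> dict[str, np.ndarray]:
    """Per-protein 1-vector of a standardised centrality index.

    Used to ablate the embedding branch: the 64-d node2vec vector is
    replaced by a single scalar, z-scored across proteins so its scale is
    comparable to the learned features.
    """
    table = compute_centrality(dataset.network, kind,
                               expr=dataset.expression)
    vals = np.array([table[v] for v in dataset.network.nodes], dtype=float)
    sd = vals.std()
    vals = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
    return {v: np.array([x]) for v, x in zip(dataset.network.nodes, vals)}


@dataclass
class EssentialityResults:
    """Everything produced by one `EssentialityModel.fit` call."""

    classifier: MultiScaleClassifier
    history: TrainingHistory
    split: SplitDataset
    plan: SamplingPlan
    embeddings: EmbeddingTable
    train_scores: ScoreTable
    test_scores: ScoreTable
    metrics: MetricsReport
    strategy: str
    feature_kind: str
    _dataset: AlignedDataset = field(repr=False, default=None)

    def predict(self, ids: list[str] | None = None,
                features: dict[str, np.ndarray] | None = None) -> ScoreTable:
        """Essential-class probabilities for ``ids`` (default: all nodes)."""
        if self.feature_kind != "embedding" and features is None:
            features = centrality_features(self._dataset, self.feature_kind)
        if features is not None:
            ids = list(ids) if ids is not None \
                else list(self._dataset.network.nodes)
            from .model import build_images

            images = build_images(self._dataset, ids)
            vecs = np.stack([features[v] for v in ids])
            probs = self.classifier.predict_proba(images, vecs)
            return ScoreTable(scores={v: float(p)
                                      for v, p in zip(ids, probs[:, 1])},
                              method_name="multiscale-cnn")
        return self.classifier.score(self._dataset, self.embeddings, ids=ids)

    def summary(self) -> str:
        d = self._dataset
        n_pos = sum(d.labels.values())
        lines = [
            "Essential-protein prediction results",
            "=" * 52,
            f"Nodes: {d.network.n_nodes}    Edges: {d.network.n_edges}    "
            f"Essential: {n_pos} ({n_pos / d.network.n_nodes:.1%})",
            f"Split: {len(self.split.train_ids)} train / "
            f"{len(self.split.test_ids)} test "
            f"(fraction {self.split.split_fraction}, seed {self.split.seed})",
            f"Sampling plan: M={self.plan.M}  N={self.plan.N}  "
            f"alpha={self.plan.alpha}  k={self.plan.k} epochs",
            f"Strategy: {self.strategy}    Features: {self.feature_kind}",
            f"Final-epoch mean loss: {self.history.losses[-1]:.4f}",
            "-" * 52,
            "Held-out test metrics",
        ]
        m = self.metrics
        for name, val in [("accuracy", m.accuracy), ("precision", m.precision),
                          ("recall", m.recall), ("F-measure", m.f_measure),
                          ("AUC", m.auc), ("AP", m.ap)]:
            lines.append(f"  {name:<12s} {val:.4f}")
        if m.undefined:
            lines.append(f"  (zero-denominator, reported as 0: "
                         f"{', '.join(m.undefined)})")
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.classifier.save(outdir / "checkpoint.npz")
        self.test_scores.to_tsv(outdir / "test_scores.tsv")
        self.metrics.to_json(outdir / "metrics.json")
        with open(outdir / "history.log", "w") as fh:
            for rec in self.history.records:
                import hashlib

                digest = hashlib.sha256(
                    ",".join(rec.sampled_majority_ids).encode()).hexdigest()[:12]
                fh.write(f"epoch={rec.epoch}\tloss={rec.mean_loss:.6f}"
                         f"\tsubset_sha={digest}\n")


class EssentialityModel:
    """Essentiality predictor bound to one aligned dataset.

    Parameters mirror the pipeline stages: walk/skip-gram configs for the
    embedding, the architecture config, the optimiser config, the balanced
    sampling threshold ``alpha`` and the train fraction.  ``fit`` is
    deterministic for a fixed seed.
    """

    def __init__(self, dataset: AlignedDataset,
                 walk_cfg: WalkConfig | None = None,
                 sg_cfg: SkipGramConfig | None = None,
                 model_cfg: ModelConfig | None = None,
                 train_cfg: TrainConfig | None = None,
                 alpha: float = 0.001,
                 split_fraction: float = 0.8):
        self.dataset = dataset
        self.walk_cfg = walk_cfg
        self.sg_cfg = sg_cfg
        self.model_cfg = model_cfg or ModelConfig()
        self.train_cfg = train_cfg
        self.alpha = alpha
        self.split_fraction = split_fraction
        self._embeddings: EmbeddingTable | None = None

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_files(cls, network_path, expression_path, labels_path,
                   **kwargs) -> "EssentialityModel":
        dataset = align(read_edge_list(network_path),
                        read_expression(expression_path),
                        read_labels(labels_path))
        return cls(dataset, **kwargs)

    @classmethod
    def from_synthetic(cls, spec: SyntheticSpec | None = None,
                       **kwargs) -> "EssentialityModel":
        return cls(generate_dataset(spec or SyntheticSpec()), **kwargs)

    # -- stages -----------------------------------------------------------

    def embed(self, seed: int | None = None,
              force: bool = False) -> EmbeddingTable:
        """node2vec embedding of the network (cached across fits)."""
        if self._embeddings is None or force:
            walk_cfg = self.walk_cfg or WalkConfig(
                seed=seed if seed is not None else 0)
            sg_cfg = self.sg_cfg or SkipGramConfig(
                seed=seed if seed is not None else 0)
            self._embeddings = embed_network(
                self.dataset.network, walk_cfg, sg_cfg,
                dim=self.model_cfg.embedding_dim)
        return self._embeddings

    def set_embeddings(self, table: EmbeddingTable) -> None:
        self._embeddings = table

    def fit(self, seed: int = 0, strategy: str = "balanced",
            features: str = "embedding",
            threshold: float = 0.5) -> EssentialityResults:
        """Split, embed, plan, train, evaluate on the held-out split.

        ``features`` is either ``"embedding"`` (node2vec vectors) or the
        name of a centrality index whose standardised scalar replaces the
        vector (ablation mode).
        """
        split = stratified_split(self.dataset, self.split_fraction, seed=seed)
        minority = [v for v in split.train_ids if self.dataset.labels[v] == 1]
        majority = [v for v in split.train_ids if self.dataset.labels[v] == 0]
        plan = SamplingPlan.from_counts(len(minority), len(majority),
                                        alpha=self.alpha)
        train_cfg = self.train_cfg or TrainConfig(seed=seed)
        if train_cfg.seed != seed:
            train_cfg = TrainConfig(batch_size=train_cfg.batch_size,
                                    learning_rate=train_cfg.learning_rate,
                                    optimizer=train_cfg.optimizer, seed=seed)

        feature_map = None
        model_cfg = self.model_cfg
        if features == "embedding":
            embeddings = self.embed(seed=seed)
        else:
            if features not in ALL_METHODS:
                raise ValueError(f"unknown feature source {features!r}")
            feature_map = centrality_features(self.dataset, features)
            model_cfg = ModelConfig(
                kernel_sizes=model_cfg.kernel_sizes,
                channels_per_scale=model_cfg.channels_per_scale,
                fc_units=model_cfg.fc_units,
                dropout_rate=model_cfg.dropout_rate,
                pool_window=model_cfg.pool_window,
                embedding_dim=1)
            embeddings = EmbeddingTable(vectors={}, dimension=1)

        classifier, history = train(self.dataset, split, embeddings,
                                    model_cfg=model_cfg, train_cfg=train_cfg,
                                    plan=plan, strategy=strategy,
                                    features=feature_map)

        def score_ids(ids):
            if feature_map is not None:
                from .model import build_images

                images = build_images(self.dataset, list(ids))
                vecs = np.stack([feature_map[v] for v in ids])
                probs = classifier.predict_proba(images, vecs)
                return ScoreTable(scores={v: float(p) for v, p
                                          in zip(ids, probs[:, 1])},
                                  method_name="multiscale-cnn")
            return classifier.score(self.dataset, embeddings, ids=list(ids))

        test_scores = score_ids(split.test_ids)
        train_scores = score_ids(split.train_ids)
        test_labels = {v: self.dataset.labels[v] for v in split.test_ids}
        metrics = full_report(test_scores, test_labels, threshold=threshold)
        return EssentialityResults(
            classifier=classifier, history=history, split=split, plan=plan,
            embeddings=embeddings, train_scores=train_scores,
            test_scores=test_scores, metrics=metrics, strategy=strategy,
            feature_kind=features, _dataset=self.dataset)

    # -- baselines --------------------------------------------------------

    def rank_centralities(self, methods: list[str] | None = None,
                          K: int | None = None,
                          ids: list[str] | None = None,
                          ) -> dict[str, tuple[ScoreTable, MetricsReport]]:
        """The top-K candidate protocol for the centrality baselines.

        Scores every protein with each index, takes the K highest-scoring
        as candidate essentials (K defaults to the true essential count)
        and reports accuracy/precision/recall/F for each method.
        """
        methods = list(methods) if methods else list(ALL_METHODS)
        ids = list(ids) if ids is not None else list(self.dataset.network.nodes)
        labels = {v: self.dataset.labels[v] for v in ids}
        if K is None:
            K = max(1, sum(labels.values()))
        out: dict[str, tuple[ScoreTable, MetricsReport]] = {}
        for kind in methods:
            table = compute_centrality(self.dataset.network, kind,
                                       expr=self.dataset.expression)
            if ids is not None:
                table = ScoreTable(scores={v: table[v] for v in ids},
                                   method_name=kind)
            out[kind] = (table, topk_protocol(table, labels, K))
        return out
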