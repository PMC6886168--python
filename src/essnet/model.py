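"""Multi-scale convolutional classifier over expression images + embeddings.

Each protein contributes two feature sources:

* its 36-point expression profile, reshaped cycle-major into a 1x3x12
  "image" (rows = metabolic cycles, columns = time points within a cycle),
  passed through parallel 2-D convolutions with square kernels of sizes
  1, 3 and 5 (zero same-padding, 8 output channels each), concatenated
  along channels (24x3x12) and max-pooled with window (1,2), stride (1,2)
  down to 24x3x6 = 432 values;
* a 64-component network-embedding vector.

The 432 + 64 = 496 concatenated features feed a 312-unit fully connected
ReLU layer with dropout 0.1, then a 2-unit softmax output layer giving
(p_nonessential, p_essential).

Everything here is plain NumPy: forward pass, analytic backward pass and
Glorot-uniform initialisation.  Inference is deterministic (dropout only
applies when a training RNG is supplied) and invariant to batch
composition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .data import AlignedDataset, N_TIMEPOINTS
from .embedding import EmbeddingTable
from .centrality import ScoreTable

IMAGE_SHAPE = (1, 3, 12)  # channel x metabolic cycles x time points


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (defaults follow the reference setup)."""

    kernel_sizes: tuple[int, ...] = (1, 3, 5)
    channels_per_scale: int = 8
    fc_units: int = 312
    dropout_rate: float = 0.1
    pool_window: tuple[int, int] = (1, 2)
    embedding_dim: int = 64

    def __post_init__(self) -> None:
        if any(k < 1 for k in self.kernel_sizes):
            raise ValueError("kernel sizes must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if min(self.channels_per_scale, self.fc_units, self.embedding_dim) < 1:
            raise ValueError("all layer sizes must be positive")

    @property
    def pooled_shape(self) -> tuple[int, int, int]:
        pr, pc = self.pool_window
        c = self.channels_per_scale * len(self.kernel_sizes)
        return (c, IMAGE_SHAPE[1] // pr, IMAGE_SHAPE[2] // pc)

    @property
    def conv_feature_len(self) -> int:
        c, h, w = self.pooled_shape
        return c * h * w

    @property
    def feature_len(self) -> int:
        """Length of the concatenated feature vector (496 at defaults)."""
        return self.conv_feature_len + self.embedding_dim


def profile_to_image(row: np.ndarray) -> np.ndarray:
    """Reshape a 36-vector cycle-major into the (1, 3, 12) image."""
    row = np.asarray(row, dtype=float)
    if row.shape != (N_TIMEPOINTS,):
        raise ValueError(f"expected a {N_TIMEPOINTS}-vector, got {row.shape}")
    return row.reshape(IMAGE_SHAPE)


def image_to_profile(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.shape != IMAGE_SHAPE:
        raise ValueError(f"expected shape {IMAGE_SHAPE}, got {image.shape}")
    return image.reshape(N_TIMEPOINTS)


def zscore_profile(row: np.ndarray) -> np.ndarray:
    """Per-protein standardisation; constant rows map to zeros."""
    row = np.asarray(row, dtype=float)
    sd = row.std()
    if sd == 0.0:
        return np.zeros_like(row)
    return (row - row.mean()) / sd


def build_images(dataset: AlignedDataset, ids: list[str],
                 normalize: bool = True) -> np.ndarray:
    """Stack (B, 1, 3, 12) images for ``ids`` from the aligned expression."""
    out = np.empty((len(ids),) + IMAGE_SHAPE)
    for i, key in enumerate(ids):
        row = dataset.expression[key]
        if normalize:
            row = zscore_profile(row)
        out[i] = profile_to_image(row)
    return out


# ---------------------------------------------------------------------------
# layer primitives (forward + backward)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B, C*k*k, H*W) with zero same-padding."""
    B, C, H, W = x.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((B, C * k * k, H * W), dtype=x.dtype)
    idx = 0
    for c in range(C):
        for i in range(k):
            for j in range(k):
                cols[:, idx, :] = xp[:, c, i:i + H, j:j + W].reshape(B, H * W)
                idx += 1
    return cols


def conv2d_same(x: np.ndarray, weight: np.ndarray, bias: np.ndarray):
    """2-D convolution with zero same-padding.

    ``weight`` has shape (out_channels, in_channels, k, k).  Returns the
    output map and a cache for the backward pass.
    """
    out_ch, in_ch, k, _ = weight.shape
    B, C, H, W = x.shape
    cols = _im2col(x, k)
    Wr = weight.reshape(out_ch, in_ch * k * k)
    out = np.einsum("of,bfp->bop", Wr, cols) + bias[None, :, None]
    return out.reshape(B, out_ch, H, W), (cols, x.shape, weight.shape)


def maxpool(x: np.ndarray, window: tuple[int, int]):
    """Non-overlapping max pooling (stride = window); trailing rest dropped."""
    pr, pc = window
    B, C, H, W = x.shape
    H2, W2 = H // pr, W // pc
    xt = x[:, :, :H2 * pr, :W2 * pc].reshape(B, C, H2, pr, W2, pc)
    out = xt.max(axis=(3, 5))
    mask = (xt == out[:, :, :, None, :, None])
    ties = mask.sum(axis=(3, 5), keepdims=True)
    return out, (mask, ties, x.shape, window)


def maxpool_backward(dout: np.ndarray, cache) -> np.ndarray:
    mask, ties, x_shape, (pr, pc) = cache
    B, C, H, W = x_shape
    H2, W2 = H // pr, W // pc
    dx = np.zeros(x_shape, dtype=dout.dtype)
    spread = mask * (dout[:, :, :, None, :, None] / ties)
    dx[:, :, :H2 * pr, :W2 * pc] = spread.reshape(B, C, H2 * pr, W2 * pc)
    return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# the classifier


class MultiScaleClassifier:
    """Multi-scale CNN + embedding concatenation + 2-way softmax head.

    Parameters are a flat name -> array dict; ``loss_and_grads`` returns
    analytic gradients for every parameter, verified against finite
    differences in the test suite.
    """

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        self.params: dict[str, np.ndarray] = {}
        self._init_params(np.random.default_rng(seed))

    def _glorot(self, rng, shape, fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape)

    def _init_params(self, rng) -> None:
        cfg = self.config
        ch = cfg.channels_per_scale
        for k in cfg.kernel_sizes:
            fan_in, fan_out = 1 * k * k, ch * k * k
            self.params[f"conv{k}_W"] = self._glorot(
                rng, (ch, 1, k, k), fan_in, fan_out)
            self.params[f"conv{k}_b"] = np.zeros(ch)
        n_feat = cfg.feature_len
        self.params["fc1_W"] = self._glorot(
            rng, (n_feat, cfg.fc_units), n_feat, cfg.fc_units)
        self.params["fc1_b"] = np.zeros(cfg.fc_units)
        self.params["fc2_W"] = self._glorot(
            rng, (cfg.fc_units, 2), cfg.fc_units, 2)
        self.params["fc2_b"] = np.zeros(2)

    # -- forward ----------------------------------------------------------

    def multiscale_features(self, images: np.ndarray,
                            with_cache: bool = False):
        """Conv at every scale, channel concat, max-pool, flatten."""
        cfg = self.config
        maps, conv_caches = [], []
        for k in cfg.kernel_sizes:
            m, cache = conv2d_same(images, self.params[f"conv{k}_W"],
                                   self.params[f"conv{k}_b"])
            maps.append(m)
            conv_caches.append(cache)
        stacked = np.concatenate(maps, axis=1)
        pooled, pool_cache = maxpool(stacked, cfg.pool_window)
        flat = pooled.reshape(images.shape[0], -1)
        if with_cache:
            return flat, (conv_caches, pool_cache, stacked.shape)
        return flat

    def _forward(self, images, embeddings, dropout_rng=None):
        cfg = self.config
        if images.ndim != 4 or images.shape[1:] != IMAGE_SHAPE:
            raise ValueError(
                f"image stage: expected (B,)+{IMAGE_SHAPE}, got {images.shape}")
        if embeddings.ndim != 2 or embeddings.shape[1] != cfg.embedding_dim:
            raise ValueError(
                f"embedding stage: expected (B, {cfg.embedding_dim}), "
                f"got {embeddings.shape}")
        if images.shape[0] != embeddings.shape[0]:
            raise ValueError("concat stage: batch sizes differ")
        conv_flat, feat_cache = self.multiscale_features(images, with_cache=True)
        features = np.concatenate([conv_flat, embeddings], axis=1)
        pre1 = features @ self.params["fc1_W"] + self.params["fc1_b"]
        hidden = np.maximum(pre1, 0.0)
        if dropout_rng is not None and cfg.dropout_rate > 0.0:
            keep = 1.0 - cfg.dropout_rate
            mask = (dropout_rng.random(hidden.shape) < keep) / keep
        else:
            mask = None
        dropped = hidden if mask is None else hidden * mask
        logits = dropped @ self.params["fc2_W"] + self.params["fc2_b"]
        probs = softmax(logits)
        cache = (feat_cache, features, pre1, dropped, mask, probs,
                 images.shape)
        return probs, cache

    def predict_proba(self, images: np.ndarray,
                      embeddings: np.ndarray) -> np.ndarray:
        """(B, 2) class probabilities; deterministic (no dropout)."""
        probs, _ = self._forward(np.asarray(images, dtype=float),
                                 np.asarray(embeddings, dtype=float))
        return probs

    def forward_single(self, embedding: np.ndarray,
                       image: np.ndarray) -> tuple[float, float]:
        """(p_nonessential, p_essential) for one protein."""
        probs = self.predict_proba(image[None], np.asarray(embedding)[None])
        return float(probs[0, 0]), float(probs[0, 1])

    # -- loss / gradients -------------------------------------------------

    def loss_and_grads(self, images, embeddings, labels, dropout_rng=None):
        """Mean cross-entropy and its gradient w.r.t. every parameter."""
        cfg = self.config
        labels = np.asarray(labels, dtype=int)
        probs, cache = self._forward(np.asarray(images, dtype=float),
                                     np.asarray(embeddings, dtype=float),
                                     dropout_rng=dropout_rng)
        feat_cache, features, pre1, dropped, mask, _, img_shape = cache
        conv_caches, pool_cache, _ = feat_cache
        B = labels.size
        eps = 1e-12
        loss = -float(np.mean(np.log(probs[np.arange(B), labels] + eps)))

        grads: dict[str, np.ndarray] = {}
        dlogits = probs.copy()
        dlogits[np.arange(B), labels] -= 1.0
        dlogits /= B
        grads["fc2_W"] = dropped.T @ dlogits
        grads["fc2_b"] = dlogits.sum(axis=0)
        ddropped = dlogits @ self.params["fc2_W"].T
        dhidden = ddropped if mask is None else ddropped * mask
        dpre1 = dhidden * (pre1 > 0.0)
        grads["fc1_W"] = features.T @ dpre1
        grads["fc1_b"] = dpre1.sum(axis=0)
        dfeatures = dpre1 @ self.params["fc1_W"].T
        dconv_flat = dfeatures[:, :cfg.conv_feature_len]
        dpooled = dconv_flat.reshape((img_shape[0],) + cfg.pooled_shape)
        dstacked = maxpool_backward(dpooled, pool_cache)
        ch = cfg.channels_per_scale
        for s, k in enumerate(cfg.kernel_sizes):
            dmap = dstacked[:, s * ch:(s + 1) * ch]
            cols, x_shape, w_shape = conv_caches[s]
            dflat = dmap.reshape(img_shape[0], ch, -1)
            grads[f"conv{k}_W"] = np.einsum("bop,bfp->of", dflat,
                                            cols).reshape(w_shape)
            grads[f"conv{k}_b"] = dflat.sum(axis=(0, 2))
        return loss, grads

    # -- scoring / persistence -------------------------------------------

    def score(self, dataset: AlignedDataset, embeddings: EmbeddingTable,
              ids: list[str] | None = None,
              normalize: bool = True) -> ScoreTable:
        """Essential-class probability per protein.

        Proteins without an embedding vector are scored with a zero vector
        (and counted in the log).
        """
        ids = list(ids) if ids is not None else list(dataset.network.nodes)
        images = build_images(dataset, ids, normalize=normalize)
        emb = embeddings.as_matrix(ids)
        probs = self.predict_proba(images, emb)
        return ScoreTable(scores={key: float(p)
                                  for key, p in zip(ids, probs[:, 1])},
                          method_name="multiscale-cnn")

    def save(self, path: str | Path) -> None:
        """Checkpoint: NumPy .npz weights + JSON config sidecar."""
        path = Path(path)
        np.savez(path, **self.params)
        sidecar = path.with_suffix(".json")
        cfg = asdict(self.config)
        cfg["kernel_sizes"] = list(cfg["kernel_sizes"])
        cfg["pool_window"] = list(cfg["pool_window"])
        sidecar.write_text(json.dumps(cfg, indent=2))

    @staticmethod
    def load(path: str | Path) -> "MultiScaleClassifier":
        path = Path(path)
        cfg_raw = json.loads(path.with_suffix(".json").read_text())
        cfg_raw["kernel_sizes"] = tuple(cfg_raw["kernel_sizes"])
        cfg_raw["pool_window"] = tuple(cfg_raw["pool_window"])
        model = MultiScaleClassifier(config=ModelConfig(**cfg_raw))
        with np.load(path if path.suffix == ".npz"
                     else path.with_suffix(".npz")) as data:
            model.params = {k: data[k] for k in data.files}
        return model
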