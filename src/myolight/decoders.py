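"""The three decoder families: Random Forest, CNN, and TMC-ViT.

Each family exists in a 5-way classification form (softmax head) and a
regression form (single linear output):

- **RF** — a 150-tree random forest (scikit-learn) over flattened windows
  or feature vectors.
- **CNN** — three convolutional blocks (convolution, batch normalization,
  dropout), four fully-connected layers, and the task head.
- **TMC-ViT** — temporal multi-channel vision transformer: two
  convolution + max-pool stages embed the raw multichannel window, 2x2
  patches are linearly projected with a learned position embedding, and a
  transformer encoder of four multi-head-attention layers (four heads each)
  feeds a pooled-token head.

Windows are treated as (time x channel) images so convolution kernels and
patches mix temporal and cross-channel structure.  LMG models consume raw
windows; EMG models consume the 8-feature table (reshaped to channel x
feature for the 2-D operators).  Training is seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from . import _nn
from .errors import ConfigError, ContractError
from .features import FeatureTable
from .preprocessing import WindowSet

FAMILIES = ("rf", "cnn", "tmcvit")
TASKS = ("classification", "regression")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters of one decoder.

    Defaults are the full-size configuration; :meth:`reduced` returns a
    desk-scale preset with the same topology (3 conv blocks + 4 FC; 2 conv
    stages + 4 attention layers x 4 heads) but narrower layers, sized to
    train on a single CPU in minutes.
    """

    family: str
    task: str = "classification"
    rf_trees: int = 150
    cnn_filters: tuple[int, ...] = (32, 64, 128)
    cnn_kernel: int = 3
    cnn_dropout: float = 0.3
    cnn_fc: tuple[int, ...] = (256, 128, 64, 32)
    vit_conv: tuple[int, ...] = (16, 32)
    patch_size: int = 2
    n_attention_layers: int = 4
    n_heads: int = 4
    embed_dim: int = 64
    mlp_dim: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown family {self.family!r}; one of {FAMILIES}")
        if self.task not in TASKS:
            raise ConfigError(f"unknown task {self.task!r}; one of {TASKS}")
        if self.rf_trees < 1:
            raise ConfigError("rf_trees must be >= 1")
        if self.embed_dim % self.n_heads:
            raise ConfigError("embed_dim must be divisible by n_heads")

    @classmethod
    def reduced(cls, family: str, task: str = "classification", seed: int = 0,
                **kwargs) -> "ModelSpec":
        return cls(
            family=family, task=task, seed=seed,
            cnn_filters=(8, 16, 16), cnn_fc=(64, 32, 16, 8),
            vit_conv=(8, 16), embed_dim=32, mlp_dim=64,
            **kwargs,
        )


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; the loss follows the task (cross-entropy for
    classification, MSE for regression).

    ``max_train_windows`` caps the per-fit training set by a seeded
    (class-stratified for classification) subsample — windowing at a 20 ms
    stride yields tens of thousands of heavily overlapping windows, far more
    than the decoders need to converge.
    """

    lr: float = 1e-3
    epochs: int = 50
    batch_size: int = 64
    patience: int = 10
    min_delta: float = 1e-4
    seed: int = 0
    max_train_windows: int | None = None

    @classmethod
    def reduced(cls, seed: int = 0, **kwargs) -> "TrainConfig":
        kwargs.setdefault("epochs", 12)
        kwargs.setdefault("patience", 3)
        kwargs.setdefault("max_train_windows", 1500)
        return cls(seed=seed, **kwargs)


def _as_array(x) -> np.ndarray:
    if isinstance(x, WindowSet):
        return x.windows
    if isinstance(x, FeatureTable):
        return x.values
    return np.asarray(x)


def _as_image(x: np.ndarray) -> np.ndarray:
    """[N,L,C] windows -> NHWC; [N,F] feature rows -> channel x feature maps."""
    if x.ndim == 3:
        return x[..., None]
    if x.ndim == 2:
        n, f = x.shape
        if f % 8 == 0 and f > 8:
            return x.reshape(n, f // 8, 8, 1)
        return x.reshape(n, f, 1, 1)
    raise ContractError(f"cannot interpret input of ndim {x.ndim}")


def _subsample(rng, y, cap: int, stratify: bool) -> np.ndarray:
    n = y.shape[0]
    if cap is None or n <= cap:
        return np.arange(n)
    if not stratify:
        return np.sort(rng.choice(n, size=cap, replace=False))
    classes, counts = np.unique(y, return_counts=True)
    per = max(1, cap // len(classes))
    keep = [
        rng.choice(np.flatnonzero(y == c), size=min(per, cnt), replace=False)
        for c, cnt in zip(classes, counts)
    ]
    return np.sort(np.concatenate(keep))


class Decoder:
    """Common fit/predict surface of the three families."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec

    # subclasses implement _fit(X2, y_enc, cfg) and _raw_predict(X2)

    def fit(self, X, y, cfg: TrainConfig | None = None) -> "Decoder":
        cfg = cfg or TrainConfig(seed=self.spec.seed)
        x = _as_array(X)
        y = np.asarray(y)
        if x.shape[0] != y.shape[0]:
            raise ContractError(
                f"{x.shape[0]} inputs vs {y.shape[0]} targets"
            )
        if self.spec.task == "classification":
            self.classes_ = np.unique(y)
            y_enc = np.searchsorted(self.classes_, y)
        else:
            y_enc = y.astype(float)
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, self.spec.seed]))
        idx = _subsample(rng, y_enc, cfg.max_train_windows,
                         stratify=self.spec.task == "classification")
        self._fit(x[idx], y_enc[idx], cfg, rng)
        return self

    def predict(self, X):
        x = _as_array(X)
        if self.spec.task == "classification":
            if x.shape[0] == 0:
                return self.classes_[:0]
            return self.classes_[np.argmax(self.predict_proba(x), axis=1)]
        if x.shape[0] == 0:
            return np.empty(0)
        return self._raw_predict(x)

    def predict_proba(self, X):
        if self.spec.task != "classification":
            raise ContractError("predict_proba is classification-only")
        x = _as_array(X)
        if x.shape[0] == 0:
            return np.empty((0, len(self.classes_)))
        return self._raw_predict(x)


class RandomForestDecoder(Decoder):
    """Random forest over flattened inputs (scikit-learn backend)."""

    def _fit(self, x, y, cfg, rng):
        cls = (RandomForestClassifier if self.spec.task == "classification"
               else RandomForestRegressor)
        self.model_ = cls(
            n_estimators=self.spec.rf_trees,
            random_state=int(rng.integers(2**31 - 1)),
        )
        self.model_.fit(x.reshape(x.shape[0], -1), y)
        self.history_ = []

    def _raw_predict(self, x):
        x2 = x.reshape(x.shape[0], -1)
        if x2.shape[0] == 0:
            k = len(self.classes_) if self.spec.task == "classification" else 0
            return np.empty((0, k)) if k else np.empty(0)
        if self.spec.task == "classification":
            return self.model_.predict_proba(x2)
        return self.model_.predict(x2)


class _NeuralDecoder(Decoder):
    """Shared training/prediction plumbing of the CNN and TMC-ViT."""

    def build_net(self, input_shape: tuple[int, int, int], n_out: int,
                  rng: np.random.Generator | None = None) -> _nn.Network:
        rng = rng or np.random.default_rng(self.spec.seed)
        layers = self._architecture(input_shape, n_out, rng)
        loss = "ce" if self.spec.task == "classification" else "mse"
        return _nn.Network(layers, loss, rng)

    def _fit(self, x, y, cfg, rng):
        img = _as_image(x)
        n_out = len(self.classes_) if self.spec.task == "classification" else 1
        self.net_ = self.build_net(img.shape[1:], n_out, rng)
        self.history_ = self.net_.fit(
            img, y, epochs=cfg.epochs, batch_size=cfg.batch_size, lr=cfg.lr,
            patience=cfg.patience, min_delta=cfg.min_delta,
        )

    def _raw_predict(self, x):
        out = self.net_.predict(_as_image(x))
        if self.spec.task == "classification":
            return _nn.softmax(out.astype(np.float64))
        return out[:, 0].astype(np.float64)


def _adaptive_pool(h: int, w: int) -> tuple[int, int]:
    """Pool by 2 along any axis still long enough to halve."""
    return (2 if h >= 4 else 1, 2 if w >= 4 else 1)


class CNNDecoder(_NeuralDecoder):
    """Three conv blocks (conv + batch-norm + dropout), four FC layers, head."""

    def _architecture(self, in_shape, n_out, rng):
        h, w, c = in_shape
        layers: list[_nn.Layer] = []
        for i, f in enumerate(self.spec.cnn_filters):
            layers += [
                _nn.Conv2D(c, f, self.spec.cnn_kernel, rng),
                _nn.BatchNorm(f),
                _nn.ReLU(),
                _nn.Dropout(self.spec.cnn_dropout, rng),
            ]
            c = f
            if i < 2:  # keep some spatial extent for the third block
                ph, pw = _adaptive_pool(h, w)
                if (ph, pw) != (1, 1):
                    layers.append(_nn.MaxPool2D(ph, pw))
                    h, w = h // ph, w // pw
        layers.append(_nn.Flatten())
        d = h * w * c
        for width in self.spec.cnn_fc:
            layers += [_nn.Dense(d, width, rng), _nn.ReLU()]
            d = width
        layers.append(_nn.Dense(d, n_out, rng))
        return layers


class TMCViTDecoder(_NeuralDecoder):
    """Conv/pool embedding, 2x2 patches, transformer encoder, pooled head."""

    def _architecture(self, in_shape, n_out, rng):
        h, w, c = in_shape
        layers: list[_nn.Layer] = []
        for f in self.spec.vit_conv:
            layers += [_nn.Conv2D(c, f, 3, rng), _nn.ReLU()]
            c = f
            ph, pw = _adaptive_pool(h, w)
            if (ph, pw) != (1, 1):
                layers.append(_nn.MaxPool2D(ph, pw))
                h, w = h // ph, w // pw
        if h < self.spec.patch_size and w < self.spec.patch_size:
            raise ContractError(
                f"embedded size {h}x{w} supports no "
                f"{self.spec.patch_size}x{self.spec.patch_size} patch; "
                f"need >= {self.spec.patch_size} samples along time or channels "
                "after the conv/pool stages"
            )
        patch = min(self.spec.patch_size, h, w)
        layers.append(_nn.PatchEmbed((h, w, c), patch, self.spec.embed_dim, rng))
        for _ in range(self.spec.n_attention_layers):
            layers.append(_nn.TransformerBlock(
                self.spec.embed_dim, self.spec.n_heads, self.spec.mlp_dim, rng))
        layers += [
            _nn.LayerNorm(self.spec.embed_dim),
            _nn.MeanPoolTokens(),
            _nn.Dense(self.spec.embed_dim, n_out, rng),
        ]
        return layers

    @property
    def encoder_blocks(self):
        """The fitted transformer encoder blocks (for introspection)."""
        return [l for l in self.net_.layers if isinstance(l, _nn.TransformerBlock)]


_REGISTRY = {
    "rf": RandomForestDecoder,
    "cnn": CNNDecoder,
    "tmcvit": TMCViTDecoder,
}


def build_model(spec: ModelSpec) -> Decoder:
    """Instantiate the decoder a :class:`ModelSpec` describes."""
    return _REGISTRY[spec.family](spec)


def train(decoder: Decoder, X, y, cfg: TrainConfig | None = None) -> Decoder:
    """Fit ``decoder`` on ``(X, y)`` and return it (with ``history_`` set)."""
    return decoder.fit(X, y, cfg)


def predict(fitted: Decoder, X):
    """Labels (classification) or force estimates (regression)."""
    return fitted.predict(X)
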