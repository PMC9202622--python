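"""Normal/abnormal classification of segmented angiograms.

A VGG-16-style convolutional network consumes the masked original image
(the segmented artery region); a spatial-attention block after the fourth
convolution block (pre-pool) reweights its features:

    C(F) = sigmoid(conv7x7([F_avg ; F_max]))

where ``F_avg`` and ``F_max`` are the channel-wise average- and max-pooled
maps (each 1 x h x w).  In parallel, an attention estimator assigns a
learnable softmax-normalized weight to each handcrafted feature column
(standardized on training statistics) feeding a linear head; the final
class logits are the sum of the CNN head and the feature head, and the
softmax ``p_j = exp(b_j) / sum_k exp(b_k)`` yields class probabilities.
Either path can be disabled for ablation.

The ``full`` VGG preset follows the canonical 16-layer architecture
(conv channels 64,64 / 128,128 / 256x3 / 512x3 / 512x3 with 3x3 kernels,
2x2 stride-2 max-pools, three dense layers); its per-layer shape trace is
available analytically without allocating the ~138M parameters.  The
``tiny`` preset keeps the same topology at desk scale (4 narrow blocks,
64 x 64 single-channel input) and is the trainable workhorse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, Conv2d, Linear, Module, Parameter, Tensor

__all__ = [
    "VGGConfig",
    "vgg_shape_trace",
    "SpatialAttention",
    "spatial_attention",
    "ClassProbabilities",
    "softmax_classify",
    "VGGClassifier",
    "build_vgg",
    "AttentionEstimator",
    "ClassifierTrainConfig",
    "train_classifier",
    "evaluate_classifier",
    "CLASS_NAMES",
]

CLASS_NAMES = ("normal", "abnormal")


# ---------------------------------------------------------------------------
# configuration and the canonical shape trace


@dataclass
class VGGConfig:
    """Architecture parameters; presets: ``full`` and ``tiny``."""

    input_size: tuple[int, int, int] = (224, 224, 3)  # (H, W, C)
    conv_blocks: tuple[tuple[int, int], ...] = (
        (64, 2),
        (128, 2),
        (256, 3),
        (512, 3),
        (512, 3),
    )  # (channels, n_convs) per block; 3x3 kernels, stride 1, 2x2 pools
    fc_sizes: tuple[int, ...] = (4096, 4096, 1000)
    dropout_rate: float = 0.5
    attention_block: int = 4  # spatial attention applied pre-pool here
    use_feature_path: bool = True
    n_features: int = 0  # handcrafted feature columns (0 = CNN only)
    seed: int = 0

    @staticmethod
    def full(n_classes: int = 1000) -> "VGGConfig":
        return VGGConfig(fc_sizes=(4096, 4096, n_classes), use_feature_path=False)

    @staticmethod
    def tiny(n_features: int = 0, seed: int = 0) -> "VGGConfig":
        return VGGConfig(
            input_size=(64, 64, 1),
            conv_blocks=((8, 1), (16, 1), (32, 1), (32, 1)),
            fc_sizes=(64, 2),
            dropout_rate=0.5,
            attention_block=4,
            use_feature_path=n_features > 0,
            n_features=n_features,
            seed=seed,
        )

    def validate(self):
        h, w, _ = self.input_size
        n_pools = len(self.conv_blocks)
        if h % 2**n_pools or w % 2**n_pools:
            raise ValueError(
                f"input {h}x{w} not divisible through {n_pools} pooling stages"
            )


def vgg_shape_trace(config: VGGConfig) -> list[tuple[str, tuple[int, int, int]]]:
    """Per-layer output shapes (H, W, C), computed analytically.

    For the full preset this follows the canonical VGG-16 progression
    224 -> 112 -> 56 -> 28 -> 14 -> 7 with channel growth 64 -> 512 and the
    dense stack 25088 -> 4096 -> 4096 -> classes.
    """
    config.validate()
    h, w, _ = config.input_size
    trace: list[tuple[str, tuple[int, int, int]]] = []
    for bi, (ch, reps) in enumerate(config.conv_blocks, start=1):
        for ri in range(1, reps + 1):
            trace.append((f"conv{bi}_{ri}-{ch}", (h, w, ch)))
        h, w = h // 2, w // 2
        trace.append((f"maxpool{bi}", (h, w, ch)))
    for fi, n in enumerate(config.fc_sizes, start=1):
        trace.append((f"fc{fi}", (1, 1, n)))
    return trace


# ---------------------------------------------------------------------------
# spatial attention (avg/max-pool fusion)


class SpatialAttention(Module):
    """7x7 convolution over concatenated channel-avg and channel-max maps."""

    def __init__(self, rng: np.random.Generator, kernel: int = 7):
        self.conv = Conv2d(2, 1, kernel, rng)

    def attention_map(self, x: Tensor) -> Tensor:
        f_a = x.channel_mean()
        f_m = x.channel_max()
        stacked = Tensor.concat([f_a, f_m], axis=1)
        return self.conv(stacked).sigmoid()

    def __call__(self, x: Tensor) -> Tensor:
        return x * self.attention_map(x)


def spatial_attention(feature_stack: np.ndarray, params: SpatialAttention) -> np.ndarray:
    """Functional attention map for a (N, C, H, W) stack, in (0, 1)."""
    return params.attention_map(Tensor(feature_stack)).data


# ---------------------------------------------------------------------------
# softmax classification head


@dataclass
class ClassProbabilities:
    logits: np.ndarray
    probabilities: np.ndarray
    label_index: int
    label: str


def softmax_classify(logits, class_names: tuple[str, ...] = CLASS_NAMES) -> ClassProbabilities:
    """Numerically stable softmax over class logits.

    Probabilities are strictly positive and sum to one; the label is the
    argmax with ties broken toward the lower class index.
    """
    z = np.asarray(logits, dtype=np.float64).ravel()
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite logits")
    ez = np.exp(z - z.max())
    p = ez / ez.sum()
    idx = int(np.argmax(p))  # argmax returns the first (lowest) max index
    name = class_names[idx] if idx < len(class_names) else str(idx)
    return ClassProbabilities(z, p, idx, name)


# ---------------------------------------------------------------------------
# attention estimator over handcrafted features


class AttentionEstimator(Module):
    """Softmax-normalized learnable weights over feature columns.

    Initialized uniform (weight 1/k each); the weights always sum to 1 and
    are exported for inspection as the model's feature-importance surface.
    """

    def __init__(self, n_features: int):
        if n_features < 1:
            raise ValueError("need at least one feature")
        self.logits = Parameter(np.zeros(n_features))

    @property
    def weights(self) -> np.ndarray:
        z = self.logits.data
        ez = np.exp(z - z.max())
        return ez / ez.sum()

    def __call__(self, x: Tensor) -> Tensor:
        z = self.logits
        ez = (z - float(z.data.max())).exp()
        w = ez / ez.sum()
        # scale by k so the uniform initialization (weight 1/k each) is the
        # identity on standardized features; exported weights still sum to 1
        return x * w.reshape(1, -1) * float(z.data.size)


# ---------------------------------------------------------------------------
# the classifier network


class VGGClassifier(Module):
    """Dual-path classifier: CNN on the masked image + weighted features."""

    def __init__(self, config: VGGConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self._rng_dropout = np.random.default_rng(config.seed + 1)
        c_in = config.input_size[2]
        self.blocks: list[list[Conv2d]] = []
        for ch, reps in config.conv_blocks:
            block = []
            for _ in range(reps):
                block.append(Conv2d(c_in, ch, 3, rng))
                c_in = ch
            self.blocks.append(block)
        self.spatial_attention = SpatialAttention(rng)
        h, w, _ = config.input_size
        n_pools = len(config.conv_blocks)
        flat = (h // 2**n_pools) * (w // 2**n_pools) * config.conv_blocks[-1][0]
        self.fcs: list[Linear] = []
        prev = flat
        for n in config.fc_sizes:
            self.fcs.append(Linear(prev, n, rng))
            prev = n
        self.n_classes = config.fc_sizes[-1]
        # zero-initialized logit heads: the network starts at the uniform
        # prediction instead of random class preferences, which keeps the
        # softmax attention over features away from sign-flip saddles
        self.fcs[-1].weight.data[:] = 0.0
        self.fcs[-1].bias.data[:] = 0.0
        if config.use_feature_path and config.n_features > 0:
            self.attention_estimator = AttentionEstimator(config.n_features)
            self.feature_head = Linear(config.n_features, self.n_classes, rng)
            self.feature_head.weight.data[:] = 0.0
            self.feature_head.bias.data[:] = 0.0
        else:
            self.attention_estimator = None
            self.feature_head = None
        # training-time standardization statistics for the feature path
        self.feature_mean: np.ndarray | None = None
        self.feature_std: np.ndarray | None = None
        self.feature_keep: np.ndarray | None = None

    # -- feature standardization -------------------------------------------

    def fit_feature_stats(self, features: np.ndarray) -> None:
        features = np.asarray(features, dtype=np.float64)
        std = features.std(axis=0)
        keep = std > 0
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} zero-variance feature column(s)")
        self.feature_mean = features.mean(axis=0)
        self.feature_std = np.where(keep, std, 1.0)
        self.feature_keep = keep

    def standardize(self, features: np.ndarray) -> np.ndarray:
        if self.feature_mean is None:
            raise RuntimeError("feature statistics not fitted")
        z = (np.asarray(features, dtype=np.float64) - self.feature_mean) / self.feature_std
        return z * self.feature_keep

    # -- forward -------------------------------------------------------------

    def forward(self, images, features=None, train: bool = False) -> Tensor:
        x = images if isinstance(images, Tensor) else Tensor(images)
        for bi, block in enumerate(self.blocks, start=1):
            for conv in block:
                x = conv(x).relu()
            if bi == self.config.attention_block:
                x = self.spatial_attention(x)
            x = x.maxpool2()
        n = x.data.shape[0]
        x = x.reshape(n, -1)
        for i, fc in enumerate(self.fcs):
            if i == len(self.fcs) - 1 and train and self.config.dropout_rate > 0:
                x = x.dropout(self.config.dropout_rate, self._rng_dropout)
            x = fc(x)
            if i < len(self.fcs) - 1:
                x = x.relu()
        logits = x
        if self.feature_head is not None and features is not None:
            f = features if isinstance(features, Tensor) else Tensor(features)
            logits = logits + self.feature_head(self.attention_estimator(f))
        return logits

    def predict_proba(self, images, features=None) -> np.ndarray:
        logits = self.forward(images, features, train=False).data
        zmax = logits.max(axis=1, keepdims=True)
        ez = np.exp(logits - zmax)
        return ez / ez.sum(axis=1, keepdims=True)

    def predict(self, images, features=None) -> np.ndarray:
        return np.argmax(self.predict_proba(images, features), axis=1)


def build_vgg(config: VGGConfig | None = None) -> VGGClassifier:
    """Construct a seeded classifier (same seed -> identical parameters)."""
    return VGGClassifier(config or VGGConfig.tiny())


def save_checkpoint(network: VGGClassifier, path) -> None:
    """Weights (and feature statistics) as .npz plus a JSON config sidecar."""
    import dataclasses as _dc
    import json
    from pathlib import Path

    path = Path(path)
    state = network.state_dict()
    if network.feature_mean is not None:
        state["_feature_mean"] = network.feature_mean
        state["_feature_std"] = network.feature_std
        state["_feature_keep"] = network.feature_keep.astype(np.float64)
    np.savez(path, **state)
    cfg = _dc.asdict(network.config)
    cfg["input_size"] = list(cfg["input_size"])
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(cfg, fh, indent=2)


def load_checkpoint(path) -> VGGClassifier:
    import json
    from pathlib import Path

    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        raw = json.load(fh)
    raw["input_size"] = tuple(raw["input_size"])
    raw["conv_blocks"] = tuple(tuple(b) for b in raw["conv_blocks"])
    raw["fc_sizes"] = tuple(raw["fc_sizes"])
    net = VGGClassifier(VGGConfig(**raw))
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        state = dict(data)
    if "_feature_mean" in state:
        net.feature_mean = state.pop("_feature_mean")
        net.feature_std = state.pop("_feature_std")
        net.feature_keep = state.pop("_feature_keep").astype(bool)
    net.load_state_dict(state)
    return net


# ---------------------------------------------------------------------------
# training


@dataclass
class ClassifierTrainConfig:
    learning_rate: float = 1e-3
    #: the feature path (attention estimator + linear head) is a shallow
    #: model on standardized inputs and tolerates a much larger step than
    #: the deep convolutional stack; with a shared rate its margins grow
    #: too slowly to outweigh the CNN head's test-time noise
    feature_learning_rate: float = 1e-2
    epochs: int = 30
    batch_size: int = 16
    seed: int = 0
    #: random dihedral (flip/transpose) augmentation of the image path;
    #: masked vessel images have no canonical orientation, and without it
    #: a small CNN memorizes a 100-image training set outright
    augment: bool = True


def train_classifier(
    network: VGGClassifier,
    images: np.ndarray,
    labels: np.ndarray,
    features: np.ndarray | None = None,
    hyper: ClassifierTrainConfig | None = None,
):
    """Cross-entropy training with Adam; returns (network, loss_curve).

    ``images`` is (n, C, H, W); ``labels`` integer class indices; both
    classes must be present.  ``features`` is the optional handcrafted
    (n, k) matrix; its standardization statistics are fitted here on the
    training set only.
    """
    hyper = hyper or ClassifierTrainConfig()
    labels = np.asarray(labels, dtype=np.int64)
    if len(np.unique(labels)) < 2:
        raise ValueError("training set contains a single class")
    feats = None
    if features is not None and network.feature_head is not None:
        network.fit_feature_stats(features)
        feats = network.standardize(features)
    rng = np.random.default_rng(hyper.seed)
    feature_params = []
    if network.feature_head is not None:
        feature_params = [
            network.attention_estimator.logits,
            network.feature_head.weight,
            network.feature_head.bias,
        ]
    feature_ids = {id(p) for p in feature_params}
    cnn_params = [p for p in network.parameters() if id(p) not in feature_ids]
    optimizers = [Adam(cnn_params, lr=hyper.learning_rate)]
    if feature_params:
        optimizers.append(Adam(feature_params, lr=hyper.feature_learning_rate))
    n = len(labels)
    losses: list[float] = []
    for _epoch in range(hyper.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, hyper.batch_size):
            idx = order[start : start + hyper.batch_size]
            f = Tensor(feats[idx]) if feats is not None else None
            batch = images[idx]
            if hyper.augment:
                batch = _dihedral_augment(batch, rng)
            logits = network.forward(Tensor(batch), f, train=True)
            loss = logits.softmax_cross_entropy(labels[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(f"NaN/inf loss at epoch {_epoch}")
            for opt in optimizers:
                opt.zero_grad()
            loss.backward()
            for opt in optimizers:
                opt.step()
            epoch_loss += float(loss.data) * len(idx)
        losses.append(epoch_loss / n)
    return network, losses


def _dihedral_augment(images: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random per-sample flip/transpose (the 8 square symmetries)."""
    out = images.copy()
    codes = rng.integers(0, 8, size=len(out))
    for i, code in enumerate(codes):
        a = out[i]
        if code & 1:
            a = a[:, ::-1, :]
        if code & 2:
            a = a[:, :, ::-1]
        if code & 4:
            a = a.transpose(0, 2, 1)
        out[i] = a
    return out


def evaluate_classifier(
    network: VGGClassifier,
    images: np.ndarray,
    labels: np.ndarray,
    features: np.ndarray | None = None,
):
    """Held-out accuracy and abnormal-class scores for ROC analysis."""
    feats = network.standardize(features) if (
        features is not None and network.feature_head is not None
    ) else None
    proba = network.predict_proba(images, feats)
    pred = np.argmax(proba, axis=1)
    labels = np.asarray(labels, dtype=np.int64)
    accuracy = float(np.mean(pred == labels))
    return accuracy, pred, proba[:, 1]
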