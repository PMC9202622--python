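"""Attention-gated nested U-Net segmentation with artery-angle estimation.

The segmenter consumes a 2-channel stack of the binarized (preprocessed)
image and the original image, so the learned stage can correct
binarization errors, and produces a vessel probability map.  Skip features
pass through attention gates: with encoder feature ``F`` and gating signal
``G`` (the decoder feature upsampled to ``F``'s grid),

    f     = relu(W_F' F + b_F) + (W_G' G + b_G)
    alpha = sigmoid(W_theta' f + b_theta)
    out   = F * alpha

where the W are 1x1 convolutions, so ``alpha`` is a pixelwise coefficient
strictly inside (0, 1) that rescales the skip features toward vessel
structures.  "Nested" means UNet++-style dense skip pathways: the node at
level i, column j convolves the concatenation of all previous same-level
nodes with the upsampled node from the level below.

After thresholding, connected components are described per artery: the
orientation of the principal axis of the component's pixel coordinates,
the geodesic extent of its morphological skeleton, and the mean width
(area / length).  Components that merge several vessels at a crossing are
split where the skeleton branches and local orientations disagree by more
than an angular threshold.  The final ``masked_original`` is the bitwise
AND of the predicted mask with the original image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree
from skimage.measure import label as cc_label
from skimage.morphology import skeletonize

from ._nn import Adam, Conv2d, Module, Parameter, Tensor
from .phantom import PhantomSample
from .preprocess import PreprocessConfig, preprocess_pipeline

__all__ = [
    "AttentionGate",
    "attention_gate",
    "NestedUNetConfig",
    "NestedUNet",
    "build_network",
    "TrainConfig",
    "train_segmenter",
    "ArteryRegion",
    "estimate_artery_angles",
    "SegmentationResult",
    "segment",
    "sample_to_input",
]


# ---------------------------------------------------------------------------
# attention gate


class AttentionGate(Module):
    """Learnable 1x1-convolution attention gate on a skip connection."""

    def __init__(self, c_f: int, c_g: int, c_inter: int, rng: np.random.Generator):
        self.w_f = Conv2d(c_f, c_inter, 1, rng)
        self.w_g = Conv2d(c_g, c_inter, 1, rng)
        self.w_theta = Conv2d(c_inter, 1, 1, rng)

    def coefficients(self, f: Tensor, g: Tensor) -> Tensor:
        if f.data.shape[2:] != g.data.shape[2:]:
            raise ValueError("F and G must be spatially aligned before gating")
        inner = self.w_f(f).relu() + self.w_g(g)
        return self.w_theta(inner).sigmoid()

    def __call__(self, f: Tensor, g: Tensor) -> Tensor:
        return f * self.coefficients(f, g)


def attention_gate(f: np.ndarray, g: np.ndarray, params: AttentionGate) -> np.ndarray:
    """Functional form on plain arrays (N, C, H, W); returns gated F."""
    return params(Tensor(f), Tensor(g)).data


# ---------------------------------------------------------------------------
# nested U-Net


@dataclass
class NestedUNetConfig:
    depth: int = 3
    base_channels: int = 8
    nested_skips: bool = True
    attention_on_skips: bool = True
    input_channels: int = 2
    seed: int = 0

    def validate(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 1 or self.input_channels < 1:
            raise ValueError("invalid channel configuration")


class _ConvBlock(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv1 = Conv2d(c_in, c_out, 3, rng)
        self.conv2 = Conv2d(c_out, c_out, 3, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv2(self.conv1(x).relu()).relu()


class NestedUNet(Module):
    """UNet++-style encoder-decoder with optional attention-gated skips."""

    def __init__(self, config: NestedUNetConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.depth
        ch = [config.base_channels * 2**i for i in range(d)]
        self.channels = ch

        self.encoders = [
            _ConvBlock(config.input_channels if i == 0 else ch[i - 1], ch[i], rng)
            for i in range(d)
        ]
        # decoder nodes indexed [i][j-1] for node X(i, j), j >= 1
        self.decoders: list[list[_ConvBlock]] = []
        self.gates: list[list[AttentionGate | None]] = []
        for i in range(d - 1):
            row_dec, row_gate = [], []
            max_j = (d - 1 - i) if config.nested_skips else 1
            for j in range(1, max_j + 1):
                skip_ch = ch[i] * j
                c_in = skip_ch + ch[i + 1]
                row_dec.append(_ConvBlock(c_in, ch[i], rng))
                if config.attention_on_skips:
                    row_gate.append(AttentionGate(skip_ch, ch[i + 1], max(ch[i] // 2, 1), rng))
                else:
                    row_gate.append(None)
            self.decoders.append(row_dec)
            self.gates.append(row_gate)
        self.head = Conv2d(ch[0], 1, 1, rng)

    def forward(self, x) -> Tensor:
        """Logit map for input (N, C, H, W)."""
        x = x if isinstance(x, Tensor) else Tensor(x)
        n, c, h, w = x.data.shape
        d = self.config.depth
        factor = 2 ** (d - 1)
        if h % factor or w % factor or h < 2 * factor or w < 2 * factor:
            raise ValueError(
                f"input {h}x{w} incompatible with depth {d} (spatial collapse)"
            )
        nodes: dict[tuple[int, int], Tensor] = {}
        cur = x
        for i in range(d):
            if i > 0:
                cur = cur.maxpool2()
            cur = self.encoders[i](cur)
            nodes[(i, 0)] = cur
        if self.config.nested_skips:
            for j in range(1, d):
                for i in range(d - j):
                    below = nodes[(i + 1, j - 1)]
                    up = below.upsample2()
                    skips = Tensor.concat([nodes[(i, k)] for k in range(j)], axis=1)
                    gate = self.gates[i][j - 1]
                    if gate is not None:
                        skips = gate(skips, up)
                    nodes[(i, j)] = self.decoders[i][j - 1](
                        Tensor.concat([skips, up], axis=1)
                    )
            top = nodes[(0, d - 1)]
        else:
            # plain variant: cascade one column per level from the bottom
            cur = nodes[(d - 1, 0)]
            for i in range(d - 2, -1, -1):
                up = cur.upsample2()
                skips = nodes[(i, 0)]
                gate = self.gates[i][0]
                if gate is not None:
                    skips = gate(skips, up)
                cur = self.decoders[i][0](Tensor.concat([skips, up], axis=1))
            top = cur
        return self.head(top)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Probability map(s) in [0, 1] without building gradients."""
        logits = self.forward(Tensor(np.asarray(x, dtype=np.float64)))
        return 1.0 / (1.0 + np.exp(-logits.data))


def build_network(config: NestedUNetConfig | None = None) -> NestedUNet:
    """Construct a seeded attention-gated nested U-Net."""
    return NestedUNet(config or NestedUNetConfig())


def save_checkpoint(network: NestedUNet, path) -> None:
    """Weights as .npz plus a JSON sidecar with the architecture config."""
    import dataclasses as _dc
    import json
    from pathlib import Path

    path = Path(path)
    np.savez(path, **network.state_dict())
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(_dc.asdict(network.config), fh, indent=2)


def load_checkpoint(path) -> NestedUNet:
    import json
    from pathlib import Path

    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        config = NestedUNetConfig(**json.load(fh))
    net = NestedUNet(config)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        net.load_state_dict(dict(data))
    return net


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    loss: str = "bce_dice"
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 8
    seed: int = 0


def sample_to_input(
    sample: PhantomSample, preprocess_config: PreprocessConfig | None = None,
    use_preprocessing: bool = True,
) -> np.ndarray:
    """(2, H, W) network input: binarized channel + normalized original.

    With preprocessing disabled (ablation), the raw image fills both
    channels so the network shape contract is unchanged.
    """
    original = np.asarray(sample.image, dtype=np.float64) / 255.0
    if use_preprocessing:
        binary = preprocess_pipeline(sample.image, preprocess_config).binary
    else:
        binary = original
    return np.stack([binary, original])


def train_segmenter(
    network: NestedUNet,
    samples: list[PhantomSample],
    hyper: TrainConfig | None = None,
    inputs: np.ndarray | None = None,
):
    """Train on phantom samples; returns (network, loss_curve).

    Loss is mean binary cross-entropy on logits plus soft Dice; optimizer
    is Adam.  All randomness (shuffling) is seeded.  ``inputs`` may carry
    precomputed (n, 2, H, W) stacks to avoid re-running preprocessing.
    """
    hyper = hyper or TrainConfig()
    if len(samples) < 8:
        raise ValueError("training requires at least 8 samples")
    if inputs is None:
        inputs = np.stack([sample_to_input(s) for s in samples])
    targets = np.stack([s.mask.astype(np.float64)[None] for s in samples])
    rng = np.random.default_rng(hyper.seed)
    opt = Adam(network.parameters(), lr=hyper.learning_rate)
    losses: list[float] = []
    n = len(samples)
    for _epoch in range(hyper.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, hyper.batch_size):
            idx = order[start : start + hyper.batch_size]
            logits = network.forward(Tensor(inputs[idx]))
            y = targets[idx]
            loss = logits.bce_with_logits(y)
            if hyper.loss == "bce_dice":
                p = logits.sigmoid()
                num = 2.0 * (p * Tensor(y)).sum() + 1.0
                den = p.sum() + float(y.sum()) + 1.0
                loss = loss + (1.0 - num / den)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {_epoch}, batch {start // hyper.batch_size}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        losses.append(epoch_loss / n)
    return network, losses


# ---------------------------------------------------------------------------
# artery-angle estimation


@dataclass
class ArteryRegion:
    """One segmented artery: geometry summary plus its pixel support."""

    region_id: int
    angle_deg: float
    length_px: float
    mean_width_px: float
    area_px: int
    pixel_mask: np.ndarray = field(repr=False, default=None)


_NEIGHBOR_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _principal_angle(coords_rc: np.ndarray) -> float:
    """Orientation (degrees in [0, 180)) of the principal axis, x-axis ref."""
    xy = coords_rc[:, ::-1].astype(np.float64)  # (x, y)
    xy = xy - xy.mean(axis=0)
    if len(xy) < 2:
        return 0.0
    cov = xy.T @ xy / len(xy)
    evals, evecs = np.linalg.eigh(cov)
    vx, vy = evecs[:, int(np.argmax(evals))]
    return float(np.degrees(np.arctan2(vy, vx)) % 180.0)


def _angle_diff(a: float, b: float) -> float:
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def _skeleton_geodesic_length(coords_rc: np.ndarray) -> float:
    """Geodesic extent of a skeleton pixel set via double Dijkstra sweep."""
    n = len(coords_rc)
    if n <= 1:
        return float(n)
    index = {tuple(p): i for i, p in enumerate(coords_rc)}
    rows, cols, weights = [], [], []
    for i, (r, c) in enumerate(coords_rc):
        for dr, dc in _NEIGHBOR_OFFSETS:
            j = index.get((r + dr, c + dc))
            if j is not None and j > i:
                w = np.hypot(dr, dc)
                rows.extend((i, j))
                cols.extend((j, i))
                weights.extend((w, w))
    if not rows:
        return 1.0
    graph = coo_matrix((weights, (rows, cols)), shape=(n, n)).tocsr()
    d0 = dijkstra(graph, indices=0)
    far = int(np.nanargmax(np.where(np.isinf(d0), np.nan, d0)))
    d1 = dijkstra(graph, indices=far)
    finite = d1[np.isfinite(d1)]
    return float(finite.max()) + 1.0 if finite.size else 1.0


def _split_component(
    comp_mask: np.ndarray, split_angle_deg: float
) -> list[np.ndarray]:
    """Split a component at skeleton crossings with disagreeing orientations.

    Branch points (skeleton pixels with 3+ skeleton neighbours) are removed;
    the remaining skeleton segments are greedily clustered by orientation,
    and component pixels are assigned to the nearest cluster's skeleton.
    Returns a list of boolean masks (one per split region).
    """
    skel = skeletonize(comp_mask.astype(bool))
    coords = np.argwhere(skel)
    if len(coords) < 8:
        return [comp_mask.astype(bool)]
    # neighbour counts on the skeleton
    neigh = np.zeros_like(skel, dtype=np.int8)
    for dr, dc in _NEIGHBOR_OFFSETS:
        neigh += np.roll(np.roll(skel, dr, axis=0), dc, axis=1).astype(np.int8)
    branch_points = skel & (neigh >= 3)
    if not branch_points.any():
        return [comp_mask.astype(bool)]
    pruned = skel & ~branch_points
    seg_labels = cc_label(pruned, connectivity=2)
    segments = []
    for sid in range(1, seg_labels.max() + 1):
        pts = np.argwhere(seg_labels == sid)
        if len(pts) >= 4:
            segments.append((pts, _principal_angle(pts)))
    if len(segments) < 2:
        return [comp_mask.astype(bool)]
    # greedy orientation clustering
    clusters: list[dict] = []
    for pts, ang in sorted(segments, key=lambda s: -len(s[0])):
        for cl in clusters:
            if _angle_diff(ang, cl["angle"]) <= split_angle_deg:
                cl["points"].append(pts)
                allpts = np.concatenate(cl["points"])
                cl["angle"] = _principal_angle(allpts)
                break
        else:
            clusters.append({"points": [pts], "angle": ang})
    if len(clusters) < 2:
        return [comp_mask.astype(bool)]
    trees = [cKDTree(np.concatenate(cl["points"]).astype(np.float64)) for cl in clusters]
    comp_coords = np.argwhere(comp_mask)
    dists = np.stack([t.query(comp_coords.astype(np.float64))[0] for t in trees])
    assign = np.argmin(dists, axis=0)
    out = []
    for k in range(len(clusters)):
        m = np.zeros_like(comp_mask, dtype=bool)
        sel = comp_coords[assign == k]
        m[sel[:, 0], sel[:, 1]] = True
        if m.any():
            out.append(m)
    return out


def estimate_artery_angles(
    mask: np.ndarray, split_angle_deg: float = 30.0
) -> list[ArteryRegion]:
    """Connected-component artery description with crossing splitting.

    Empty masks return an empty list.
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        return []
    labels = cc_label(m, connectivity=2)
    regions: list[ArteryRegion] = []
    rid = 0
    for cid in range(1, labels.max() + 1):
        comp = labels == cid
        for sub in _split_component(comp, split_angle_deg):
            coords = np.argwhere(sub)
            area = int(coords.shape[0])
            if area == 0:
                continue
            angle = _principal_angle(coords)
            skel_coords = np.argwhere(skeletonize(sub))
            if len(skel_coords) == 0:
                skel_coords = coords[:1]
            length = _skeleton_geodesic_length(skel_coords)
            regions.append(
                ArteryRegion(
                    region_id=rid,
                    angle_deg=angle,
                    length_px=length,
                    mean_width_px=area / max(length, 1.0),
                    area_px=area,
                    pixel_mask=sub,
                )
            )
            rid += 1
    return regions


# ---------------------------------------------------------------------------
# full segmentation


@dataclass
class SegmentationResult:
    probability_map: np.ndarray
    mask: np.ndarray
    per_artery_regions: list[ArteryRegion]
    masked_original: np.ndarray


def segment(
    original: np.ndarray,
    binary: np.ndarray,
    network: NestedUNet,
    threshold: float = 0.5,
    split_angle_deg: float = 30.0,
) -> SegmentationResult:
    """Run the trained network on the (binary, original) stack.

    The output mask is ``probability >= threshold``; per-artery regions are
    estimated from it, and ``masked_original`` is the original image under
    the mask (bitwise-AND semantics), zero elsewhere.  An all-background
    binary input short-circuits to the empty result (nothing to gate).
    """
    original = np.asarray(original, dtype=np.float64)
    binary = np.asarray(binary, dtype=np.float64)
    if original.shape != binary.shape:
        raise ValueError("original and binary must have the same shape")
    if not (binary > 0).any():
        empty = np.zeros_like(original)
        return SegmentationResult(empty, empty.astype(np.uint8), [], empty)
    x = np.stack([binary, original / 255.0])[None]
    prob = network.predict_proba(x)[0, 0]
    mask = (prob >= threshold).astype(np.uint8)
    regions = estimate_artery_angles(mask, split_angle_deg)
    masked_original = np.where(mask > 0, original, 0.0)
    return SegmentationResult(prob, mask, regions, masked_original)
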