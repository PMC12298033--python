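"""Heatmap-regression keypoint network and its target/decode plumbing.

The network follows the simple-baselines recipe: a strided convolutional
backbone downsamples the image, a transposed-convolution head upsamples
back to heatmap resolution, and a 1×1 convolution emits one heatmap per
keypoint.  Training regresses rendered Gaussian target heatmaps with a
visibility-masked MSE loss; inference decodes the per-channel argmax back
to image pixels.

Two configurations ship: a desk-scale ``tiny`` backbone (64×64 grayscale
in, 16×16 heatmaps, a few thousand parameters) used throughout the test
suite and federation experiments, and a deeper ``resnet50_style``
configuration mirroring the classical 256×256 → 64×64 setup with three
256-channel kernel-4 deconvolution layers.  The aggregation strategies
operate on flat gradient vectors and are agnostic to which is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .nn import Adam, Conv2d, ConvTranspose2d, ReLU, SGD, Sequential, masked_mse
from .params import ClientUpdate, ParamVector

__all__ = [
    "PoseNetConfig", "TINY", "RESNET50_STYLE", "PoseNet",
    "build_pose_net", "render_target_heatmaps", "decode_heatmaps", "local_train",
]

KEYPOINT_NAMES = ("shoulder", "elbow", "wrist")


@dataclass(frozen=True)
class PoseNetConfig:
    """Architecture and target-rendering configuration.

    ``backbone_channels`` lists the output channels of the stride-2
    convolution blocks; ``deconv_specs`` lists (channels, kernel, stride)
    for the upsampling head.  The stride products must satisfy
    input_size / heatmap_size = 2^(#stride-2 convs) / Π(deconv strides).
    """

    n_keypoints: int = 3
    input_size: int = 64
    heatmap_size: int = 16
    backbone: str = "tiny"
    backbone_channels: tuple[int, ...] = (8, 16, 16)
    deconv_specs: tuple[tuple[int, int, int], ...] = ((16, 4, 2), (16, 3, 1))
    sigma: float = 2.0
    decode_quarter_offset: bool = True

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        down = 2 ** len(self.backbone_channels)
        up = int(np.prod([s for _, _, s in self.deconv_specs])) if self.deconv_specs else 1
        if self.input_size * up != self.heatmap_size * down:
            raise ValueError(
                f"stride arithmetic inconsistent: input {self.input_size} with "
                f"{len(self.backbone_channels)} stride-2 blocks and deconv strides "
                f"×{up} cannot produce {self.heatmap_size} heatmaps"
            )

    @property
    def stride_ratio(self) -> float:
        """Image pixels per heatmap cell."""
        return self.input_size / self.heatmap_size


TINY = PoseNetConfig()

# Classical full-scale recipe: 256×256 input, five stride-2 blocks down to
# 8×8, then three 256-channel kernel-4 stride-2 deconvolutions up to 64×64.
RESNET50_STYLE = PoseNetConfig(
    input_size=256,
    heatmap_size=64,
    backbone="resnet50_style",
    backbone_channels=(32, 64, 128, 256, 256),
    deconv_specs=((256, 4, 2), (256, 4, 2), (256, 4, 2)),
)


class PoseNet:
    """Convolutional heatmap regressor with a flat-parameter contract."""

    def __init__(self, config: PoseNetConfig = TINY, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        layers: list[tuple[str, object]] = []
        cin = 1
        for i, cout in enumerate(config.backbone_channels):
            layers.append((f"conv{i}", Conv2d(cin, cout, k=3, stride=2, pad=1, rng=rng)))
            layers.append((f"relu{i}", ReLU()))
            cin = cout
        for i, (cout, k, stride) in enumerate(config.deconv_specs):
            pad = (k - stride) // 2 if stride > 1 else k // 2
            layers.append((f"deconv{i}", ConvTranspose2d(cin, cout, k=k, stride=stride,
                                                         pad=pad, rng=rng)))
            layers.append((f"derelu{i}", ReLU()))
            cin = cout
        head = Conv2d(cin, config.n_keypoints, k=1, stride=1, pad=0, rng=rng)
        head.params["b"][:] = 0.0
        layers.append(("head", head))
        self.net = Sequential(layers)

    def forward(self, images: np.ndarray) -> np.ndarray:
        """(N, 1, H, W) images → (N, K, h, w) heatmaps."""
        return self.net.forward(np.asarray(images, dtype=np.float32))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.net.backward(dout)

    def get_params(self) -> ParamVector:
        return ParamVector.from_arrays(self.net.named_params())

    def set_params(self, pv: ParamVector) -> None:
        self.net.set_named_params(pv.to_arrays())

    @property
    def n_params(self) -> int:
        return sum(v.size for v in self.net.named_params().values())


def build_pose_net(config: PoseNetConfig = TINY, seed: int = 0) -> PoseNet:
    return PoseNet(config, seed=seed)


def render_target_heatmaps(
    keypoints: np.ndarray,
    config: PoseNetConfig,
    quantize_center: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian target heatmaps for one sample.

    ``keypoints`` is (K, 3) of [x, y, visibility] in input-image pixels.
    Each visible joint becomes an isotropic Gaussian of std ``sigma``
    (heatmap cells) centred at the joint mapped into heatmap coordinates;
    with ``quantize_center`` the centre is rounded to the nearest cell so
    the peak cell holds exactly 1.  Invisible joints yield an all-zero
    channel and a 0 entry in the returned loss mask.

    Returns (heatmaps (K, h, w), mask (K,)).
    """
    kps = np.asarray(keypoints, dtype=np.float64)
    k = kps.shape[0]
    h = w = config.heatmap_size
    ratio = config.stride_ratio
    ys, xs = np.mgrid[0:h, 0:w]
    maps = np.zeros((k, h, w), dtype=np.float32)
    mask = np.zeros(k, dtype=np.float32)
    for i in range(k):
        x, y, v = kps[i]
        if v <= 0:
            continue
        cx, cy = x / ratio, y / ratio
        if quantize_center:
            cx, cy = np.round(cx), np.round(cy)
        if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
            continue
        d2 = (xs - cx) ** 2 + (ys - cy) ** 2
        maps[i] = np.exp(-d2 / (2.0 * config.sigma ** 2)).astype(np.float32)
        mask[i] = 1.0
    return maps, mask


def decode_heatmaps(stack: np.ndarray, config: PoseNetConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel argmax → keypoint coordinates in input-image pixels.

    Ties resolve to the first maximum in row-major order.  With the
    quarter-offset flag, the decoded cell is nudged 0.25 cells toward the
    larger of its two horizontal/vertical neighbours before scaling —
    the standard sub-cell refinement for Gaussian peaks.  An all-constant
    channel decodes to (0, 0) and is flagged degenerate.

    Accepts (K, h, w) or (N, K, h, w); returns (coords [..., K, 2] as
    (x, y), degenerate flags [..., K]).
    """
    arr = np.asarray(stack, dtype=np.float64)
    single = arr.ndim == 3
    if single:
        arr = arr[None]
    n, k, h, w = arr.shape
    coords = np.zeros((n, k, 2))
    degenerate = np.zeros((n, k), dtype=bool)
    ratio = config.stride_ratio
    for s in range(n):
        for c in range(k):
            ch = arr[s, c]
            if np.all(ch == ch.flat[0]):
                degenerate[s, c] = True
                continue
            idx = int(np.argmax(ch))
            cy, cx = divmod(idx, w)
            x, y = float(cx), float(cy)
            if config.decode_quarter_offset:
                if 0 < cx < w - 1:
                    x += 0.25 * np.sign(ch[cy, cx + 1] - ch[cy, cx - 1])
                if 0 < cy < h - 1:
                    y += 0.25 * np.sign(ch[cy + 1, cx] - ch[cy - 1, cx])
            coords[s, c] = (x * ratio, y * ratio)
    if single:
        return coords[0], degenerate[0]
    return coords, degenerate


def _make_optimizer(name: str, lr: float):
    name = name.lower()
    if name == "adam":
        return Adam(lr=lr)
    if name == "sgd":
        return SGD(lr=lr)
    raise ValueError(f"unknown optimizer: {name!r}")


def local_train(
    model: PoseNet,
    images: np.ndarray,
    targets: np.ndarray,
    masks: np.ndarray,
    epochs: int,
    rng: np.random.Generator,
    optimizer: str = "adam",
    lr: float = 1e-3,
    batch_size: int = 32,
    client_id: int = 0,
    penalty=None,
) -> tuple[ClientUpdate, list[float]]:
    """Run local epochs of masked-MSE heatmap regression on one client.

    ``penalty``, if given, is a callable ``(flat_params) -> flat_grad``
    returning an additional parameter-space gradient (used by proximal /
    dynamic-regularization strategies).  Returns the post-training
    :class:`ClientUpdate` and the per-epoch mean training losses.
    Deterministic for a fixed ``rng`` under single-threaded execution.
    """
    n = images.shape[0]
    if n == 0:
        raise ValueError("client dataset is empty")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    opt = _make_optimizer(optimizer, lr)
    epoch_losses = []
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            pred = model.forward(images[idx])
            loss, dpred = masked_mse(pred, targets[idx], masks[idx])
            model.backward(dpred)
            grads = model.net.named_grads()
            if penalty is not None:
                flat = model.get_params()
                pgrad = ParamVector(penalty(flat.values), flat.layout).to_arrays()
                grads = {k: g + pgrad[k] for k, g in grads.items()}
            opt.step(model.net.named_params(), grads)
            losses.append(loss)
        epoch_losses.append(float(np.mean(losses)))
    return ClientUpdate(client_id=client_id, params=model.get_params(), n_samples=n), epoch_losses
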