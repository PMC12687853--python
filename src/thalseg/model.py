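"""Coordinate channels and the 4-level coordinate-aware 3D U-Net.

The network receives a single image channel concatenated with three
normalized coordinate channels (CoordConv): at index ``i`` along an axis of
extent ``N >= 2`` the coordinate value is ``-1 + 2 i / (N - 1)``, spanning
[-1, 1] with 0 at the spatial center for odd extents (an even extent such as
96 has no voxel at exactly 0). All convolutions use replicate padding so that
the coordinate value 0 never leaks in at the borders, four encoder stages of
two convolution blocks (3x3x3 kernels, instance normalization, LeakyReLU)
each end in 2x2x2 max pooling, a bottleneck sits below, and each decoder
stage performs trilinear 2x upsampling, a convolution block, concatenation
with the mirrored encoder features, and two further convolution blocks. A
final convolution and channel softmax produce 14-channel voxelwise class
probabilities (background plus 13 thalamic nuclei).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ._nn import (
    Conv3d,
    InstanceNorm3d,
    LeakyReLU,
    MaxPool3d,
    Sequential,
    Upsample2xTrilinear,
    softmax_backward,
    softmax_channels,
)
from .types import N_CLASSES, UsageError

__all__ = [
    "NetworkConfig",
    "build_coord_channels",
    "CoordUNet3D",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``levels`` counts the pooling stages (the bottleneck sits below them);
    ``base_width`` is the channel count at the first level, doubling per
    level. ``in_channels`` is 1 image channel + 3 coordinate channels.
    """

    levels: int = 4
    base_width: int = 16
    in_channels: int = 4
    out_channels: int = N_CLASSES
    negative_slope: float = 0.01
    padding_mode: str = "replicate"

    def __post_init__(self) -> None:
        if self.out_channels != N_CLASSES:
            raise UsageError(f"out_channels must be {N_CLASSES}")
        if self.padding_mode != "replicate":
            raise UsageError("padding_mode is fixed to 'replicate'")


def build_coord_channels(shape: tuple[int, int, int]) -> np.ndarray:
    """Three coordinate channels of the given shape, each in [-1, 1].

    Along its own axis a channel runs from -1 to +1 (``-1 + 2i/(N-1)``);
    an extent-1 axis yields the single value 0. Channels are constant along
    the other two axes.
    """
    if any(n < 1 for n in shape):
        raise UsageError(f"extents must be >= 1, got {shape}")
    axes = [
        np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1) for n in shape
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    return np.stack(coords).astype(np.float32)


def _conv_block(cin: int, cout: int, slope: float, rng) -> Sequential:
    return Sequential(Conv3d(cin, cout, rng), InstanceNorm3d(cout), LeakyReLU(slope))


class CoordUNet3D:
    """The segmentation network; batch-free, channel-first NumPy tensors."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator | int = 0):
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        self.cfg = cfg
        w = [cfg.base_width * 2**l for l in range(cfg.levels + 1)]
        s = cfg.negative_slope
        self.enc: list[Sequential] = []
        cin = cfg.in_channels
        for l in range(cfg.levels):
            self.enc.append(
                Sequential(
                    *_conv_block(cin, w[l], s, rng).layers,
                    *_conv_block(w[l], w[l], s, rng).layers,
                )
            )
            cin = w[l]
        self.pools = [MaxPool3d() for _ in range(cfg.levels)]
        self.bottleneck = Sequential(
            *_conv_block(w[-2], w[-1], s, rng).layers,
            *_conv_block(w[-1], w[-1], s, rng).layers,
        )
        self.ups = [Upsample2xTrilinear() for _ in range(cfg.levels)]
        self.dec_pre: list[Sequential] = []  # conv block after upsampling
        self.dec_post: list[Sequential] = []  # two blocks after concatenation
        cur = w[-1]
        for l in reversed(range(cfg.levels)):
            self.dec_pre.append(_conv_block(cur, w[l], s, rng))
            self.dec_post.append(
                Sequential(
                    *_conv_block(2 * w[l], w[l], s, rng).layers,
                    *_conv_block(w[l], w[l], s, rng).layers,
                )
            )
            cur = w[l]
        self.head = Conv3d(w[0], cfg.out_channels, rng)
        self._modules: list = (
            self.enc + [self.bottleneck] + self.dec_pre + self.dec_post + [self.head]
        )

    # -- parameter plumbing -------------------------------------------------
    def named_params(self) -> dict[str, np.ndarray]:
        out = {}
        for i, mod in enumerate(self._modules):
            layers = mod.layers if isinstance(mod, Sequential) else [mod]
            for j, layer in enumerate(layers):
                for k, v in layer.params.items():
                    out[f"m{i}.l{j}.{k}"] = v
        return out

    def named_grads(self) -> dict[str, np.ndarray]:
        out = {}
        for i, mod in enumerate(self._modules):
            layers = mod.layers if isinstance(mod, Sequential) else [mod]
            for j, layer in enumerate(layers):
                for k, v in layer.grads.items():
                    out[f"m{i}.l{j}.{k}"] = v
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_params()
        missing = set(params) ^ set(state)
        if missing:
            raise UsageError(f"checkpoint/network parameter mismatch: {sorted(missing)[:4]}")
        for k, v in params.items():
            if v.shape != state[k].shape:
                raise UsageError(f"shape mismatch for {k}")
            v[...] = state[k]

    def zero_grad(self) -> None:
        for mod in self._modules:
            mod.zero_grad()

    # -- forward / backward -------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[0] != self.cfg.in_channels:
            raise UsageError(
                f"expected ({self.cfg.in_channels}, D, H, W) input, got {x.shape}"
            )
        divisor = 2**self.cfg.levels
        if any(n % divisor for n in x.shape[1:]):
            raise UsageError(
                f"spatial extents {x.shape[1:]} must be divisible by "
                f"2^levels = {divisor}"
            )

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Map a (in_channels, D, H, W) input to (14, D, H, W) probabilities."""
        self._check_input(x)
        x = x.astype(np.float32)
        skips = []
        for enc, pool in zip(self.enc, self.pools):
            x = enc.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_channels = []
        for up, pre, post, skip in zip(
            self.ups, self.dec_pre, self.dec_post, reversed(skips)
        ):
            x = up.forward(x)
            x = pre.forward(x)
            self._skip_channels.append(skip.shape[0])
            x = np.concatenate([skip, x], axis=0)
            x = post.forward(x)
        logits = self.head.forward(x)
        self._probs = softmax_channels(logits)
        return self._probs

    def backward(self, grad_probs: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the output probabilities."""
        g = softmax_backward(self._probs, grad_probs.astype(np.float32))
        g = self.head.backward(g)
        skip_grads = []
        for up, pre, post, nskip in zip(
            reversed(self.ups),
            reversed(self.dec_pre),
            reversed(self.dec_post),
            reversed(self._skip_channels),
        ):
            # walk decoder stages in reverse execution order
            g = post.backward(g)
            skip_grads.append(g[:nskip])
            g = pre.backward(g[nskip:])
            g = up.backward(g)
        g = self.bottleneck.backward(g)
        # skip_grads[i] belongs to encoder level i (decoder ran deep-first,
        # so its reverse walk emitted shallow levels first)
        for enc, pool, gskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(skip_grads)
        ):
            g = pool.backward(g)
            g = g + gskip
            g = enc.backward(g)

    def predict_probs(self, image: np.ndarray) -> np.ndarray:
        """Convenience: concatenate coordinate channels and run forward."""
        image = np.asarray(image, dtype=np.float32)
        if image.ndim != 3:
            raise UsageError("expected a single-channel 3D image")
        coords = build_coord_channels(image.shape)
        return self.forward(np.concatenate([image[None], coords], axis=0))


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, net: CoordUNet3D, meta: dict | None = None) -> None:
    """Serialize weights + architecture config (+ training metadata) together."""
    payload = {f"param::{k}": v for k, v in net.named_params().items()}
    header = {"config": asdict(net.cfg), "meta": meta or {}}
    payload["header"] = np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8
    )
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple[CoordUNet3D, dict]:
    """Load a checkpoint; verifies the 14-class output contract."""
    with np.load(path) as data:
        header = json.loads(bytes(data["header"].tobytes()).decode())
        cfg = NetworkConfig(**header["config"])  # re-validates out_channels
        net = CoordUNet3D(cfg, rng=0)
        state = {
            k[len("param::") :]: data[k] for k in data.files if k.startswith("param::")
        }
    net.load_state(state)
    return net, header["meta"]
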