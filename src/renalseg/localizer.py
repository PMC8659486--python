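"""3D Rb-UNet: coarse three-class kidney localisation and bounding boxes.

The localiser is a residual U-Net over the 5-channel, 64^3 reduced volume.
Its three output classes are background / right kidney / left kidney; the
per-class coarse masks are mapped back to the original resolution as minimum
bounding boxes, with an absent kidney encoded as a single-voxel
``present=False`` box.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .nn import (
    BatchNorm3d,
    Conv3d,
    ConvTranspose3d,
    Dropout,
    Module,
    Tensor,
)
from .nn import functional as F
from .nn.tensor import no_grad
from .preprocess import preprocess_series
from .training import OptimizerConfig, fit, weighted_cross_entropy
from .volumes import BoundingBox3D, DceSeries, KidneyMask

__all__ = [
    "RbUNetConfig",
    "CoarsePrediction",
    "RbUNet",
    "build_rb_unet",
    "weighted_cross_entropy",
    "train_localizer",
    "split_left_right",
    "predict_coarse_labels",
    "boxes_from_coarse_labels",
    "predict_boxes",
    "save_checkpoint",
    "load_localizer",
]

CLASS_BACKGROUND, CLASS_RIGHT, CLASS_LEFT = 0, 1, 2


@dataclass
class RbUNetConfig:
    in_channels: int = 5
    n_classes: int = 3
    encoder_blocks: int = 4
    decoder_blocks: int = 5
    base_filters: int = 32
    dropout_rate: float = 0.2
    seed: int = 0


@dataclass
class CoarsePrediction:
    """Per-voxel softmax over the three classes plus the argmax labels."""

    class_probs: np.ndarray  # (3, 64, 64, 64)
    argmax_labels: np.ndarray  # (64, 64, 64) over {0, 1, 2}


class _ResidualBlock(Module):
    """Two 3x3x3 conv+ReLU with an additive identity shortcut from the block
    input (1x1x1 projection when channel counts differ)."""

    def __init__(self, cin: int, cout: int, rng, residual: bool = True):
        super().__init__()
        self.conv1 = Conv3d(cin, cout, 3, rng=rng)
        self.conv2 = Conv3d(cout, cout, 3, rng=rng)
        self.residual = residual
        self.proj = Conv3d(cin, cout, 1, bias=False, rng=rng) if (residual and cin != cout) else None

    def forward(self, x: Tensor) -> Tensor:
        out = F.relu(self.conv2(F.relu(self.conv1(x))))
        if not self.residual:
            return out
        shortcut = self.proj(x) if self.proj is not None else x
        return F.add(out, shortcut)


class RbUNet(Module):
    """Residual U-Net: 4 encoder blocks (each pooled 2x), a bottleneck and 5
    decoder blocks (4 upsampling + 1 full-resolution), with skip
    concatenation at equal scales and a BN + 1x1x1 head to 3 classes."""

    def __init__(self, config: RbUNetConfig, residual: bool = True):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        f = config.base_filters
        widths = [f * 2**i for i in range(config.encoder_blocks)]
        self.enc = []
        cin = config.in_channels
        for w in widths:
            self.enc.append(_ResidualBlock(cin, w, rng, residual))
            cin = w
        self.enc_drop = [Dropout(config.dropout_rate) for _ in widths]
        bw = widths[-1] * 2
        self.bott_conv1 = Conv3d(cin, bw, 3, rng=rng)
        self.bott_drop = Dropout(config.dropout_rate)
        self.bott_conv2 = Conv3d(bw, bw, 3, rng=rng)
        self.up = []
        self.dec = []
        cin = bw
        for w in reversed(widths):
            self.up.append(ConvTranspose3d(cin, w, kernel=2, stride=2, rng=rng))
            self.dec.append(_ResidualBlock(2 * w, w, rng, residual))
            cin = w
        # fifth decoder block: full-resolution refinement, no upsampling left
        self.dec_final = _ResidualBlock(cin, cin, rng, residual)
        self.head_bn = BatchNorm3d(cin)
        self.head = Conv3d(cin, config.n_classes, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        spatial = x.data.shape[2:]
        factor = 2 ** len(self.enc)
        if any(s % factor for s in spatial):
            raise ValueError(f"input spatial size {spatial} must divide by {factor}")
        x = F.scale(x, 1.0 / 255.0)  # display-scale input to unit scale
        skips = []
        for block, drop in zip(self.enc, self.enc_drop):
            x = block(x)
            skips.append(x)
            x = drop(F.max_pool3d(x, 2))
        x = F.relu(self.bott_conv1(x))
        x = self.bott_drop(x)
        x = F.relu(self.bott_conv2(x))
        for up, dec, skip in zip(self.up, self.dec, reversed(skips)):
            x = up(x)
            x = dec(F.concat([skip, x], axis=1))
        x = self.dec_final(x)
        return self.head(self.head_bn(x))

    def predict(self, x: np.ndarray) -> CoarsePrediction:
        """Eval-mode forward of one ``(5, 64, 64, 64)`` reduced volume."""
        self.eval()
        with no_grad():
            probs = F.softmax_channel(self.forward(Tensor(x[None]))).data[0]
        return CoarsePrediction(class_probs=probs, argmax_labels=probs.argmax(axis=0))


def build_rb_unet(config: RbUNetConfig | None = None, residual: bool = True) -> RbUNet:
    return RbUNet(config or RbUNetConfig(), residual=residual)


def split_left_right(mask: KidneyMask | np.ndarray) -> np.ndarray:
    """Three-class localisation target from a whole-kidney mask.

    Connected components are assigned to the right (class 1) or left
    (class 2) kidney by which side of the volume's mid-x plane their
    centroid falls on (the right kidney sits at low x).
    """
    data = mask.data if isinstance(mask, KidneyMask) else np.asarray(mask)
    out = np.zeros(data.shape, np.uint8)
    comp, n = ndimage.label(data > 0)
    if n == 0:
        return out
    mid = data.shape[2] / 2.0
    for cid in range(1, n + 1):
        sel = comp == cid
        cx = np.argwhere(sel)[:, 2].mean()
        out[sel] = CLASS_RIGHT if cx < mid else CLASS_LEFT
    return out


def downsample_labels(labels: np.ndarray, target=(64, 64, 64)) -> np.ndarray:
    factors = [t / s for t, s in zip(target, labels.shape)]
    out = ndimage.zoom(labels, factors, order=0, mode="nearest", grid_mode=True)
    return out[: target[0], : target[1], : target[2]]


def train_localizer(
    dataset: list[tuple[np.ndarray, np.ndarray]],
    config: RbUNetConfig | None = None,
    optimizer_config: OptimizerConfig | None = None,
) -> tuple[RbUNet, list[float]]:
    """Train the localiser on ``(reduced 5-channel volume, 3-class labels)``
    pairs; returns the model and the per-epoch loss history."""
    config = config or RbUNetConfig()
    model = build_rb_unet(config)
    history = fit(model, dataset, config.n_classes, optimizer_config or OptimizerConfig())
    return model, history


def predict_coarse_labels(model, series: DceSeries, **preproc_kwargs) -> np.ndarray:
    """Preprocess a series and return the 64^3 argmax class labels."""
    reduced = preprocess_series(series, **preproc_kwargs)
    return model.predict(reduced.data).argmax_labels


def boxes_from_coarse_labels(
    labels64: np.ndarray,
    original_shape: tuple[int, int, int],
    margin_cells: int = 0,
) -> tuple[BoundingBox3D, BoundingBox3D]:
    """Map per-class coarse masks to original-resolution minimum boxes.

    Returns ``(left, right)``; an empty class yields the absent-kidney
    single-voxel box.  ``margin_cells`` expands the box by that many coarse
    grid cells per side (clamped), compensating the quantisation of the
    coarse grid.
    """
    scale = [o / c for o, c in zip(original_shape, labels64.shape)]

    def box_for(cls: int) -> BoundingBox3D:
        fg = np.argwhere(labels64 == cls)
        if fg.size == 0:
            return BoundingBox3D.absent()
        lo = fg.min(axis=0) - margin_cells
        hi = fg.max(axis=0) + margin_cells
        mins = [max(0, int(np.floor(l * s))) for l, s in zip(lo, scale)]
        maxs = [
            min(int(np.ceil((h + 1) * s)) - 1, o - 1)
            for h, s, o in zip(hi, scale, original_shape)
        ]
        return BoundingBox3D(mins[0], maxs[0], mins[1], maxs[1], mins[2], maxs[2])

    return box_for(CLASS_LEFT), box_for(CLASS_RIGHT)


def predict_boxes(
    model, series: DceSeries, margin_cells: int = 1, **preproc_kwargs
) -> tuple[BoundingBox3D, BoundingBox3D]:
    """Coarse segmentation of a series followed by per-kidney box generation.

    A one-cell margin absorbs the coarse grid's quantisation so the box still
    encloses foreground lost to nearest-neighbour downsampling.
    """
    labels64 = predict_coarse_labels(model, series, **preproc_kwargs)
    return boxes_from_coarse_labels(labels64, series.shape, margin_cells=margin_cells)


def save_checkpoint(model: Module, path: str | Path) -> None:
    """Persist parameters, buffers and (when present) the network config."""
    import dataclasses
    import json

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    config = getattr(model, "config", None)
    if config is not None:
        state["__config__"] = np.frombuffer(
            json.dumps(dataclasses.asdict(config)).encode(), dtype=np.uint8
        )
    np.savez(path, **state)


def _load_state(path: str | Path) -> tuple[dict, dict | None]:
    import json

    with np.load(Path(path)) as raw:
        state = dict(raw)
    config = None
    if "__config__" in state:
        config = json.loads(state.pop("__config__").tobytes().decode())
    return state, config


def load_localizer(path: str | Path, config: RbUNetConfig | None = None) -> RbUNet:
    state, saved = _load_state(path)
    if config is None:
        config = RbUNetConfig(**saved) if saved else RbUNetConfig()
    model = build_rb_unet(config)
    model.load_state_dict(state)
    return model
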