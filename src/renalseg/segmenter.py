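"""3D FC-DenseNet: binary whole-kidney segmentation of cropped regions.

A fully convolutional DenseNet ("Tiramisu") over the 5-channel 64^3 crop:
six dense blocks of 4/5/7/10/12/15 layers on the down path (transition-down
after the first five), five transition-up blocks each followed by a dense
block of 12/10/7/5/4 layers with skip concatenation, and a 1x1x1 softmax
head over kidney / non-kidney.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .nn import BatchNorm3d, Conv3d, ConvTranspose3d, Dropout, Module, Tensor
from .nn import functional as F
from .nn.tensor import no_grad
from .preprocess import downsample_spatial, pca_reduce, resample_temporal, rescale_to_255
from .training import OptimizerConfig, fit
from .volumes import BoundingBox3D, DceSeries, KidneyMask, crop, paste_into

__all__ = [
    "FcDenseNetConfig",
    "FcDenseNet",
    "build_fc_densenet",
    "train_segmenter",
    "predict_kidney_mask",
    "load_segmenter",
]


@dataclass
class FcDenseNetConfig:
    in_channels: int = 5
    n_classes: int = 2
    down_block_layers: tuple[int, ...] = (4, 5, 7, 10, 12, 15)
    up_block_layers: tuple[int, ...] = (12, 10, 7, 5, 4)
    growth_rate: int = 12
    reduction: float = 0.8
    initial_filters: int = 48
    dropout_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.down_block_layers) != len(self.up_block_layers) + 1:
            raise ValueError("need one more down block (bottleneck) than up blocks")
        if self.growth_rate <= 0:
            raise ValueError("growth rate must be positive")


class _DenseLayer(Module):
    """BN -> ReLU -> 3x3x3 conv (growth_rate channels) -> dropout."""

    def __init__(self, cin: int, growth: int, dropout_rate: float, rng):
        super().__init__()
        self.bn = BatchNorm3d(cin)
        self.conv = Conv3d(cin, growth, 3, rng=rng)
        self.drop = Dropout(dropout_rate)

    def forward(self, x: Tensor) -> Tensor:
        return self.drop(self.conv(F.relu(self.bn(x))))


class _DenseBlock(Module):
    """``n_layers`` dense layers; each layer's input is the concatenation of
    the block input with all previous layers' outputs."""

    def __init__(self, cin: int, n_layers: int, growth: int, dropout_rate: float, rng):
        super().__init__()
        self.layers = [
            _DenseLayer(cin + i * growth, growth, dropout_rate, rng) for i in range(n_layers)
        ]
        self.out_channels = cin + n_layers * growth
        self.new_channels = n_layers * growth

    def forward_full(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (input ++ new features, new features only)."""
        feats = [x]
        new = []
        for layer in self.layers:
            cur = feats[0] if len(feats) == 1 else F.concat(feats, axis=1)
            y = layer(cur)
            feats.append(y)
            new.append(y)
        full = F.concat(feats, axis=1)
        new_cat = new[0] if len(new) == 1 else F.concat(new, axis=1)
        return full, new_cat

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_full(x)[0]


class _TransitionDown(Module):
    """BN -> ReLU -> 1x1x1 conv (channel reduction) -> dropout -> 2x max-pool."""

    def __init__(self, cin: int, reduction: float, dropout_rate: float, rng):
        super().__init__()
        self.out_channels = int(np.floor(cin * reduction))
        self.bn = BatchNorm3d(cin)
        self.conv = Conv3d(cin, self.out_channels, 1, rng=rng)
        self.drop = Dropout(dropout_rate)

    def forward(self, x: Tensor) -> Tensor:
        return F.max_pool3d(self.drop(self.conv(F.relu(self.bn(x)))), 2)


class FcDenseNet(Module):
    def __init__(self, config: FcDenseNetConfig | None = None):
        super().__init__()
        self.config = config = config or FcDenseNetConfig()
        rng = np.random.default_rng(config.seed)
        g = config.growth_rate
        self.init_conv = Conv3d(config.in_channels, config.initial_filters, 3, rng=rng)
        ch = config.initial_filters
        self.down_blocks = []
        self.down_trans = []
        skip_channels = []
        for n_layers in config.down_block_layers[:-1]:
            block = _DenseBlock(ch, n_layers, g, config.dropout_rate, rng)
            self.down_blocks.append(block)
            skip_channels.append(block.out_channels)
            td = _TransitionDown(block.out_channels, config.reduction, config.dropout_rate, rng)
            self.down_trans.append(td)
            ch = td.out_channels
        self.bottleneck = _DenseBlock(
            ch, config.down_block_layers[-1], g, config.dropout_rate, rng
        )
        self.up_trans = []
        self.up_blocks = []
        new_ch = self.bottleneck.new_channels
        for n_layers, skip_ch in zip(config.up_block_layers, reversed(skip_channels)):
            tu = ConvTranspose3d(new_ch, new_ch, kernel=3, stride=2, pad=1, output_padding=1, rng=rng)
            self.up_trans.append(tu)
            block = _DenseBlock(skip_ch + new_ch, n_layers, g, config.dropout_rate, rng)
            self.up_blocks.append(block)
            new_ch = block.new_channels
        self.head = Conv3d(self.up_blocks[-1].out_channels, config.n_classes, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        spatial = x.data.shape[2:]
        factor = 2 ** len(self.down_trans)
        if any(s % factor for s in spatial):
            raise ValueError(f"input spatial size {spatial} must divide by {factor}")
        # display-scale input to unit scale: the init-conv channels reach the
        # head through the dense concatenation, so unnormalised input would
        # saturate the softmax at initialisation
        x = self.init_conv(F.scale(x, 1.0 / 255.0))
        skips = []
        for block, td in zip(self.down_blocks, self.down_trans):
            full = block(x)
            skips.append(full)
            x = td(full)
        _, new = self.bottleneck.forward_full(x)
        out = None
        for tu, block, skip in zip(self.up_trans, self.up_blocks, reversed(skips)):
            up = tu(new)
            out, new = block.forward_full(F.concat([skip, up], axis=1))
        return self.head(out)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Eval-mode argmax labels for one ``(5, d, h, w)`` volume."""
        self.eval()
        with no_grad():
            probs = F.softmax_channel(self.forward(Tensor(x[None]))).data[0]
        return probs.argmax(axis=0).astype(np.uint8)


def build_fc_densenet(config: FcDenseNetConfig | None = None) -> FcDenseNet:
    return FcDenseNet(config)


def train_segmenter(
    cropped_dataset: list[tuple[np.ndarray, np.ndarray]],
    config: FcDenseNetConfig | None = None,
    optimizer_config: OptimizerConfig | None = None,
) -> tuple[FcDenseNet, list[float]]:
    """Train on per-kidney crops: ``(5-channel volume, binary labels)``."""
    config = config or FcDenseNetConfig()
    model = build_fc_densenet(config)
    history = fit(model, cropped_dataset, config.n_classes, optimizer_config or OptimizerConfig())
    return model, history


def preprocess_crop(
    series: DceSeries,
    box: BoundingBox3D,
    pad: int = 0,
    n_samples: int = 50,
    max_seconds: float = 300.0,
    n_components: int = 5,
    target: tuple[int, int, int] = (64, 64, 64),
) -> tuple[np.ndarray, BoundingBox3D]:
    """Crop a series to a kidney box and fit it to the network input size."""
    sub, used = crop(series, box, pad=pad)
    res = resample_temporal(sub, n_samples=n_samples, max_seconds=max_seconds)
    red = pca_reduce(res, n_components=n_components)
    data = rescale_to_255(downsample_spatial(red.data, target=target))
    return data, used


def predict_kidney_mask(
    model,
    series: DceSeries,
    box: BoundingBox3D,
    side: str = "both",
    pad: int = 0,
    **preproc_kwargs,
) -> KidneyMask:
    """Whole-kidney mask at original resolution for one bounding box.

    An absent box yields an all-zero mask.  The 64^3 prediction is resampled
    back to the crop extent with nearest-neighbour interpolation (preserving
    binarity) and pasted at the box offset.
    """
    if not box.present:
        return KidneyMask(data=np.zeros(series.shape, np.uint8), side=side)
    x, used = preprocess_crop(series, box, pad=pad, **preproc_kwargs)
    pred = model.predict(x)
    factors = [e / p for e, p in zip(used.extent, pred.shape)]
    up = ndimage.zoom(pred, factors, order=0, mode="nearest", grid_mode=True)
    up = up[: used.extent[0], : used.extent[1], : used.extent[2]]
    mask = paste_into(
        KidneyMask(data=(up > 0).astype(np.uint8), side=side), used, series.shape
    )
    return mask


def load_segmenter(path: str | Path, config: FcDenseNetConfig | None = None) -> FcDenseNet:
    from .localizer import _load_state

    state, saved = _load_state(path)
    if config is None and saved:
        saved["down_block_layers"] = tuple(saved["down_block_layers"])
        saved["up_block_layers"] = tuple(saved["up_block_layers"])
        config = FcDenseNetConfig(**saved)
    model = build_fc_densenet(config)
    model.load_state_dict(state)
    return model
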