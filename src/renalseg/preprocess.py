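"""Temporal standardisation and channel reduction for network input.

The networks consume a 5-channel 64x64x64 tensor per scan.  A raw 4D series
is first interpolated onto a uniform temporal grid (50 frames over five
minutes by default), the time axis is then reduced to 5 channels by a
per-scan principal component analysis of the voxel x time matrix, the result
is trilinearly downsampled to 64^3 and linearly rescaled to [0, 255].
Training-time augmentation applies a small random integer translation and
zoom, identically to image and label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.decomposition import PCA

from .volumes import DceSeries

__all__ = [
    "ReducedVolume",
    "resample_temporal",
    "pca_reduce",
    "downsample_spatial",
    "rescale_to_255",
    "AugmentParams",
    "draw_augmentation",
    "apply_augmentation",
    "augment",
    "preprocess_series",
]


@dataclass
class ReducedVolume:
    """A channel-reduced scan: ``(c, z, y, x)`` float array plus the fraction
    of temporal variance each principal component explains."""

    data: np.ndarray
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, np.float32)
        self.explained_variance_ratio = np.asarray(self.explained_variance_ratio, float)
        if self.data.ndim != 4:
            raise ValueError("reduced volume must be (c, z, y, x)")


def resample_temporal(
    series: DceSeries, n_samples: int = 50, max_seconds: float = 300.0
) -> DceSeries:
    """Per-voxel linear interpolation onto ``n_samples`` uniform times.

    The grid covers ``(0, max_seconds]``; values outside the acquired range
    are clamped to the nearest acquired frame.
    """
    if series.T < 2:
        raise ValueError("temporal resampling needs at least two frames")
    new_times = np.linspace(max_seconds / n_samples, max_seconds, n_samples)
    t = series.times
    idx = np.searchsorted(t, new_times, side="left")
    idx = np.clip(idx, 1, len(t) - 1)
    t0, t1 = t[idx - 1], t[idx]
    w = (new_times - t0) / (t1 - t0)
    w = np.clip(w, 0.0, 1.0)  # clamp beyond the acquired range
    w = np.where(new_times <= t[0], 0.0, w)
    lo = series.data[idx - 1]
    hi = series.data[idx]
    shaped = w[(slice(None),) + (None,) * 3]
    data = (1.0 - shaped) * lo + shaped * hi
    return DceSeries(data=data.astype(np.float32), times=new_times, spacing=series.spacing)


def pca_reduce(series: DceSeries, n_components: int = 5) -> ReducedVolume:
    """Reduce the time axis to ``n_components`` principal-component channels.

    Each voxel's time course is one sample of a ``T``-dimensional feature
    space; the components are the leading eigendirections of the time-time
    covariance taken over voxels, fitted per scan.  Channels are ordered by
    decreasing explained variance, and each component's sign is fixed so its
    largest-magnitude loading is positive (reproducibility).  Zero-variance
    input yields zero ratios without error.
    """
    T = series.T
    if T < n_components:
        raise ValueError(f"need T >= {n_components} frames, got {T}")
    X = series.data.reshape(T, -1).T  # (voxels, T)
    if np.allclose(X.std(axis=0), 0.0):
        data = np.zeros((n_components,) + series.shape, np.float32)
        return ReducedVolume(data=data, explained_variance_ratio=np.zeros(n_components))
    pca = PCA(n_components=n_components, svd_solver="covariance_eigh")
    Z = pca.fit_transform(X)  # (voxels, c)
    flip = np.where(
        pca.components_[np.arange(n_components), np.abs(pca.components_).argmax(axis=1)] < 0,
        -1.0,
        1.0,
    )
    Z = Z * flip
    data = Z.T.reshape((n_components,) + series.shape).astype(np.float32)
    return ReducedVolume(
        data=data, explained_variance_ratio=pca.explained_variance_ratio_.copy()
    )


def downsample_spatial(
    volume: np.ndarray, target: tuple[int, int, int] = (64, 64, 64)
) -> np.ndarray:
    """Trilinear resampling of a ``(c, z, y, x)`` or 3D volume to ``target``."""
    vol = np.asarray(volume, np.float32)
    squeeze = vol.ndim == 3
    if squeeze:
        vol = vol[None]
    factors = [t / s for t, s in zip(target, vol.shape[1:])]
    out = np.stack(
        [ndimage.zoom(c, factors, order=1, mode="nearest", grid_mode=True) for c in vol]
    )
    # guard against off-by-one rounding in zoom's output size
    if out.shape[1:] != tuple(target):
        out = out[:, : target[0], : target[1], : target[2]]
    return out[0] if squeeze else out


def rescale_to_255(volume: np.ndarray) -> np.ndarray:
    """Linear map of [min, max] to [0, 255]; a constant volume maps to 0."""
    vol = np.asarray(volume, np.float32)
    lo, hi = float(vol.min()), float(vol.max())
    if hi <= lo:
        return np.zeros_like(vol)
    return (vol - lo) * (255.0 / (hi - lo))


@dataclass(frozen=True)
class AugmentParams:
    """One sampled augmentation: per-axis integer shift and isotropic zoom."""

    shift: tuple[int, int, int]
    zoom: float


def draw_augmentation(
    rng: np.random.Generator,
    translate_range: tuple[int, int] = (1, 4),
    zoom_range: tuple[float, float] = (0.96, 1.04),
) -> AugmentParams:
    lo, hi = translate_range
    mags = rng.integers(lo, hi + 1, size=3)
    signs = rng.choice((-1, 1), size=3)
    zoom = float(rng.uniform(*zoom_range))
    return AugmentParams(shift=tuple(int(m * s) for m, s in zip(mags, signs)), zoom=zoom)


def _shift_int(vol: np.ndarray, shift: tuple[int, int, int]) -> np.ndarray:
    out = np.zeros_like(vol)
    src = []
    dst = []
    for s, n in zip(shift, vol.shape[-3:]):
        if abs(s) >= n:
            return out
        src.append(slice(max(0, -s), n - max(0, s)))
        dst.append(slice(max(0, s), n - max(0, -s)))
    if vol.ndim == 4:
        out[(slice(None),) + tuple(dst)] = vol[(slice(None),) + tuple(src)]
    else:
        out[tuple(dst)] = vol[tuple(src)]
    return out


def _zoom_about_center(vol: np.ndarray, factor: float, order: int) -> np.ndarray:
    if factor == 1.0:
        return vol
    spatial = vol.shape[-3:]

    def _one(v):
        z = ndimage.zoom(v, factor, order=order, mode="nearest")
        out = np.zeros(spatial, v.dtype)
        src, dst = [], []
        for n, m in zip(spatial, z.shape):
            if m >= n:
                off = (m - n) // 2
                src.append(slice(off, off + n))
                dst.append(slice(0, n))
            else:
                off = (n - m) // 2
                src.append(slice(0, m))
                dst.append(slice(off, off + m))
        out[tuple(dst)] = z[tuple(src)]
        return out

    if vol.ndim == 4:
        return np.stack([_one(c) for c in vol])
    return _one(vol)


def apply_augmentation(
    image: np.ndarray, label: np.ndarray, params: AugmentParams
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one transform identically to a channel image and its label map.

    Translation is by whole voxels with zero fill; zoom is about the volume
    centre, trilinear for the image and nearest-neighbour for the label.
    """
    img = _zoom_about_center(np.asarray(image, np.float32), params.zoom, order=1)
    lab = _zoom_about_center(np.asarray(label), params.zoom, order=0)
    return _shift_int(img, params.shift), _shift_int(lab, params.shift)


def augment(
    sample: tuple[np.ndarray, np.ndarray], seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random augmentation of an (image, label) training pair."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    params = draw_augmentation(rng)
    return apply_augmentation(sample[0], sample[1], params)


def preprocess_series(
    series: DceSeries,
    n_samples: int = 50,
    max_seconds: float = 300.0,
    n_components: int = 5,
    target: tuple[int, int, int] = (64, 64, 64),
) -> ReducedVolume:
    """Full network-input pipeline: temporal resample -> PCA -> downsample ->
    rescale to [0, 255]."""
    res = resample_temporal(series, n_samples=n_samples, max_seconds=max_seconds)
    red = pca_reduce(res, n_components=n_components)
    data = downsample_spatial(red.data, target=target)
    data = rescale_to_255(data)
    return ReducedVolume(data=data, explained_variance_ratio=red.explained_variance_ratio)
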