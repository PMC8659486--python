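"""Synthetic 4D DCE-MRI phantom generator with exact ground truth.

The phantom emulates the structure the segmentation pipeline assumes: one or
two ellipsoidal kidneys either side of the sagittal midline, each with a
bright cortical shell (and internal cortical columns) surrounding darker
medullary lobes, compartment-specific contrast-enhancement time courses in
which the cortex peaks earlier than the medulla, additive noise, and optional
streak/blur artefacts of the kind produced by undersampled radial
acquisitions and breathing motion.  Abnormal variants cover a missing kidney
and a dilated collecting system (hydronephrosis-like central cavity).

Intensities live on a [0, 255] scale.  All randomness is driven by the
config seed; the same config yields a bit-identical phantom.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volumes import CompartmentLabels, DceSeries, KidneyMask

__all__ = ["CompartmentKinetics", "PhantomConfig", "PhantomTruth", "enhancement_curve", "generate", "add_artefacts"]


@dataclass(frozen=True)
class CompartmentKinetics:
    """Enhancement time-course parameters for one tissue compartment.

    ``baseline`` is the pre-contrast tissue intensity above background,
    ``amplitude`` the peak enhancement, ``time_to_peak`` seconds from
    injection to maximum, and ``washout`` the post-peak exponential decay
    rate (1/s).
    """

    baseline: float
    amplitude: float
    time_to_peak: float
    washout: float


# Defaults chosen so the cortex rises fast (arterial phase) and stays brighter
# than the slower, lower-amplitude medullary enhancement over the whole
# six-minute window, matching the contrast ordering the rule-based
# compartment algorithm relies on.
DEFAULT_KINETICS: dict[str, CompartmentKinetics] = {
    "cortex": CompartmentKinetics(baseline=40.0, amplitude=170.0, time_to_peak=40.0, washout=0.004),
    "medulla": CompartmentKinetics(baseline=30.0, amplitude=60.0, time_to_peak=90.0, washout=0.003),
}


@dataclass
class PhantomConfig:
    """Configuration of one synthetic scan.

    Defaults follow the canonical acquisition geometry: 32 coronal slices of
    224x224 at 1.25x1.25x3 mm, ~50 frames over five minutes.
    """

    shape: tuple[int, int, int] = (32, 224, 224)  # (D, H, W)
    T: int = 50
    duration: float = 300.0
    n_kidneys: int = 2
    cortex_thickness: int = 2
    n_lobes: int | None = None  # None: draw 2-4 per kidney from the seed
    kinetics: dict[str, CompartmentKinetics] = field(
        default_factory=lambda: dict(DEFAULT_KINETICS)
    )
    background_level: float = 20.0
    noise_sigma: float = 4.0
    noise_model: str = "gaussian"  # or "rician"
    streak_amplitude: float = 0.0
    blur_sigma: float = 0.0
    abnormality: str = "none"  # none | missing_kidney | dilated_pelvis
    spacing: tuple[float, float, float] = (3.0, 1.25, 1.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_kidneys not in (0, 1, 2):
            raise ValueError("n_kidneys must be 0, 1 or 2")
        if self.abnormality not in ("none", "missing_kidney", "dilated_pelvis"):
            raise ValueError(f"unknown abnormality {self.abnormality!r}")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        for name, k in self.kinetics.items():
            if k.amplitude < 0:
                raise ValueError(f"{name} amplitude must be non-negative")
        ck = self.kinetics["cortex"]
        mk = self.kinetics["medulla"]
        if not ck.time_to_peak < mk.time_to_peak:
            raise ValueError("cortex time-to-peak must precede medulla time-to-peak")


@dataclass
class PhantomTruth:
    """A generated series with its exact ground truth."""

    series: DceSeries
    labels: CompartmentLabels
    left_mask: KidneyMask
    right_mask: KidneyMask

    @property
    def whole_mask(self) -> KidneyMask:
        return KidneyMask(
            data=((self.left_mask.data | self.right_mask.data) > 0).astype(np.uint8),
            side="both",
        )


def enhancement_curve(
    compartment: str, t: np.ndarray | float, kinetics: dict[str, CompartmentKinetics]
) -> np.ndarray:
    """Deterministic tissue enhancement at time ``t`` seconds post injection.

    The curve starts at the compartment baseline, rises smoothly (half-sine)
    to ``baseline + amplitude`` at the configured time-to-peak and then
    washes out exponentially towards baseline.
    """
    k = kinetics[compartment]
    if k.amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    t = np.asarray(t, dtype=float)
    rise = k.baseline + k.amplitude * np.sin(0.5 * np.pi * np.minimum(t, k.time_to_peak) / k.time_to_peak)
    decay = k.baseline + k.amplitude * np.exp(-k.washout * np.maximum(t - k.time_to_peak, 0.0))
    return np.where(t <= k.time_to_peak, rise, decay)


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = center
    az, ay, ax = semi_axes
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _make_kidney(
    shape: tuple[int, int, int],
    center: tuple[float, float, float],
    cortex_thickness: int,
    n_lobes: int | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One kidney's (mask, labels): cortical shell + columns, medullary lobes.

    Size, position and lobe count vary with the seed, emulating the broad
    anatomical variability of a paediatric cohort.
    """
    D, H, W = shape
    # kidneys span most of the coronal stack, as in the acquisitions the
    # pipeline targets, so the central slice range cuts through parenchyma
    # containing both compartments
    semi = (
        rng.uniform(0.36, 0.44) * D,
        rng.uniform(0.19, 0.25) * H,
        rng.uniform(0.095, 0.125) * W,
    )
    center = (
        center[0] + rng.uniform(-0.02, 0.02) * D,
        center[1] + rng.uniform(-0.03, 0.03) * H,
        center[2] + rng.uniform(-0.015, 0.015) * W,
    )
    if n_lobes is None:
        n_lobes = int(rng.integers(2, 5))
    if min(semi) < cortex_thickness + 2:
        raise ValueError(
            f"kidney of semi-axes {semi} does not fit a cortex shell of "
            f"thickness {cortex_thickness} in volume {shape}"
        )
    mask = _ellipsoid(shape, center, semi)
    interior = ndimage.binary_erosion(
        mask, structure=np.ones((3, 3, 3), bool), iterations=cortex_thickness
    )
    if not interior.any():
        raise ValueError("cortex shell consumes the whole kidney; enlarge the volume")
    # Medullary lobes: rod-shaped pyramids strung along the long (y) axis,
    # elongated through the slice direction so every interior slice shows
    # medulla.  The in-plane radius is capped at cortex_thickness+1 so every
    # medulla voxel keeps a cortex voxel nearby; the rest of the interior
    # acts as cortical columns.
    r_lobe = cortex_thickness + 1
    lobes = np.zeros(shape, bool)
    cz, cy, cx = center
    offsets = np.linspace(-0.55, 0.55, n_lobes) * semi[1]
    for dy in offsets:
        lobes |= _ellipsoid(shape, (cz, cy + dy, cx), (semi[0], r_lobe, r_lobe))
    medulla = lobes & interior
    labels = np.zeros(shape, np.uint8)
    labels[mask] = 2
    labels[medulla] = 1
    return mask.astype(np.uint8), labels


def generate(config: PhantomConfig) -> PhantomTruth:
    """Generate a phantom scan with exact compartment labels and side masks."""
    D, H, W = config.shape
    rng = np.random.default_rng(config.seed)
    empty = np.zeros(config.shape, np.uint8)
    labels = np.zeros(config.shape, np.uint8)
    left_mask, right_mask = empty.copy(), empty.copy()

    want_right = config.n_kidneys >= 1
    want_left = config.n_kidneys == 2 and config.abnormality != "missing_kidney"
    cz, cy = D / 2.0 - 0.5, H / 2.0 - 0.5
    if want_right:
        right_mask, lab = _make_kidney(
            config.shape, (cz, cy, 0.25 * W), config.cortex_thickness, config.n_lobes, rng
        )
        labels = np.where(lab > 0, lab, labels)
    if want_left:
        left_mask, lab = _make_kidney(
            config.shape, (cz, cy, 0.75 * W), config.cortex_thickness, config.n_lobes, rng
        )
        labels = np.where(lab > 0, lab, labels)

    if config.abnormality == "dilated_pelvis" and want_left:
        # Fluid-filled central cavity replacing parenchyma of the left kidney:
        # excluded from the mask and labels, non-enhancing in the signal.
        cavity = _ellipsoid(
            config.shape,
            (cz, cy, 0.75 * W),
            (max(1.5, 0.12 * D), 0.10 * H, 0.05 * W),
        )
        left_mask = np.where(cavity, 0, left_mask).astype(np.uint8)
        labels = np.where(cavity, 0, labels)

    times = np.linspace(config.duration / config.T, config.duration, config.T)
    frames = np.empty((config.T, D, H, W), np.float32)
    med_curve = enhancement_curve("medulla", times, config.kinetics)
    cor_curve = enhancement_curve("cortex", times, config.kinetics)
    med = labels == 1
    cor = labels == 2
    for i in range(config.T):
        frame = np.full(config.shape, config.background_level, np.float32)
        frame[med] += med_curve[i]
        frame[cor] += cor_curve[i]
        frames[i] = frame

    if config.noise_sigma > 0:
        if config.noise_model == "gaussian":
            frames = frames + rng.normal(0.0, config.noise_sigma, frames.shape)
        else:  # Rician: magnitude of a complex Gaussian around the signal
            n1 = rng.normal(0.0, config.noise_sigma, frames.shape)
            n2 = rng.normal(0.0, config.noise_sigma, frames.shape)
            frames = np.hypot(frames + n1, n2)
    frames = np.clip(frames, 0.0, 255.0).astype(np.float32)

    series = DceSeries(data=frames, times=times, spacing=config.spacing)
    truth = PhantomTruth(
        series=series,
        labels=CompartmentLabels(data=labels),
        left_mask=KidneyMask(data=left_mask, side="left"),
        right_mask=KidneyMask(data=right_mask, side="right"),
    )
    if config.streak_amplitude > 0 or config.blur_sigma > 0:
        truth = replace(truth, series=add_artefacts(series, config))
    return truth


def add_artefacts(series: DceSeries, config: PhantomConfig) -> DceSeries:
    """Overlay radial streaks and per-frame Gaussian blur on a series.

    Streaks are a zero-mean angular spoke pattern about the in-plane centre,
    constant along z (as produced by a stack-of-stars acquisition) with a
    random per-frame rotation; blur is applied per frame over all three
    spatial axes.  Zero amplitudes leave the series untouched.
    """
    if config.streak_amplitude <= 0 and config.blur_sigma <= 0:
        return series
    data = series.data.copy()
    T, D, H, W = data.shape
    if config.streak_amplitude > 0:
        rng = np.random.default_rng(config.seed + 1)
        yy, xx = np.mgrid[:H, :W]
        theta = np.arctan2(yy - (H - 1) / 2.0, xx - (W - 1) / 2.0)
        for t in range(T):
            phase = rng.uniform(0, 2 * np.pi)
            pattern = config.streak_amplitude * np.sin(24.0 * theta + phase)
            data[t] += pattern[None, :, :]
    if config.blur_sigma > 0:
        for t in range(T):
            data[t] = ndimage.gaussian_filter(
                data[t], sigma=config.blur_sigma, mode="nearest"
            )
    data = np.clip(data, 0.0, 255.0)
    return DceSeries(data=data, times=series.times.copy(), spacing=series.spacing)
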