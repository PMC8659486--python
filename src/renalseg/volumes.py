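"""Core data model and file I/O for 4D DCE-MRI series, masks, labels and boxes.

In-memory axis order is canonical ``(t, z, y, x)`` where ``z`` indexes the
coronal slice (the acquisition's depth ``D``).  On disk, NIfTI stores
``(x, y, z, t)``; the readers and writers here transpose between the two.
Acquisition times and voxel spacing travel in a small JSON sidecar next to
each NIfTI file when the header cannot carry them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "DceSeries",
    "KidneyMask",
    "CompartmentLabels",
    "BoundingBox3D",
    "read_dce",
    "write_dce",
    "read_mask",
    "write_mask",
    "read_labels",
    "write_labels",
    "compute_bounding_box",
    "crop",
    "paste_into",
]

LABEL_BACKGROUND = 0
LABEL_MEDULLA = 1
LABEL_CORTEX = 2


@dataclass
class DceSeries:
    """A 4D DCE-MRI scan: ``T`` 3D volumes over time.

    Parameters
    ----------
    data
        Float array indexed ``(t, z, y, x)`` with non-negative intensities.
    times
        Seconds from contrast injection for each frame, strictly increasing.
    spacing
        Voxel spacing ``(dz, dy, dx)`` in millimetres.
    """

    data: np.ndarray
    times: np.ndarray
    spacing: tuple[float, float, float] = (3.0, 1.25, 1.25)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"series data must be 4D (t,z,y,x), got {self.data.ndim}D")
        if self.data.shape[0] != len(self.times):
            raise ValueError("len(times) must equal the number of frames T")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def T(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial shape ``(D, H, W)``."""
        return self.data.shape[1:]


@dataclass
class KidneyMask:
    """Binary whole-kidney mask over a 3D grid ``(z, y, x)``."""

    data: np.ndarray
    side: str = "both"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D (z,y,x)")
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("mask values must be 0/1")
        if self.side not in ("left", "right", "both"):
            raise ValueError(f"unknown side {self.side!r}")
        self.data = self.data.astype(np.uint8)

    def is_empty(self) -> bool:
        return not bool(self.data.any())


@dataclass
class CompartmentLabels:
    """3D label volume: 0=background, 1=medulla, 2=cortex."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("labels must be 3D (z,y,x)")
        if not np.isin(self.data, (0, 1, 2)).all():
            raise ValueError("labels must take values in {0,1,2}")
        self.data = self.data.astype(np.uint8)


@dataclass
class BoundingBox3D:
    """Inclusive per-axis voxel index ranges enclosing one kidney.

    ``present=False`` encodes an absent kidney as a degenerate single-voxel
    box, mirroring the testing-stage convention for a missing organ.
    """

    zmin: int
    zmax: int
    ymin: int
    ymax: int
    xmin: int
    xmax: int
    present: bool = True

    def __post_init__(self) -> None:
        for lo, hi in ((self.zmin, self.zmax), (self.ymin, self.ymax), (self.xmin, self.xmax)):
            if lo > hi:
                raise ValueError("box min must not exceed max on any axis")
        if not self.present and self.extent != (1, 1, 1):
            raise ValueError("an absent kidney must be a single-voxel box")

    @property
    def extent(self) -> tuple[int, int, int]:
        return (
            self.zmax - self.zmin + 1,
            self.ymax - self.ymin + 1,
            self.xmax - self.xmin + 1,
        )

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return (
            slice(self.zmin, self.zmax + 1),
            slice(self.ymin, self.ymax + 1),
            slice(self.xmin, self.xmax + 1),
        )

    @classmethod
    def absent(cls) -> "BoundingBox3D":
        return cls(0, 0, 0, 0, 0, 0, present=False)


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    dz, dy, dx = spacing
    return np.diag([dx, dy, dz, 1.0])


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_dce(path: str | Path, default_frame_interval: float = 3.3) -> DceSeries:
    """Read a 4D NIfTI series into canonical ``(t, z, y, x)`` order.

    ``path`` may also be a directory of per-timepoint 3D NIfTI files
    (sorted by name) with an optional ``times.json`` sidecar listing the
    acquisition times.  Times default to uniform sampling at
    ``default_frame_interval`` seconds when no sidecar is present.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dce_dir(path, default_frame_interval)
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 4:
        raise ValueError(f"{path} is {arr.ndim}D; a 4D series (x,y,z,t) is required")
    data = np.ascontiguousarray(arr.transpose(3, 2, 1, 0)).astype(np.float32)
    zooms = img.header.get_zooms()
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    times = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "times" in meta:
            times = np.asarray(meta["times"], dtype=float)
        if "spacing" in meta:
            spacing = tuple(float(v) for v in meta["spacing"])
    if times is None:
        times = np.arange(data.shape[0], dtype=float) * default_frame_interval
    return DceSeries(data=data, times=times, spacing=spacing)


def _read_dce_dir(path: Path, default_frame_interval: float) -> DceSeries:
    frames = sorted(p for p in path.iterdir() if p.name.endswith((".nii", ".nii.gz")))
    if not frames:
        raise ValueError(f"no NIfTI frames found in directory {path}")
    volumes, spacing = zip(*(_read_volume3d(p) for p in frames))
    shapes = {v.shape for v in volumes}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame shapes in {path}: {sorted(shapes)}")
    times = None
    sidecar = path / "times.json"
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        times = np.asarray(meta["times"] if isinstance(meta, dict) else meta, dtype=float)
    if times is None:
        times = np.arange(len(frames), dtype=float) * default_frame_interval
    return DceSeries(
        data=np.stack(volumes).astype(np.float32), times=times, spacing=spacing[0]
    )


def write_dce(series: DceSeries, path: str | Path) -> None:
    """Write a series as 4D NIfTI ``(x, y, z, t)`` plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = series.data.transpose(3, 2, 1, 0)
    img = nib.Nifti1Image(arr, _affine(series.spacing))
    img.header.set_zooms((series.spacing[2], series.spacing[1], series.spacing[0], 1.0))
    nib.save(img, str(path))
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        json.dumps({"times": series.times.tolist(), "spacing": list(series.spacing)})
    )


def _read_volume3d(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 3:
        raise ValueError(f"{path} is {arr.ndim}D; a 3D volume is required")
    zooms = img.header.get_zooms()
    return arr.transpose(2, 1, 0), (float(zooms[2]), float(zooms[1]), float(zooms[0]))


def _write_volume3d(
    data: np.ndarray, path: str | Path, spacing: tuple[float, float, float]
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(data.transpose(2, 1, 0).astype(np.uint8), _affine(spacing))
    nib.save(img, str(path))


def read_mask(path: str | Path, side: str = "both") -> KidneyMask:
    data, _ = _read_volume3d(path)
    return KidneyMask(data=(data > 0).astype(np.uint8), side=side)


def write_mask(
    mask: KidneyMask, path: str | Path, spacing: tuple[float, float, float] = (3.0, 1.25, 1.25)
) -> None:
    _write_volume3d(mask.data, path, spacing)


def read_labels(path: str | Path) -> CompartmentLabels:
    data, _ = _read_volume3d(path)
    return CompartmentLabels(data=np.rint(data).astype(np.uint8))


def write_labels(
    labels: CompartmentLabels,
    path: str | Path,
    spacing: tuple[float, float, float] = (3.0, 1.25, 1.25),
) -> None:
    _write_volume3d(labels.data, path, spacing)


# ---------------------------------------------------------------------------
# Bounding boxes, crop and paste


def compute_bounding_box(mask: KidneyMask | np.ndarray) -> BoundingBox3D:
    """Tightest inclusive box around foreground; absent convention when empty."""
    data = mask.data if isinstance(mask, KidneyMask) else np.asarray(mask)
    fg = np.argwhere(data > 0)
    if fg.size == 0:
        return BoundingBox3D.absent()
    mins = fg.min(axis=0)
    maxs = fg.max(axis=0)
    return BoundingBox3D(
        int(mins[0]), int(maxs[0]), int(mins[1]), int(maxs[1]), int(mins[2]), int(maxs[2])
    )


def _clamped_box(box: BoundingBox3D, shape: tuple[int, int, int], pad: int) -> BoundingBox3D:
    D, H, W = shape
    return BoundingBox3D(
        max(0, box.zmin - pad),
        min(D - 1, box.zmax + pad),
        max(0, box.ymin - pad),
        min(H - 1, box.ymax + pad),
        max(0, box.xmin - pad),
        min(W - 1, box.xmax + pad),
    )


def crop(
    series: DceSeries, box: BoundingBox3D, pad: int = 0
) -> tuple[DceSeries, BoundingBox3D]:
    """Spatial sub-series over the (padded, clamped) box; time axis untouched.

    Returns the cropped series together with the effective box actually used,
    so the caller can paste results back at the original coordinates.

    Raises
    ------
    ValueError
        If the box encodes an absent kidney.
    """
    if not box.present:
        raise ValueError("kidney absent: cannot crop a present=False box")
    used = _clamped_box(box, series.shape, pad)
    sub = series.data[(slice(None),) + used.slices]
    return (
        DceSeries(data=sub.copy(), times=series.times.copy(), spacing=series.spacing),
        used,
    )


def paste_into(
    labels: CompartmentLabels | KidneyMask | np.ndarray,
    box: BoundingBox3D,
    canvas_shape: tuple[int, int, int],
    canvas: np.ndarray | None = None,
):
    """Place a label/mask volume at the box offset on a zero canvas.

    The volume's shape must equal the box extent.  When ``canvas`` is given
    the labels are written into it in place (useful for assembling the two
    kidneys into one volume); otherwise a fresh zero canvas is allocated.
    Returns the same wrapper type as the input.
    """
    data = labels.data if isinstance(labels, (CompartmentLabels, KidneyMask)) else np.asarray(labels)
    if tuple(data.shape) != box.extent:
        raise ValueError(f"labels shape {data.shape} does not match box extent {box.extent}")
    if canvas is None:
        canvas = np.zeros(canvas_shape, dtype=data.dtype)
    elif tuple(canvas.shape) != tuple(canvas_shape):
        raise ValueError("canvas shape mismatch")
    region = canvas[box.slices]
    np.copyto(region, np.where(data > 0, data, region))
    if isinstance(labels, CompartmentLabels):
        return CompartmentLabels(data=canvas)
    if isinstance(labels, KidneyMask):
        return KidneyMask(data=canvas, side=labels.side)
    return canvas
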