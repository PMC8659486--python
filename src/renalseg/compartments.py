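"""Rule-based medulla/cortex segmentation by contrast maximisation.

Given a 4D series and a whole-kidney mask, every coronal slice of every
frame is pushed through a contrast cascade — an intensity shift for central
slices, gamma correction for peripheral slices, a sigmoidal contrast
enhancement — and then binarised with Otsu's method: dark pixels inside the
kidney become medulla candidates, bright pixels cortex candidates.  The
per-frame label volumes are finally fused around a reference frame chosen in
the early-to-mid acquisition (where cortico-medullary contrast peaks), with
a cortex refinement pass that restores thin cortical rims and demotes
implausible medulla.

All slices are processed masked: the cascade and the Otsu histogram consider
only non-zero (intra-kidney) pixels, so the threshold separates medulla from
cortex rather than kidney from background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.morphology import closing, dilation, disk, erosion

from .volumes import (
    LABEL_CORTEX,
    LABEL_MEDULLA,
    CompartmentLabels,
    DceSeries,
    KidneyMask,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CompartmentParams",
    "SliceMarkers",
    "LabelSeries",
    "depth_ranges",
    "compute_markers",
    "shift_intensities",
    "gamma_correct",
    "contrast_sigmoid",
    "sigmoid_enhance",
    "otsu_threshold",
    "otsu_binarise",
    "label_slice",
    "process2",
    "medulla_fraction",
    "process3",
    "segment_compartments",
]


@dataclass
class CompartmentParams:
    """Tunable thresholding and fusion parameters.

    ``delta``/``mu`` drive the sigmoidal enhancement, ``gamma`` the
    peripheral-slice gamma correction, ``r_f``/``r_l`` delimit the central
    slice range as fractions of the depth, ``alpha``/``beta`` bound the
    plausible medulla percentage of a slice, and ``x`` locates the reference
    frame as a fraction of the acquisition.
    """

    delta: float = 2.0
    mu: float = 1.5
    gamma: float = 1.5
    r_f: float = 0.3
    r_l: float = 0.7
    alpha: float = 30.0
    beta: float = 60.0
    x: float = 0.375
    closing_radius: int = 2
    rim_radius: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.r_f < self.r_l < 1:
            raise ValueError("need 0 < r_f < r_l < 1")
        if not 0 <= self.alpha < self.beta <= 100:
            raise ValueError("need 0 <= alpha < beta <= 100")
        if not 0.25 <= self.x <= 0.50:
            raise ValueError("reference-time fraction x must lie in [0.25, 0.50]")


@dataclass
class SliceMarkers:
    """Numerical guides of one slice: its sorted unique non-zero intensities
    with their extremes, and (for labelled slices) area and medulla counts."""

    a_d: np.ndarray
    a_min: float
    a_max: float
    area_d: int = 0
    med_d: int = 0

    @property
    def rMA(self) -> float | None:
        """Medulla percentage of total kidney area; None when undefined."""
        if self.area_d == 0:
            return None
        return 100.0 * self.med_d / self.area_d


@dataclass
class LabelSeries:
    """Per-frame compartment label volumes L_1..L_T (one per time point)."""

    volumes: list[CompartmentLabels]

    def __post_init__(self) -> None:
        if not self.volumes:
            raise ValueError("label series must not be empty")
        shapes = {v.data.shape for v in self.volumes}
        if len(shapes) != 1:
            raise ValueError("all label volumes must share one shape")

    def __len__(self) -> int:
        return len(self.volumes)

    def __getitem__(self, t: int) -> CompartmentLabels:
        return self.volumes[t]


def depth_ranges(r_f: float, r_l: float, D: int) -> tuple[int, int]:
    """Central slice range [p_f, p_l] (0-based, inclusive) from the depth
    fractions: ``p_f = floor(r_f * D)`` and ``p_l = round(r_l * D) - 1``
    (the nearest 1-based slice to ``r_l * D``, converted to 0-based), both
    clamped into the volume."""
    if not 0 < r_f < r_l < 1:
        raise ValueError("need 0 < r_f < r_l < 1")
    if D < 1:
        raise ValueError("depth must be at least 1")
    p_f = max(0, int(np.floor(r_f * D)))
    p_l = min(D - 1, int(np.floor(r_l * D + 0.5)) - 1)
    p_l = max(p_l, p_f)
    return p_f, p_l


def compute_markers(slice_: np.ndarray) -> SliceMarkers:
    nz = slice_[slice_ > 0]
    if nz.size == 0:
        return SliceMarkers(a_d=np.array([]), a_min=0.0, a_max=0.0)
    a_d = np.unique(nz)
    return SliceMarkers(a_d=a_d, a_min=float(a_d[0]), a_max=float(a_d[-1]))


def shift_intensities(slice_: np.ndarray, markers: SliceMarkers | None = None) -> np.ndarray:
    """Shift strictly interior intensities down by the slice minimum.

    Pixels with ``a_min < s < a_max`` become ``s - a_min``; the extremes and
    zeros are untouched.  Applied to central slices only (caller enforced).
    """
    s = np.asarray(slice_, np.float32).copy()
    m = markers or compute_markers(s)
    if m.a_d.size < 3:  # fewer than 3 distinct values: no strict interior
        return s
    interior = (s > m.a_min) & (s < m.a_max)
    s[interior] -= m.a_min
    return s


def gamma_correct(slice_: np.ndarray, gamma: float) -> np.ndarray:
    """Power-law transform ``(s / 255)^gamma * 255`` on non-zero pixels.

    With gamma > 1 this darkens bright regions; 0 and 255 are fixed points
    and gamma = 1 is the identity.  Applied to peripheral slices only.
    """
    s = np.asarray(slice_, np.float32)
    if np.any(s < 0):
        raise ValueError("gamma correction requires non-negative intensities")
    out = s.copy()
    nz = s > 0
    # ratio first: (s/255)^gamma stays in [0, 1] even for large gamma
    out[nz] = ((s[nz].astype(np.float64) / 255.0) ** gamma * 255.0).astype(np.float32)
    return out


def contrast_sigmoid(s: np.ndarray | float, delta: float, mu: float) -> np.ndarray:
    """The raw sigmoidal enhancement ``E(s) = 1 / (1 + exp(delta (mu - s)))``
    on normalised intensities; strictly increasing in ``s`` for delta > 0."""
    s = np.asarray(s, dtype=np.float64)
    return 1.0 / (1.0 + np.exp(delta * (mu - s)))


def sigmoid_enhance(slice_: np.ndarray, delta: float, mu: float) -> np.ndarray:
    """Sigmoidal contrast enhancement of a [0, 255] slice.

    Non-zero pixels are rescaled to [0, 1], passed through
    :func:`contrast_sigmoid` and mapped back to the [1, 255] intensity range;
    zeros (background) are preserved and tissue keeps a strictly positive
    value so the background sentinel never swallows the darkest compartment.
    The map is strictly monotone, so it changes the Otsu threshold but never
    the intensity ordering.
    """
    s = np.asarray(slice_, np.float32)
    out = s.copy()
    nz = s > 0
    if not nz.any():
        return out
    lo, hi = float(s[nz].min()), float(s[nz].max())
    unit = (s[nz] - lo) / (hi - lo) if hi > lo else np.zeros(int(nz.sum()))
    e = contrast_sigmoid(unit, delta, mu)
    e_lo, e_hi = contrast_sigmoid(0.0, delta, mu), contrast_sigmoid(1.0, delta, mu)
    out[nz] = 1.0 + (e - e_lo) / (e_hi - e_lo) * 254.0 if e_hi > e_lo else 1.0
    return out.astype(np.float32)


def otsu_threshold(values: np.ndarray) -> float | None:
    """Threshold maximising between-class variance over the given sample.

    Candidates are the unique values; class split is ``<= tau`` versus
    ``> tau``; ties resolve to the lowest maximising threshold.  Returns
    None when fewer than two distinct values exist.
    """
    vals = np.sort(np.asarray(values, np.float64).ravel())
    uniq, counts = np.unique(vals, return_counts=True)
    if uniq.size < 2:
        return None
    n = vals.size
    w0 = np.cumsum(counts)[:-1]  # pixels <= candidate, per candidate
    w1 = n - w0
    csum = np.cumsum(uniq * counts)[:-1]
    mu0 = csum / w0
    mu1 = (vals.sum() - csum) / w1
    sigma_b = (w0 / n) * (w1 / n) * (mu0 - mu1) ** 2
    return float(uniq[:-1][int(np.argmax(sigma_b))])


def otsu_binarise(slice_: np.ndarray) -> tuple[np.ndarray, float | None]:
    """Binarise the non-zero region of a slice at the Otsu threshold.

    Returns ``(o_d, tau)`` where dark pixels (``<= tau``) are 0 (medulla
    candidates) and bright pixels 1 (cortex candidates).  A constant region
    yields an all-zero slice and ``tau=None`` with a warning.
    """
    s = np.asarray(slice_, np.float32)
    nz = s > 0
    tau = otsu_threshold(s[nz]) if nz.any() else None
    o = np.zeros(s.shape, np.uint8)
    if tau is None:
        if nz.any():
            logger.warning("constant slice: Otsu undefined, returning all-zero binarisation")
        return o, None
    o[nz & (s > tau)] = 1
    return o, tau


def fully_close(binary: np.ndarray, radius: int = 2) -> np.ndarray:
    """"Fully close" a binary slice: morphological closing (disk of
    ``radius``) to bridge small gaps, then hole filling.  This is the
    closure the labelling and fusion rules reason against."""
    b = np.asarray(binary) > 0
    if radius > 0:
        b = closing(b, disk(radius))
    return binary_fill_holes(b)


def label_slice(
    o_d: np.ndarray, b_d: np.ndarray, closing_radius: int = 2
) -> np.ndarray:
    """Turn a binarised slice into medulla/cortex labels within the kidney.

    The kidney mask slice is fully closed (gap-bridged and hole-filled);
    candidates outside the closure are discarded as false positives.  Inside
    the kidney, dark (``o=0``) pixels become medulla and bright pixels
    cortex; bright pixels in the closure's filled-in region also count as
    cortex.
    """
    o = np.asarray(o_d)
    b = np.asarray(b_d) > 0
    if o.shape != b.shape:
        raise ValueError("binarised slice and mask slice shapes differ")
    b_close = fully_close(b, closing_radius)
    o = np.where(b_close, o, 0)
    out = np.zeros(o.shape, np.uint8)
    out[b & (o == 0)] = LABEL_MEDULLA
    out[b_close & (o == 1)] = LABEL_CORTEX
    return out


def process2(
    series: DceSeries, mask: KidneyMask, params: CompartmentParams | None = None
) -> LabelSeries:
    """Per-frame medulla/cortex labelling of every slice of every volume.

    Central slices (``p_f <= d <= p_l``) get the intensity shift, peripheral
    slices the gamma correction; all slices are sigmoid-enhanced, Otsu
    binarised and labelled against the kidney mask.
    """
    params = params or CompartmentParams()
    if mask.is_empty():
        raise ValueError("kidney absent: empty whole-kidney mask")
    D = series.shape[0]
    p_f, p_l = depth_ranges(params.r_f, params.r_l, D)
    volumes = []
    mdata = mask.data
    for t in range(series.T):
        lab = np.zeros(series.shape, np.uint8)
        for d in range(D):
            b_d = mdata[d]
            if not b_d.any():
                continue
            s = series.data[t, d] * b_d  # mask the slice: background to zero
            if p_f <= d <= p_l:
                s = shift_intensities(s)
            else:
                s = gamma_correct(np.clip(s, 0, 255), params.gamma)
            s = sigmoid_enhance(s, params.delta, params.mu)
            o_d, _ = otsu_binarise(s)
            lab[d] = label_slice(o_d, b_d, params.closing_radius)
        volumes.append(CompartmentLabels(data=lab))
    return LabelSeries(volumes=volumes)


def medulla_fraction(l_d: np.ndarray) -> SliceMarkers:
    """Area markers of a labelled slice, including the medulla percentage."""
    l = np.asarray(l_d)
    markers = compute_markers(l.astype(np.float32))
    markers.area_d = int((l > 0).sum())
    markers.med_d = int((l == LABEL_MEDULLA).sum())
    return markers


def process3(
    L: LabelSeries,
    series: DceSeries,
    mask: KidneyMask,
    params: CompartmentParams | None = None,
) -> CompartmentLabels:
    """Fuse the per-frame labellings into the "optimum" compartment volume.

    The reference volume is the labelling at ``t_x = round(x * T)``.  For
    central slices, cortex pixels of the reference are demoted to medulla
    wherever some frame calls them medulla and that frame's slice has a
    plausible medulla percentage (``alpha < rMA < beta``).  Cortex is then
    refined: medulla claimed outside the closed reference cortex region is
    returned to cortex, and the rim of the whole-kidney mask (dilation minus
    erosion) is labelled cortex.  Labels never leave the closed kidney mask.
    """
    params = params or CompartmentParams()
    T = len(L)
    D = L[0].data.shape[0]
    p_f, p_l = depth_ranges(params.r_f, params.r_l, D)
    t_x = min(max(int(round(params.x * T)), 0), T - 1)
    k = L[t_x].data.copy()

    for t in range(T):
        l_vol = L[t].data
        for d in range(p_f, p_l + 1):
            l_d = l_vol[d]
            m = medulla_fraction(l_d)
            if m.rMA is None:
                continue
            if params.alpha < m.rMA < params.beta:
                k[d][(l_d == LABEL_MEDULLA) & (k[d] == LABEL_CORTEX)] = LABEL_MEDULLA

    rim_selem = disk(params.rim_radius)
    for d in range(D):
        Y = mask.data[d] > 0
        if not Y.any():
            continue
        # fully closed cortex-candidate region at the reference frame: the
        # filled cortex contour.  Medulla claimed outside it (degenerate
        # slices, collecting-system edges) reverts to cortex.
        theta = fully_close(L[t_x].data[d] == LABEL_CORTEX, params.closing_radius)
        k_d = k[d]
        k_d[Y & ~theta & (k_d == LABEL_MEDULLA)] = LABEL_CORTEX
        rim = dilation(Y, rim_selem) & ~erosion(Y, rim_selem)
        k_d[rim] = LABEL_CORTEX
        # containment: labels stay within the fully closed kidney mask
        k_d[~fully_close(Y, params.closing_radius)] = 0
    return CompartmentLabels(data=k)


def segment_compartments(
    series: DceSeries,
    masks: list[KidneyMask],
    params: CompartmentParams | None = None,
) -> CompartmentLabels:
    """Run Processes 2-3 independently per kidney and merge by union.

    Masks must be spatially disjoint (left/right kidneys), so labels cannot
    collide.  Empty masks are skipped (absent kidney).
    """
    params = params or CompartmentParams()
    out = np.zeros(series.shape, np.uint8)
    for mask in masks:
        if mask.is_empty():
            logger.info("skipping absent kidney (side=%s)", mask.side)
            continue
        L = process2(series, mask, params)
        vol = process3(L, series, mask, params)
        out = np.where(vol.data > 0, vol.data, out)
    return CompartmentLabels(data=out)
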