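"""Small shared helpers: unit conversion, morphology by radius, seeded RNG plumbing."""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import ndimage as ndi

log = logging.getLogger("nervequant")


def um2_to_px(area_um2: float, pixel_size_um: float) -> float:
    """Convert an area in µm² to pixels at the given lateral pixel size."""
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    return float(area_um2) / (pixel_size_um * pixel_size_um)


def px_to_um2(area_px: float, pixel_size_um: float) -> float:
    return float(area_px) * pixel_size_um * pixel_size_um


def dilate_radius(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Binary dilation by a Euclidean disk of the given radius (exact, via EDT of the complement)."""
    mask = np.asarray(mask, bool)
    if radius_px <= 0 or not mask.any():
        return mask.copy()
    return ndi.distance_transform_edt(~mask) <= radius_px


def erode_radius(mask: np.ndarray, radius_px: float) -> np.ndarray:
    mask = np.asarray(mask, bool)
    if radius_px <= 0:
        return mask.copy()
    return ndi.distance_transform_edt(mask) > radius_px


def disk_selem(radius: int) -> np.ndarray:
    """Disk-shaped structuring element (matches skimage.morphology.disk)."""
    r = int(radius)
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    return (x * x + y * y) <= r * r


def wrap_axial_deg(angle: float | np.ndarray) -> float | np.ndarray:
    """Wrap an orientation angle (axial, period 180°) into (-90, 90]."""
    a = -((-np.asarray(angle, float) + 90.0) % 180.0) + 90.0
    # maps -90 -> +90, keeps (-90, 90] otherwise
    return a if isinstance(angle, np.ndarray) else float(a)


def rng_from(seed) -> np.random.Generator:
    """Single entry point for randomness: everything derives from one integer seed."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from a master seed."""
    ss = np.random.SeedSequence(int(seed))
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n, dtype=np.uint64)]


def filter_small_objects(mask: np.ndarray, min_area_px: float) -> np.ndarray:
    """Remove connected components with area strictly below min_area_px (area opening)."""
    mask = np.asarray(mask, bool)
    lbl, n = ndi.label(mask)
    if n == 0:
        return mask.copy()
    sizes = np.bincount(lbl.ravel())
    keep = sizes >= min_area_px
    keep[0] = False
    return keep[lbl]


def safe_otsu(img: np.ndarray) -> float | None:
    """Otsu threshold, or None when the image is constant (no histogram split exists)."""
    img = np.asarray(img)
    if img.size == 0 or float(img.max()) == float(img.min()):
        return None
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(img))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Sørensen–Dice coefficient 2|A∩B|/(|A|+|B|) of two binary masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    s = int(a.sum()) + int(b.sum())
    if s == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / s


def iou(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    u = int((a | b).sum())
    if u == 0:
        return 1.0
    return int((a & b).sum()) / u


def circ_mean_axial_deg(samples_deg: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted circular mean of axial angles (period 180°), result in (-90, 90]."""
    th = np.deg2rad(np.asarray(samples_deg, float) * 2.0)
    w = np.ones_like(th) if weights is None else np.asarray(weights, float)
    c = float(np.sum(w * np.cos(th)))
    s = float(np.sum(w * np.sin(th)))
    return wrap_axial_deg(math.degrees(math.atan2(s, c)) / 2.0)


def circ_std_axial_deg(samples_deg: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted circular standard deviation of axial angles, in degrees."""
    th = np.deg2rad(np.asarray(samples_deg, float) * 2.0)
    w = np.ones_like(th) if weights is None else np.asarray(weights, float)
    wsum = float(np.sum(w))
    if wsum <= 0:
        return float("nan")
    c = float(np.sum(w * np.cos(th))) / wsum
    s = float(np.sum(w * np.sin(th))) / wsum
    r = math.hypot(c, s)
    r = min(max(r, 1e-12), 1.0)
    return math.degrees(math.sqrt(-2.0 * math.log(r))) / 2.0
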