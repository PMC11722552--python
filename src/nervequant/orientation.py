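"""Fiber directionality: structure-tensor orientations, abundance histogram, Gaussian peak.

Local orientation is the eigen-direction of the windowed structure tensor of
Gaussian-derivative gradients; the per-pixel angle (axial, (-90, 90], 0° along
the image x-axis), gradient energy and coherence feed a weighted orientation
histogram, to which a single wrapped Gaussian peak (baseline + amplitude) is
fitted by bounded least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import least_squares

from ._util import circ_mean_axial_deg, circ_std_axial_deg, log

__all__ = [
    "OrientationField",
    "OrientationHistogram",
    "GaussianPeak",
    "local_orientations",
    "orientation_histogram",
    "fit_gaussian_peak",
]


@dataclass
class OrientationField:
    angle_deg: np.ndarray  # per-pixel orientation in (-90, 90]
    energy: np.ndarray  # trace of the structure tensor
    coherence: np.ndarray  # (l1 - l2)/(l1 + l2) in [0, 1]


@dataclass
class OrientationHistogram:
    """Normalized directional-abundance histogram on the periodic domain (-90, 90]."""

    centers_deg: np.ndarray
    weights: np.ndarray
    bin_deg: float

    def __post_init__(self):
        total = float(self.weights.sum())
        if total <= 0:
            raise ValueError("histogram weights must have positive total")
        self.weights = np.asarray(self.weights, float) / total


@dataclass
class GaussianPeak:
    center_deg: float
    sigma_deg: float
    amplitude: float
    baseline: float
    r_squared: float
    reliable: bool = True
    message: str = ""


def local_orientations(
    img: np.ndarray, sigma_grad_px: float = 1.0, sigma_window_px: float = 2.0
) -> OrientationField:
    """Per-pixel structure-tensor orientation, energy and coherence.

    Gradients are Gaussian derivatives at ``sigma_grad_px``; the tensor products
    are averaged over a Gaussian window of ``sigma_window_px``. A constant image
    yields zero energy everywhere (flagged by a log message).
    """
    img = np.asarray(img, float)
    gy = ndi.gaussian_filter(img, sigma_grad_px, order=(1, 0))
    gx = ndi.gaussian_filter(img, sigma_grad_px, order=(0, 1))
    jxx = ndi.gaussian_filter(gx * gx, sigma_window_px)
    jyy = ndi.gaussian_filter(gy * gy, sigma_window_px)
    jxy = ndi.gaussian_filter(gx * gy, sigma_window_px)
    energy = jxx + jyy
    if float(energy.max()) == 0.0:
        log.info("constant image: zero gradient energy, orientations undefined")
    # dominant gradient direction, rotated 90° to the structure (tangent) direction
    phi = 0.5 * np.arctan2(2.0 * jxy, jxx - jyy)
    angle = np.degrees(phi) + 90.0
    angle = -((-angle + 90.0) % 180.0) + 90.0  # wrap to (-90, 90]
    lam_diff = np.sqrt((jxx - jyy) ** 2 + 4.0 * jxy**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.where(energy > 0, lam_diff / np.where(energy > 0, energy, 1.0), 0.0)
    return OrientationField(angle_deg=angle, energy=energy, coherence=np.clip(coherence, 0, 1))


def orientation_histogram(
    angles_deg: np.ndarray,
    weights: np.ndarray | None = None,
    bin_deg: float = 1.0,
) -> OrientationHistogram:
    """Weighted, normalized orientation histogram on (-90, 90].

    ``weights`` default to 1 per sample; the caller typically passes
    energy * coherence from :func:`local_orientations`. All-zero weights raise.
    """
    angles = np.asarray(angles_deg, float).ravel()
    w = np.ones_like(angles) if weights is None else np.asarray(weights, float).ravel()
    if angles.shape != w.shape:
        raise ValueError("angles and weights must have the same size")
    if float(w.sum()) <= 0:
        raise ValueError("all-zero weights: no orientation signal to histogram")
    edges = np.arange(-90.0, 90.0 + bin_deg / 2, bin_deg)
    # map angles into (-90, 90] then bin (left-open via nextafter on the -90 edge)
    a = -((-angles + 90.0) % 180.0) + 90.0
    hist, _ = np.histogram(a, bins=edges, weights=w)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return OrientationHistogram(centers_deg=centers, weights=hist, bin_deg=float(bin_deg))


def _wrap_delta(theta: np.ndarray, center: float) -> np.ndarray:
    """Signed axial angular difference theta - center wrapped into (-90, 90]."""
    return ((theta - center + 90.0) % 180.0) - 90.0


def fit_gaussian_peak(hist: OrientationHistogram) -> GaussianPeak:
    """Least-squares fit of baseline + amplitude * exp(-d²/(2σ²)) with periodic d.

    Initial guesses: center at the argmax bin, sigma from the circular standard
    deviation, baseline at the minimum bin. Sigma is kept within
    [bin width, 90°]. A flat histogram yields amplitude ~ 0 and is flagged
    unreliable; optimizer failure raises, carrying the best iterate in the message.
    """
    x = hist.centers_deg
    y = hist.weights
    bin_w = hist.bin_deg
    baseline0 = float(y.min())
    amp0 = float(y.max() - y.min())
    center0 = float(x[int(np.argmax(y))])
    sigma0 = float(np.clip(circ_std_axial_deg(x, y), bin_w, 90.0))

    def model(p):
        base, amp, center, sigma = p
        d = _wrap_delta(x, center)
        return base + amp * np.exp(-(d**2) / (2.0 * sigma**2))

    def resid(p):
        return model(p) - y

    p0 = [baseline0, max(amp0, 1e-12), center0, sigma0]
    lb = [0.0, 0.0, -180.0, bin_w]
    ub = [max(float(y.max()), 1e-9), np.inf, 180.0, 90.0]
    try:
        res = least_squares(resid, p0, bounds=(lb, ub), max_nfev=2000)
    except Exception as exc:  # pragma: no cover - scipy failure path
        raise RuntimeError(f"Gaussian peak fit failed at p0={p0}: {exc}") from exc
    base, amp, center, sigma = res.x
    center = -((-center + 90.0) % 180.0) + 90.0
    ss_res = float(np.sum(res.fun**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    resid_sd = float(np.std(y - model(res.x)))
    reliable = res.success and amp > max(3.0 * resid_sd, 0.2 * base, 1e-6)
    msg = "" if reliable else "peak amplitude not distinguishable from baseline noise"
    if not res.success:
        msg = f"optimizer did not converge (status {res.status}); best iterate returned"
        reliable = False
    return GaussianPeak(
        center_deg=float(center),
        sigma_deg=float(sigma),
        amplitude=float(amp),
        baseline=float(base),
        r_squared=r2,
        reliable=bool(reliable),
        message=msg,
    )


def dominant_orientation(
    img: np.ndarray,
    sigma_grad_px: float = 1.0,
    sigma_window_px: float = 2.0,
    bin_deg: float = 1.0,
) -> tuple[OrientationHistogram, GaussianPeak]:
    """Image -> weighted orientation histogram -> fitted Gaussian peak."""
    field = local_orientations(img, sigma_grad_px, sigma_window_px)
    w = field.energy * field.coherence
    hist = orientation_histogram(field.angle_deg, w, bin_deg=bin_deg)
    return hist, fit_gaussian_peak(hist)


def weighted_circular_summary(field: OrientationField) -> tuple[float, float]:
    """Energy-coherence weighted circular mean and std of an orientation field."""
    w = (field.energy * field.coherence).ravel()
    a = field.angle_deg.ravel()
    return circ_mean_axial_deg(a, w), circ_std_axial_deg(a, w)
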