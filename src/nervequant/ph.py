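"""Ratiometric pHluorin2 quantification at mitochondria–lysosome contact sites.

The pipeline: per-channel background estimation, background-corrected
long/short excitation ratio, a buffer-ladder calibration fitted as a quartic
polynomial pH(ratio) with iterative z-score outlier rejection, geometric
detection of contact objects (mitochondrial pixels within a small radius of the
lysosome mask), and per-contact ratio -> pH assignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from ._util import dilate_radius, log, rng_from

__all__ = [
    "RatioMeasurement",
    "MeasurementRejected",
    "CalibrationCurve",
    "CalibrationError",
    "estimate_background",
    "compute_ratio",
    "sample_membrane_rois",
    "build_calibration",
    "estimate_ph",
    "detect_contacts",
    "measure_contact_ph",
]

BUFFER_LADDER_PH = (3.5, 4.0, 4.5, 5.0, 5.5, 6.0, 6.5, 7.0, 7.5, 8.0)


class MeasurementRejected(ValueError):
    """A ratio measurement that cannot be formed; carries a machine-readable reason."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(f"measurement rejected: {reason}")


@dataclass
class RatioMeasurement:
    """Mean intensities of one measurement: long = 475-nm, short = 405-nm excitation."""

    I_m_long: float
    I_b_long: float
    I_m_short: float
    I_b_short: float
    source: str = ""


def estimate_background(img: np.ndarray, cell_mask: np.ndarray, dilate_px: float = 3.0) -> float:
    """Median intensity over pixels outside a 3-px dilation of the cell mask.

    Fields whose cells cover >= 95% of the frame carry no usable background and
    raise, asking for an explicit background ROI instead.
    """
    img = np.asarray(img, float)
    cell_mask = np.asarray(cell_mask, bool)
    if img.shape != cell_mask.shape:
        raise ValueError("image and cell mask must share one shape")
    if cell_mask.mean() >= 0.95:
        raise ValueError(
            "cell mask covers >= 95% of the field; supply an explicit background ROI"
        )
    outside = ~dilate_radius(cell_mask, dilate_px)
    if not outside.any():
        raise ValueError("no background pixels left after dilation; supply a background ROI")
    return float(np.median(img[outside]))


def compute_ratio(meas: RatioMeasurement) -> float:
    """Background-corrected dual-excitation ratio (I_m,long − I_b,long)/(I_m,short − I_b,short)."""
    num = meas.I_m_long - meas.I_b_long
    den = meas.I_m_short - meas.I_b_short
    if num <= 0:
        raise MeasurementRejected("nonpositive_numerator")
    if den <= 0:
        raise MeasurementRejected("nonpositive_denominator")
    return float(num / den)


def sample_membrane_rois(
    mask: np.ndarray,
    pixel_size_um: float,
    n: int,
    roi_um: tuple[float, float] = (2.0, 0.5),
    seed: int = 0,
    max_tries: int = 5000,
) -> list[np.ndarray]:
    """Rectangular ROIs (physical size roi_um) centered on membrane pixels.

    Each ROI is oriented along the local boundary tangent (from the smoothed-mask
    gradient) and returned as an (N, 2) array of (row, col) pixel indices; ROIs
    are pairwise disjoint. If fewer than ``n`` fit, the shorter list is returned
    with a logged warning.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty membrane mask")
    rng = rng_from(seed)
    h, w = mask.shape
    half_l = roi_um[0] / 2.0 / pixel_size_um
    half_w = roi_um[1] / 2.0 / pixel_size_um
    sm = ndi.gaussian_filter(mask.astype(float), 2.0)
    gy = ndi.sobel(sm, axis=0)
    gx = ndi.sobel(sm, axis=1)
    ys, xs = np.nonzero(mask)
    order = rng.permutation(ys.size)
    used = np.zeros(mask.shape, bool)
    rois: list[np.ndarray] = []
    yy, xx = np.mgrid[0:h, 0:w]
    for idx in order[: max_tries]:
        if len(rois) == n:
            break
        cy, cx = float(ys[idx]), float(xs[idx])
        g = np.hypot(gy[int(cy), int(cx)], gx[int(cy), int(cx)])
        if g < 1e-6:
            continue
        ny, nx = gy[int(cy), int(cx)] / g, gx[int(cy), int(cx)] / g
        ty, tx = -nx, ny  # boundary tangent
        u = (xx - cx) * tx + (yy - cy) * ty
        v = (xx - cx) * nx + (yy - cy) * ny
        sel = (np.abs(u) <= half_l) & (np.abs(v) <= half_w)
        if not sel.any():
            continue
        if (sel & used).any():
            continue
        if sel[[0, -1], :].any() or sel[:, [0, -1]].any():
            continue  # keep ROIs fully inside the frame
        used |= sel
        rois.append(np.column_stack(np.nonzero(sel)))
    if len(rois) < n:
        log.warning("only %d of %d requested membrane ROIs could be placed", len(rois), n)
    return rois


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationCurve:
    """Quartic pH-vs-ratio calibration with provenance and fit diagnostics.

    ``coefficients`` are c0..c4 of pH = sum c_i * ratio^i; the curve is valid on
    [ratio_min, ratio_max] spanned by the retained calibration points.
    """

    coefficients: np.ndarray
    ratio_min: float
    ratio_max: float
    retained: list[tuple[float, float]]  # (pH, ratio)
    rejected: list[tuple[float, float]]
    rmse: float
    n_iterations: int
    monotone: bool = True

    def predict(self, ratio: float) -> float:
        return float(np.polynomial.polynomial.polyval(ratio, self.coefficients))

    def summary(self) -> str:
        lines = [
            "Quartic pH(ratio) calibration",
            f"  retained points : {len(self.retained)}",
            f"  rejected points : {len(self.rejected)}",
            f"  valid ratio     : [{self.ratio_min:.4f}, {self.ratio_max:.4f}]",
            f"  RMSE            : {self.rmse:.4f} pH",
            f"  iterations      : {self.n_iterations}",
            f"  monotone in range: {self.monotone}",
            "  coefficients (c0..c4): "
            + ", ".join(f"{c:.6g}" for c in self.coefficients),
        ]
        return "\n".join(lines)

    def to_json(self, path) -> None:
        payload = {
            "coefficients": [float(c) for c in self.coefficients],
            "ratio_min": self.ratio_min,
            "ratio_max": self.ratio_max,
            "retained": [[float(p), float(r)] for p, r in self.retained],
            "rejected": [[float(p), float(r)] for p, r in self.rejected],
            "rmse": self.rmse,
            "n_iterations": self.n_iterations,
            "monotone": self.monotone,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        d = json.loads(Path(path).read_text())
        return cls(
            coefficients=np.asarray(d["coefficients"], float),
            ratio_min=d["ratio_min"],
            ratio_max=d["ratio_max"],
            retained=[tuple(p) for p in d["retained"]],
            rejected=[tuple(p) for p in d["rejected"]],
            rmse=d["rmse"],
            n_iterations=d["n_iterations"],
            monotone=d.get("monotone", True),
        )


def build_calibration(
    points: list[tuple[float, float]], z_cut: float = 2.5, max_iter: int = 10
) -> CalibrationCurve:
    """Fit the quartic pH(ratio) calibration with iterative z-score outlier rejection.

    ``points`` are (buffer pH, measured ratio) pairs — at least 8, spanning at
    least 3 pH units. Each iteration fits the quartic by least squares, computes
    z-scores of the jackknife (leave-one-out) residuals, and drops |z| > z_cut,
    until stable or ``max_iter``. Deleted residuals are used because a corrupted
    *ratio* acts as a leverage point: the quartic bends through it, so ordinary
    residuals stay small while the leave-one-out prediction error explodes.
    Fewer than 6 retained points is an error (under-determined quartic).
    """
    pts = [(float(p), float(r)) for p, r in points]
    if len(pts) < 8:
        raise CalibrationError(f"need at least 8 calibration points, got {len(pts)}")
    phs = np.array([p for p, _ in pts])
    ratios = np.array([r for _, r in pts])
    if phs.max() - phs.min() < 3.0:
        raise CalibrationError("calibration points must span at least 3 pH units")

    keep = np.ones(len(pts), bool)
    n_iter = 0
    coef = None
    polyval = np.polynomial.polynomial.polyval
    polyfit = np.polynomial.polynomial.polyfit
    for n_iter in range(1, max_iter + 1):
        if keep.sum() < 6:
            raise CalibrationError(
                f"only {int(keep.sum())} points retained; quartic under-determined"
            )
        idx = np.where(keep)[0]
        coef = polyfit(ratios[idx], phs[idx], 4)
        if keep.sum() <= 6:
            break
        # jackknife residual of each retained point against the fit without it
        dres = np.empty(idx.size)
        for j, i in enumerate(idx):
            m = idx[idx != i]
            cj = polyfit(ratios[m], phs[m], 4)
            dres[j] = phs[i] - polyval(ratios[i], cj)
        sd = dres.std()
        if sd <= 0:
            break
        z = (dres - dres.mean()) / sd
        drop = np.abs(z) > z_cut
        if not drop.any():
            break
        # never drop below the identifiability floor
        if keep.sum() - drop.sum() < 6:
            order = np.argsort(-np.abs(z))
            allowed = int(keep.sum()) - 6
            drop = np.zeros_like(drop)
            drop[order[:allowed]] = True
            if not drop.any():
                break
        keep[idx[drop]] = False

    resid = phs[keep] - np.polynomial.polynomial.polyval(ratios[keep], coef)
    r_min, r_max = float(ratios[keep].min()), float(ratios[keep].max())
    # monotonicity check of the fitted quartic inside the valid range
    grid = np.linspace(r_min, r_max, 512)
    deriv = np.polynomial.polynomial.polyval(
        grid, np.polynomial.polynomial.polyder(coef)
    )
    monotone = bool((deriv >= 0).all() or (deriv <= 0).all())
    if not monotone:
        log.warning("fitted calibration quartic is not monotone on its valid range")
    return CalibrationCurve(
        coefficients=np.asarray(coef, float),
        ratio_min=r_min,
        ratio_max=r_max,
        retained=[(float(p), float(r)) for p, r in zip(phs[keep], ratios[keep])],
        rejected=[(float(p), float(r)) for p, r in zip(phs[~keep], ratios[~keep])],
        rmse=float(np.sqrt(np.mean(resid**2))),
        n_iterations=n_iter,
        monotone=monotone,
    )


def estimate_ph(ratio: float, curve: CalibrationCurve) -> tuple[float, bool]:
    """pH from a ratio via the calibration polynomial.

    Ratios outside the curve's valid range are clamped to the nearest boundary
    and flagged extrapolated.
    """
    extrapolated = ratio < curve.ratio_min or ratio > curve.ratio_max
    r = float(np.clip(ratio, curve.ratio_min, curve.ratio_max))
    return curve.predict(r), extrapolated


def detect_contacts(
    mito_mask: np.ndarray,
    lyso_mask: np.ndarray,
    contact_radius_px: int = 2,
    min_area_px: int = 4,
) -> np.ndarray:
    """Labeled mitochondria–lysosome contact objects.

    Contacts are connected components of mito_mask ∩ dilate(lyso_mask, radius),
    with components below ``min_area_px`` discarded. The radius is an explicit
    resolution-limited proxy for true membrane apposition.
    """
    mito = np.asarray(mito_mask, bool)
    lyso = np.asarray(lyso_mask, bool)
    if mito.shape != lyso.shape:
        raise ValueError("masks must share one shape")
    region = mito & dilate_radius(lyso, contact_radius_px)
    labels, n = ndi.label(region)
    if n:
        sizes = np.bincount(labels.ravel())
        ok = sizes >= min_area_px
        ok[0] = False
        relabel = np.cumsum(ok).astype(np.int32) * ok
        labels = relabel[labels]
    return labels.astype(np.int32)


def measure_contact_ph(
    contacts: np.ndarray,
    I_long: np.ndarray,
    I_short: np.ndarray,
    backgrounds: tuple[float, float],
    curve: CalibrationCurve,
    pixel_size_um: float = 1.0,
    field_id: str = "field",
) -> pd.DataFrame:
    """Per-contact mean intensities -> ratio -> pH table.

    ``backgrounds`` is (long, short). Contacts whose corrected intensities cannot
    form a ratio are kept with a reason code and missing pH.
    """
    contacts = np.asarray(contacts)
    b_long, b_short = backgrounds
    rows = []
    for lab in range(1, int(contacts.max()) + 1):
        sel = contacts == lab
        area = int(sel.sum())
        if area == 0:
            continue
        meas = RatioMeasurement(
            I_m_long=float(I_long[sel].mean()),
            I_b_long=float(b_long),
            I_m_short=float(I_short[sel].mean()),
            I_b_short=float(b_short),
            source=f"contact {lab}",
        )
        row = {
            "field_id": field_id,
            "object_id": lab,
            "area_px": area,
            "area_um2": area * pixel_size_um**2,
            "ratio": np.nan,
            "ph": np.nan,
            "extrapolated": False,
            "reason": "",
        }
        try:
            ratio = compute_ratio(meas)
            ph, extrap = estimate_ph(ratio, curve)
            row.update(ratio=ratio, ph=ph, extrapolated=extrap)
        except MeasurementRejected as exc:
            row["reason"] = exc.reason
        rows.append(row)
    cols = ["field_id", "object_id", "area_px", "area_um2", "ratio", "ph", "extrapolated", "reason"]
    return pd.DataFrame(rows, columns=cols)
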