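"""Seeded synthetic microscopy scenes with exact ground truth.

Every generator is a pure function of (parameters, seed) and emulates one of the
acquisition types the analysis stages assume: neuron fields (soma + neurites +
organelle puncta + nuclei), 3D puncta volumes with known ellipsoid axes, node-of-
Ranvier crops with controllable length/fragmentation/asymmetry, dual-excitation
ratiometric pairs generated from a ground-truth pH map, and fiber fields with a
wrapped-normal orientation distribution.

Noise model: Poisson shot noise on the expected intensity plus Gaussian read
noise; ``snr`` is the peak expected signal divided by the read-noise sigma, and
``snr=None`` disables noise entirely (expected image returned as float).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from ._util import dilate_radius, erode_radius, rng_from, wrap_axial_deg
from .io import ImageStack

__all__ = [
    "Scene",
    "ProbeModel",
    "DEFAULT_PROBE",
    "forward_ratio_model",
    "make_neuron_scene",
    "make_puncta_volume",
    "make_node_scene",
    "make_ratiometric_scene",
    "make_fiber_field",
]


@dataclass
class Scene:
    """A synthetic acquisition plus its exact ground truth."""

    image: ImageStack
    truth: dict
    seed: int
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ProbeModel:
    """Sigmoidal ratio-vs-pH response of a dual-excitation ratiometric probe.

    R(pH) = R_min + (R_max - R_min) / (1 + 10^(hill * (pKa - pH)))

    The defaults describe a probe whose response spans the pH 3.5-8.0 buffer
    ladder used for calibration: pKa at the ladder midpoint and a shallow
    effective slope (hill 0.45, 10-90% response over ~4.4 pH units), so the
    ratio carries pH information across the whole calibrated range.
    """

    r_min: float = 0.2
    r_max: float = 3.0
    pka: float = 5.75
    hill: float = 0.45

    def __post_init__(self):
        if not (self.r_max > self.r_min > 0):
            raise ValueError("require R_max > R_min > 0")
        if self.hill <= 0:
            raise ValueError("hill must be positive")

    def ratio(self, ph):
        return forward_ratio_model(ph, self)


DEFAULT_PROBE = ProbeModel()


def forward_ratio_model(ph, model: ProbeModel = DEFAULT_PROBE):
    """Expected long/short excitation ratio at the given pH (strictly increasing)."""
    ph = np.asarray(ph, float)
    r = model.r_min + (model.r_max - model.r_min) / (
        1.0 + 10.0 ** (model.hill * (model.pka - ph))
    )
    return float(r) if r.ndim == 0 else r


def apply_noise(expected: np.ndarray, snr: float | None, rng: np.random.Generator) -> np.ndarray:
    """Poisson shot noise + Gaussian read noise with sigma = peak(expected)/snr."""
    expected = np.asarray(expected, float)
    if snr is None:
        return expected.copy()
    if snr <= 0:
        raise ValueError("snr must be positive")
    peak = float(expected.max())
    read_sigma = peak / snr if peak > 0 else 0.0
    noisy = rng.poisson(np.clip(expected, 0, None)).astype(float)
    noisy += rng.normal(0.0, read_sigma, expected.shape)
    return np.clip(noisy, 0.0, None)


# ---------------------------------------------------------------------------
# neuron fields (soma + neurites + puncta + nuclei)
# ---------------------------------------------------------------------------


def _sample_separated_points(
    region: np.ndarray, n: int, min_sep_px: float, rng: np.random.Generator, max_tries: int = 4000
) -> np.ndarray:
    """n points (y, x) inside a binary region, pairwise at least min_sep_px apart."""
    ys, xs = np.nonzero(region)
    if ys.size == 0 and n > 0:
        raise ValueError("region too small to place requested objects")
    pts: list[tuple[int, int]] = []
    for _ in range(max_tries):
        if len(pts) == n:
            break
        i = int(rng.integers(ys.size))
        cand = (int(ys[i]), int(xs[i]))
        if all((cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 >= min_sep_px**2 for p in pts):
            pts.append(cand)
    if len(pts) < n:
        raise ValueError(f"could not place {n} objects with separation {min_sep_px}px")
    return np.array(pts, int)


def _gaussian_spot(canvas: np.ndarray, cy: float, cx: float, sigma: float, amp: float) -> None:
    r = int(math.ceil(4 * sigma))
    y0, y1 = max(0, int(cy) - r), min(canvas.shape[0], int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(canvas.shape[1], int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    canvas[y0:y1, x0:x1] += amp * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2)
    )


def make_neuron_scene(
    n_somas: int = 1,
    soma_radius_um: float = 9.1,
    neurite_width_um: float = 2.1,
    puncta_per_compartment: tuple[int, int] = (12, 5),
    snr: float | None = 12.0,
    seed: int = 0,
    pixel_size_um: float = 0.07,
    shape: tuple[int, int] = (640, 640),
    neurites_per_soma: int = 3,
    spot_sigma_px: float = 2.5,
) -> Scene:
    """A 2D neuron field: bright somas, thin neurites, punctate organelle channel, nuclei.

    Truth carries the cell/soma/neurite masks, the planted puncta positions and
    their per-compartment counts (soma, neurite).
    """
    rng = rng_from(seed)
    radius_px = soma_radius_um / pixel_size_um
    width_px = neurite_width_um / pixel_size_um
    if soma_radius_um <= neurite_width_um:
        raise ValueError("soma_radius_um must exceed neurite_width_um")
    if width_px < 2:
        raise ValueError("neurite width below 2 px is not representable at this pixel size")
    h, w = shape
    if 2 * radius_px + 20 > min(h, w):
        raise ValueError("soma does not fit in the requested field")

    yy, xx = np.mgrid[0:h, 0:w]
    soma_mask = np.zeros(shape, bool)
    centers = []
    margin = int(radius_px) + 10
    for _ in range(n_somas):
        for _try in range(500):
            cy = int(rng.integers(margin, h - margin))
            cx = int(rng.integers(margin, w - margin))
            if all((cy - c[0]) ** 2 + (cx - c[1]) ** 2 >= (2.4 * radius_px) ** 2 for c in centers):
                centers.append((cy, cx))
                break
        else:
            raise ValueError("could not place all somas without overlap")
        soma_mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2

    # neurites: straight processes from each soma center out of the field
    line_canvas = np.zeros(shape, bool)
    for cy, cx in centers:
        angles = rng.uniform(0, 2 * np.pi, neurites_per_soma)
        for ang in angles:
            dy, dx = math.sin(ang), math.cos(ang)
            t_max = 2 * (h + w)
            ts = np.arange(0, t_max, 0.5)
            ys = np.round(cy + ts * dy).astype(int)
            xs = np.round(cx + ts * dx).astype(int)
            ok = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
            line_canvas[ys[ok], xs[ok]] = True
    neurite_tube = dilate_radius(line_canvas, width_px / 2.0)
    cell_mask = soma_mask | neurite_tube
    neurite_mask = cell_mask & ~soma_mask

    # plant puncta well inside each compartment so compartment membership is unambiguous
    n_soma_p, n_neur_p = puncta_per_compartment
    soma_interior = erode_radius(soma_mask, 10)
    neur_interior = erode_radius(neurite_mask, min(8.0, width_px / 2 - 1)) & ~dilate_radius(
        soma_mask, 15
    )
    # 6 sigma separation keeps the saddle between neighboring spots ~2% of peak,
    # so planted puncta stay countable after thresholding
    soma_pts = _sample_separated_points(soma_interior, n_soma_p, 6 * spot_sigma_px, rng)
    neur_pts = _sample_separated_points(neur_interior, n_neur_p, 6 * spot_sigma_px, rng)

    organelle = np.zeros(shape, float)
    for cy, cx in np.vstack([soma_pts, neur_pts]) if (n_soma_p + n_neur_p) else []:
        _gaussian_spot(organelle, cy, cx, spot_sigma_px, 150.0)
    tubulin = ndi.gaussian_filter(cell_mask.astype(float) * 120.0, 1.0)
    nuclei = np.zeros(shape, float)
    for cy, cx in centers:
        _gaussian_spot(nuclei, cy, cx, radius_px / 3.0, 100.0)

    chans = [apply_noise(c, snr, rng) for c in (organelle, tubulin, nuclei)]
    image = ImageStack(
        pixels=np.stack(chans)[:, None],
        pixel_size_um=pixel_size_um,
        channel_names=["organelle", "tubulin", "nuclei"],
    )
    truth = {
        "cell_mask": cell_mask,
        "soma_mask": soma_mask,
        "neurite_mask": neurite_mask,
        "soma_centers": centers,
        "puncta_soma": soma_pts,
        "puncta_neurite": neur_pts,
        "puncta_counts": {"soma": int(n_soma_p), "neurite": int(n_neur_p)},
        "soma_radius_px": radius_px,
        "neurite_width_px": width_px,
    }
    params = dict(
        n_somas=n_somas,
        soma_radius_um=soma_radius_um,
        neurite_width_um=neurite_width_um,
        puncta_per_compartment=tuple(puncta_per_compartment),
        snr=snr,
        pixel_size_um=pixel_size_um,
        shape=tuple(shape),
    )
    return Scene(image=image, truth=truth, seed=seed, params=params)


# ---------------------------------------------------------------------------
# 3D puncta volumes with known ellipsoid axes
# ---------------------------------------------------------------------------


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation matrix (QR of a Gaussian matrix, det +1)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_puncta_volume(
    n_objects: int = 8,
    semi_axes_um: tuple[float, float, float] | list[tuple[float, float, float]] = (0.6, 0.3, 0.3),
    pixel_size_um: float = 0.1,
    z_step_um: float = 0.3,
    snr: float | None = 15.0,
    seed: int = 0,
    rotate: bool = True,
    shape_zyx: tuple[int, int, int] | None = None,
) -> Scene:
    """A 3D stack of non-overlapping ellipsoidal puncta with recorded axes and rotations.

    Truth lists each object's centroid (µm), rotation matrix and semi-axes
    (a >= b >= c, µm); a label volume gives the exact voxelization.
    """
    rng = rng_from(seed)
    axes_list = (
        [tuple(semi_axes_um)] * n_objects
        if np.ndim(semi_axes_um) == 1
        else [tuple(a) for a in semi_axes_um]
    )
    if len(axes_list) != n_objects:
        raise ValueError("semi_axes_um list length must equal n_objects")
    a_max = max(max(a) for a in axes_list)
    spacing = np.array([z_step_um, pixel_size_um, pixel_size_um])
    if shape_zyx is None:
        margin_um = a_max + 2.0 * float(spacing.max())
        footprint = 2.0 * a_max + 0.4
        side_um = 2.0 * margin_um + footprint * max(1.0, math.sqrt(n_objects)) * 1.4
        z_um = 2.0 * margin_um + footprint
        shape_zyx = (
            max(int(math.ceil(z_um / z_step_um)), 8),
            max(int(math.ceil(side_um / pixel_size_um)), 32),
            max(int(math.ceil(side_um / pixel_size_um)), 32),
        )
    nz, ny, nx = shape_zyx
    extent = spacing * np.array([nz, ny, nx])

    centers: list[np.ndarray] = []
    for i in range(n_objects):
        margin = max(axes_list[i]) + 2 * max(spacing)
        placed = False
        for _ in range(400):
            c = rng.uniform(margin, extent - margin)
            if all(
                np.linalg.norm(c - cj) >= max(axes_list[i]) + max(axes_list[j]) + 0.2
                for j, cj in enumerate(centers)
            ):
                centers.append(c)
                placed = True
                break
        if not placed:
            raise ValueError("could not place objects without overlap; reduce n_objects")

    labels = np.zeros(shape_zyx, np.int32)
    objects = []
    zc = (np.arange(nz) + 0.5) * z_step_um
    yc = (np.arange(ny) + 0.5) * pixel_size_um
    xc = (np.arange(nx) + 0.5) * pixel_size_um
    for i, (c, axes) in enumerate(zip(centers, axes_list), start=1):
        rot = _random_rotation(rng) if rotate else np.eye(3)
        a_sorted = tuple(sorted(axes, reverse=True))
        # bounding window in index space
        r_um = max(axes)
        z0, z1 = np.searchsorted(zc, [c[0] - r_um - z_step_um, c[0] + r_um + z_step_um])
        y0, y1 = np.searchsorted(yc, [c[1] - r_um - pixel_size_um, c[1] + r_um + pixel_size_um])
        x0, x1 = np.searchsorted(xc, [c[2] - r_um - pixel_size_um, c[2] + r_um + pixel_size_um])
        zz, yy, xx = np.meshgrid(zc[z0:z1], yc[y0:y1], xc[x0:x1], indexing="ij")
        d = np.stack([zz - c[0], yy - c[1], xx - c[2]], axis=-1)  # physical offsets (z,y,x)
        local = d @ rot  # rotate into the ellipsoid frame
        q = (
            (local[..., 0] / axes[0]) ** 2
            + (local[..., 1] / axes[1]) ** 2
            + (local[..., 2] / axes[2]) ** 2
        )
        sub = labels[z0:z1, y0:y1, x0:x1]
        sub[q <= 1.0] = i
        objects.append(
            {
                "id": i,
                "centroid_um_zyx": tuple(float(v) for v in c),
                "semi_axes_um": tuple(float(v) for v in a_sorted),
                "rotation_zyx": rot,
            }
        )

    expected = ndi.gaussian_filter((labels > 0).astype(float) * 200.0, 0.7)
    img = apply_noise(expected, snr, rng)
    image = ImageStack(
        pixels=img[None],
        pixel_size_um=pixel_size_um,
        z_step_um=z_step_um,
        channel_names=["puncta"],
    )
    truth = {"labels": labels, "objects": objects}
    params = dict(
        n_objects=n_objects,
        semi_axes_um=axes_list,
        pixel_size_um=pixel_size_um,
        z_step_um=z_step_um,
        snr=snr,
        rotate=rotate,
        shape_zyx=tuple(shape_zyx),
    )
    return Scene(image=image, truth=truth, seed=seed, params=params)


# ---------------------------------------------------------------------------
# node-of-Ranvier crops
# ---------------------------------------------------------------------------


def make_node_scene(
    length_um: float = 2.0,
    n_fragments: int = 1,
    asymmetry: float = 0.0,
    angle_deg: float = 0.0,
    snr: float | None = 12.0,
    seed: int = 0,
    pixel_size_um: float = 0.05,
    width_um: float | None = None,
    shape: tuple[int, int] | None = None,
) -> Scene:
    """A single node of Ranvier with controllable length, fragmentation and asymmetry.

    The node profile is a superellipse along the major axis; ``asymmetry`` in [0, 1]
    thins the lower flank by a ramp that grows along the axis, so the mask is exactly
    mirror-symmetric about its major axis at 0 and increasingly wedge-shaped towards 1.
    Fragment gaps never shorten the oriented extent: the outermost fragments end at
    +/- length/2.
    """
    if length_um <= 0:
        raise ValueError("length_um must be positive")
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    if not 0.0 <= asymmetry <= 1.0:
        raise ValueError("asymmetry must lie in [0, 1]")
    rng = rng_from(seed)
    L = length_um / pixel_size_um
    W = (width_um if width_um is not None else length_um / 2.5) / pixel_size_um
    gap = max(3.0, 0.05 * L)
    frag_len = (L - (n_fragments - 1) * gap) / n_fragments
    if frag_len < 3.0:
        raise ValueError("fragments too small to rasterize at this pixel size")
    if shape is None:
        side = int(math.ceil(L * 1.6)) + 24
        shape = (side, side)
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    th = math.radians(angle_deg)
    yy, xx = np.mgrid[0:h, 0:w]
    u = (xx - cx) * math.cos(th) + (yy - cy) * math.sin(th)
    v = -(xx - cx) * math.sin(th) + (yy - cy) * math.cos(th)

    prof = (W / 2.0) * np.clip(1.0 - np.abs(2.0 * u / L) ** 6, 0.0, None) ** 0.5
    ramp = np.clip(u / L + 0.5, 0.0, 1.0)  # 0 at one tip, 1 at the other
    lower = -(1.0 - asymmetry * ramp) * prof
    inside = (v <= prof) & (v >= lower) & (np.abs(u) <= L / 2.0)

    starts = -L / 2.0 + np.arange(n_fragments) * (frag_len + gap)
    in_frag = np.zeros_like(inside)
    for s in starts:
        in_frag |= (u >= s) & (u <= s + frag_len)
    mask = inside & in_frag

    n_cc = ndi.label(mask)[1]
    if n_cc != n_fragments:
        raise ValueError(
            f"requested {n_fragments} fragments but rasterization yields {n_cc}; "
            "increase length_um or reduce n_fragments"
        )

    expected = ndi.gaussian_filter(mask.astype(float) * 180.0, 0.6)
    img = apply_noise(expected, snr, rng)
    image = ImageStack(
        pixels=img[None, None], pixel_size_um=pixel_size_um, channel_names=["nav16"]
    )
    truth = {
        "mask": mask,
        "length_um": length_um,
        "n_fragments": n_fragments,
        "asymmetry": asymmetry,
        "angle_deg": angle_deg,
        "width_um": W * pixel_size_um,
    }
    params = dict(
        length_um=length_um,
        n_fragments=n_fragments,
        asymmetry=asymmetry,
        angle_deg=angle_deg,
        snr=snr,
        pixel_size_um=pixel_size_um,
        shape=tuple(shape),
    )
    return Scene(image=image, truth=truth, seed=seed, params=params)


# ---------------------------------------------------------------------------
# dual-excitation ratiometric scenes
# ---------------------------------------------------------------------------


def make_ratiometric_scene(
    n_contacts: int = 10,
    base_ph: float = 7.0,
    contact_ph: float | list[float] = 7.0,
    model: ProbeModel = DEFAULT_PROBE,
    snr: float | None = None,
    backgrounds: tuple[float, float, float] = (0.0, 0.0, 0.0),
    background_gradient: float = 0.0,
    seed: int = 0,
    pixel_size_um: float = 0.07,
    shape: tuple[int, int] = (320, 320),
    contact_radius_px: int = 2,
    amp_short: float = 500.0,
) -> Scene:
    """Mitochondria + lysosome channels with planted membrane-contact sites and a pH map.

    Per-pixel expected intensities satisfy I_long / I_short = R(truth pH) on the
    mitochondrial mask before background and noise; backgrounds are additive
    per-channel constants (405-ex, 475-ex, lysosome) plus an optional smooth
    gradient of the given amplitude. Truth records each contact's mask and pH.
    """
    rng = rng_from(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]

    # mitochondrial network: a few straight tubes crossing the field
    mito = np.zeros(shape, bool)
    tubes = []
    n_tubes = max(3, int(math.ceil(n_contacts / 4)))
    for _ in range(n_tubes):
        ang = rng.uniform(0, np.pi)
        cy, cx = rng.uniform(0.25 * h, 0.75 * h), rng.uniform(0.25 * w, 0.75 * w)
        d = np.array([math.sin(ang), math.cos(ang)])
        tubes.append((cy, cx, ang))
        ts = np.arange(-max(h, w), max(h, w), 0.5)
        ys = np.round(cy + ts * d[0]).astype(int)
        xs = np.round(cx + ts * d[1]).astype(int)
        ok = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
        line = np.zeros(shape, bool)
        line[ys[ok], xs[ok]] = True
        mito |= dilate_radius(line, 3.0)

    # lysosomes adjacent to mitochondria -> planted contacts
    phs = (
        [float(contact_ph)] * n_contacts
        if np.ndim(contact_ph) == 0
        else [float(p) for p in contact_ph]
    )
    if len(phs) != n_contacts:
        raise ValueError("contact_ph list must have n_contacts entries")
    lyso = np.zeros(shape, bool)
    ph_map = np.full(shape, float(base_ph))
    contact_masks: list[np.ndarray] = []
    placed_centers: list[tuple[float, float]] = []
    mito_edt_in = ndi.distance_transform_edt(mito)
    skeleton_band = mito & (mito_edt_in >= 2.5)  # near tube axis
    ys_ax, xs_ax = np.nonzero(skeleton_band)
    r_lyso = 5.0
    tries = 0
    while len(contact_masks) < n_contacts:
        tries += 1
        if tries > 4000:
            raise ValueError("could not plant the requested number of contacts")
        i = int(rng.integers(ys_ax.size))
        py, px = float(ys_ax[i]), float(xs_ax[i])
        if any((py - c[0]) ** 2 + (px - c[1]) ** 2 < 30.0**2 for c in placed_centers):
            continue
        if not (r_lyso + 6 < py < h - r_lyso - 6 and r_lyso + 6 < px < w - r_lyso - 6):
            continue
        # place the lysosome center one pixel off the mito surface along a random normal
        ang = rng.uniform(0, 2 * np.pi)
        dist_axis = mito_edt_in[int(py), int(px)]
        off = dist_axis + r_lyso - 1.0  # lysosome rim overlaps the tube rim by ~1 px
        ly, lx = py + off * math.sin(ang), px + off * math.cos(ang)
        disk = (yy - ly) ** 2 + (xx - lx) ** 2 <= r_lyso**2
        region = mito & dilate_radius(disk, contact_radius_px)
        lbl, n_cc = ndi.label(region)
        if n_cc != 1 or region.sum() < 8:
            continue
        if any((region & m).any() for m in contact_masks):
            continue
        lyso |= disk
        contact_masks.append(region)
        placed_centers.append((py, px))
        ph_map[region] = phs[len(contact_masks) - 1]

    ratio_map = forward_ratio_model(ph_map, model)
    grad = background_gradient * (xx / max(w - 1, 1))
    i_short = amp_short * mito.astype(float) + backgrounds[0] + grad
    i_long = amp_short * mito.astype(float) * ratio_map + backgrounds[1] + grad
    i_lyso = 300.0 * lyso.astype(float) + backgrounds[2]

    chans = [apply_noise(c, snr, rng) for c in (i_short, i_long, i_lyso)]
    image = ImageStack(
        pixels=np.stack(chans)[:, None],
        pixel_size_um=pixel_size_um,
        channel_names=["ex405", "ex475", "lysosome"],
    )
    contact_labels = np.zeros(shape, np.int32)
    for k, m in enumerate(contact_masks, start=1):
        contact_labels[m] = k
    truth = {
        "mito_mask": mito,
        "lyso_mask": lyso,
        "contact_labels": contact_labels,
        "contact_masks": contact_masks,
        "contact_ph": phs,
        "ph_map": ph_map,
        "backgrounds": tuple(backgrounds),
        "model": model,
    }
    params = dict(
        n_contacts=n_contacts,
        base_ph=base_ph,
        contact_ph=phs,
        snr=snr,
        backgrounds=tuple(backgrounds),
        background_gradient=background_gradient,
        pixel_size_um=pixel_size_um,
        shape=tuple(shape),
        contact_radius_px=contact_radius_px,
    )
    return Scene(image=image, truth=truth, seed=seed, params=params)


# ---------------------------------------------------------------------------
# fiber fields with wrapped-normal orientations
# ---------------------------------------------------------------------------


def make_fiber_field(
    center_deg: float = 0.0,
    sigma_deg: float = 10.0,
    n_fibers: int = 120,
    snr: float | None = 15.0,
    seed: int = 0,
    pixel_size_um: float = 0.1,
    shape: tuple[int, int] = (640, 640),
    fiber_length_px: float = 60.0,
) -> Scene:
    """A field of straight fibers with orientations ~ wrapped normal(center, sigma) on (-90, 90].

    Angles are axial: 0° is the image x-axis, positive towards +y (row) direction.
    Truth records the sampled orientations and their realized circular mean/std.
    """
    if sigma_deg < 0:
        raise ValueError("sigma_deg must be >= 0")
    rng = rng_from(seed)
    h, w = shape
    samples = wrap_axial_deg(rng.normal(center_deg, sigma_deg, n_fibers)) if sigma_deg > 0 else (
        np.full(n_fibers, wrap_axial_deg(center_deg))
    )
    canvas = np.zeros(shape, float)
    half = fiber_length_px / 2.0
    for th_deg in samples:
        th = math.radians(th_deg)
        cy = rng.uniform(10, h - 10)
        cx = rng.uniform(10, w - 10)
        ts = np.arange(-half, half, 0.5)
        ys = cy + ts * math.sin(th)
        xs = cx + ts * math.cos(th)
        ok = (ys >= 0) & (ys < h - 1) & (xs >= 0) & (xs < w - 1)
        ys, xs = ys[ok], xs[ok]
        # bilinear splatting: deposited energy per unit length is angle-independent,
        # so broad orientation distributions are not skewed by rasterization aliasing
        y0 = np.floor(ys).astype(int)
        x0 = np.floor(xs).astype(int)
        fy = ys - y0
        fx = xs - x0
        np.add.at(canvas, (y0, x0), (1 - fy) * (1 - fx))
        np.add.at(canvas, (y0 + 1, x0), fy * (1 - fx))
        np.add.at(canvas, (y0, x0 + 1), (1 - fy) * fx)
        np.add.at(canvas, (y0 + 1, x0 + 1), fy * fx)
    expected = ndi.gaussian_filter(canvas, 1.0)
    if expected.max() > 0:
        expected *= 100.0 / expected.max()
    img = apply_noise(expected, snr, rng)
    image = ImageStack(
        pixels=img[None, None], pixel_size_um=pixel_size_um, channel_names=["fibers"]
    )
    from ._util import circ_mean_axial_deg, circ_std_axial_deg

    truth = {
        "orientations_deg": np.asarray(samples, float),
        "center_deg": float(center_deg),
        "sigma_deg": float(sigma_deg),
        "sample_circ_mean_deg": circ_mean_axial_deg(np.asarray(samples, float)),
        "sample_circ_std_deg": circ_std_axial_deg(np.asarray(samples, float)),
    }
    params = dict(
        center_deg=center_deg,
        sigma_deg=sigma_deg,
        n_fibers=n_fibers,
        snr=snr,
        pixel_size_um=pixel_size_um,
        shape=tuple(shape),
    )
    return Scene(image=image, truth=truth, seed=seed, params=params)
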