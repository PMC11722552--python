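"""Calibrated microscopy image I/O and tidy result tables.

Images are held as :class:`ImageStack` — a (channel, z, y, x) array with physical
calibration in µm. TIFF and OME-TIFF are read and written through tifffile; the
calibration precedence is explicit override > OME metadata > TIFF resolution tags,
and a missing calibration is a hard error, never a silent default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from ._util import log

__all__ = [
    "ImageStack",
    "ResultsTable",
    "CalibrationMissingError",
    "read_image",
    "write_image",
    "write_table",
    "read_table",
]


class CalibrationMissingError(ValueError):
    """Raised when a required physical calibration field is absent."""

    def __init__(self, missing_field: str):
        self.missing_field = missing_field
        super().__init__(
            f"calibration field '{missing_field}' not found in image metadata and no "
            f"override supplied; pass overrides={{'{missing_field}': <µm>}}"
        )


@dataclass
class ImageStack:
    """Multichannel pixel data with physical calibration.

    pixels are indexed (channel, z, y, x); 2D fields have z = 1. Intensities are
    non-negative; pixel_size_um is the lateral sampling (x and y), z_step_um the
    axial step (None for 2D data).
    """

    pixels: np.ndarray
    pixel_size_um: float
    z_step_um: float | None = None
    channel_names: list[str] = field(default_factory=list)
    bit_depth: int | None = None

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim == 2:
            px = px[None, None]
        elif px.ndim == 3:  # (c, y, x)
            px = px[:, None]
        elif px.ndim != 4:
            raise ValueError(f"pixels must be 2D-4D, got shape {px.shape}")
        self.pixels = px
        if not self.pixel_size_um or self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.z_step_um is not None and self.z_step_um <= 0:
            raise ValueError("z_step_um must be positive when given")
        if float(px.min()) < 0:
            raise ValueError("intensities must be non-negative")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(px.shape[0])]
        if len(self.channel_names) != px.shape[0]:
            raise ValueError("channel_names length must equal channel count")
        if self.bit_depth is None and np.issubdtype(px.dtype, np.integer):
            self.bit_depth = int(px.dtype.itemsize * 8)

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_z(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]

    def channel(self, name_or_index: str | int, projection: str | None = "max") -> np.ndarray:
        """One channel as a 2D plane (max projection by default) or the 3D stack (projection=None)."""
        if isinstance(name_or_index, str):
            try:
                idx = self.channel_names.index(name_or_index)
            except ValueError:
                raise KeyError(
                    f"channel '{name_or_index}' not in {self.channel_names}"
                ) from None
        else:
            idx = int(name_or_index)
        vol = self.pixels[idx]
        if projection is None:
            return vol
        if projection == "max":
            return vol.max(axis=0)
        raise ValueError(f"unknown projection '{projection}'")


def _calib_from_ome(tf: tifffile.TiffFile) -> dict:
    out: dict = {}
    if not tf.ome_metadata:
        return out
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tf.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")} if "}" in root.tag else {}
        pix = root.find(".//ome:Pixels" if ns else ".//Pixels", ns)
        if pix is not None:
            if pix.get("PhysicalSizeX"):
                out["pixel_size_um"] = float(pix.get("PhysicalSizeX"))
            if pix.get("PhysicalSizeZ"):
                out["z_step_um"] = float(pix.get("PhysicalSizeZ"))
            if pix.get("DimensionOrder"):
                out["dimension_order"] = pix.get("DimensionOrder")
        chans = root.findall(".//ome:Channel" if ns else ".//Channel", ns)
        names = [c.get("Name") for c in chans if c.get("Name")]
        if names and len(names) == len(chans):
            out["channel_names"] = names
    except Exception as exc:  # malformed OME block: fall through to tags
        log.warning("failed to parse OME metadata: %s", exc)
    return out


def _calib_from_tags(tf: tifffile.TiffFile) -> dict:
    out: dict = {}
    page = tf.pages[0]
    xres = page.tags.get("XResolution")
    unit = page.tags.get("ResolutionUnit")
    if xres is not None:
        num, den = xres.value
        if num:
            px_per_unit = num / den
            unit_um = {2: 25400.0, 3: 10000.0}.get(
                getattr(unit.value, "value", unit.value) if unit else 3, None
            )
            if unit_um and px_per_unit > 0:
                out["pixel_size_um"] = unit_um / px_per_unit
    return out


def _normalize_axes(arr: np.ndarray, axes: str | None) -> np.ndarray:
    """Bring a tifffile array into (c, z, y, x) order."""
    if axes:
        axes = axes.upper().replace("S", "C")
        # drop singleton axes tifffile sometimes reports (e.g. T)
        keep = []
        for i, a in enumerate(axes):
            if a in "CZYX":
                keep.append((a, i))
            elif arr.shape[i] == 1:
                arr = arr.take(0, axis=i)
                axes = axes[:i] + axes[i + 1 :]
                return _normalize_axes(arr, axes)
            else:
                raise ValueError(f"unsupported non-singleton axis '{a}' in TIFF axes '{axes}'")
        order = [i for a in "CZYX" for (aa, i) in keep if aa == a]
        arr = np.transpose(arr, order)
        present = "".join(a for a in "CZYX" if a in axes)
        shape = [arr.shape[present.index(a)] if a in present else 1 for a in "CZYX"]
        return arr.reshape(shape)
    # no axes metadata: use rank heuristics
    if arr.ndim == 2:
        return arr[None, None]
    if arr.ndim == 3:
        # small first dim -> channels, else z
        return arr[:, None] if arr.shape[0] <= 8 else arr[None]
    if arr.ndim == 4:
        return arr
    raise ValueError(f"cannot interpret array of rank {arr.ndim} as an image stack")


def read_image(path, overrides: dict | None = None) -> ImageStack:
    """Read a TIFF/OME-TIFF into an ImageStack with calibration populated.

    overrides (pixel_size_um, z_step_um, channel_names, axes) take precedence over
    OME metadata, which takes precedence over TIFF resolution tags. A 3D stack with
    no calibration and no override raises :class:`CalibrationMissingError`.
    """
    overrides = dict(overrides or {})
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta: dict = {}
        meta.update(_calib_from_tags(tf))
        meta.update(_calib_from_ome(tf))
        axes = overrides.pop("axes", None)
        if axes is None:
            try:
                axes = tf.series[0].axes
            except Exception:
                axes = None
    meta.update({k: v for k, v in overrides.items() if v is not None})
    if "pixel_size_um" not in meta:
        raise CalibrationMissingError("pixel_size_um")
    pixels = _normalize_axes(np.asarray(arr), axes)
    if pixels.shape[1] > 1 and "z_step_um" not in meta:
        raise CalibrationMissingError("z_step_um")
    bit_depth = int(pixels.dtype.itemsize * 8) if np.issubdtype(pixels.dtype, np.integer) else None
    return ImageStack(
        pixels=pixels,
        pixel_size_um=float(meta["pixel_size_um"]),
        z_step_um=float(meta["z_step_um"]) if meta.get("z_step_um") else None,
        channel_names=list(meta.get("channel_names") or []),
        bit_depth=bit_depth,
    )


def write_image(stack: ImageStack, path) -> None:
    """Write an ImageStack as OME-TIFF, embedding calibration and channel names."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "axes": "CZYX",
        "PhysicalSizeX": stack.pixel_size_um,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": stack.pixel_size_um,
        "PhysicalSizeYUnit": "µm",
        "Channel": {"Name": list(stack.channel_names)},
    }
    if stack.z_step_um is not None:
        meta["PhysicalSizeZ"] = stack.z_step_um
        meta["PhysicalSizeZUnit"] = "µm"
    tifffile.imwrite(path, stack.pixels, ome=True, metadata=meta)


SCHEMA_VERSION = "1"


@dataclass
class ResultsTable:
    """Tidy per-object results keyed by (field_id, object_id)."""

    data: pd.DataFrame
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self):
        df = self.data
        for col in ("field_id", "object_id"):
            if col not in df.columns:
                raise ValueError(f"ResultsTable requires a '{col}' column")
        if df.duplicated(subset=["field_id", "object_id"]).any():
            raise ValueError("(field_id, object_id) keys must be unique")
        num = df.select_dtypes(include=[np.number])
        bad = ~(np.isfinite(num) | num.isna())
        if bad.to_numpy().any():
            raise ValueError("numeric cells must be finite or missing (NaN)")

    def __len__(self) -> int:
        return len(self.data)

    def equals(self, other: "ResultsTable", rtol: float = 1e-9) -> bool:
        a, b = self.data, other.data
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for col in a.columns:
            if pd.api.types.is_numeric_dtype(a[col]):
                x, y = a[col].to_numpy(float), b[col].to_numpy(float)
                ok = np.isclose(x, y, rtol=rtol, equal_nan=True)
                if not ok.all():
                    return False
            elif not (a[col].astype(str) == b[col].astype(str)).all():
                return False
        return True


def write_table(table: ResultsTable, path, format: str | None = None) -> None:
    """Write a ResultsTable to CSV or JSON (format inferred from the suffix when omitted)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = format or path.suffix.lstrip(".").lower() or "csv"
    if fmt == "csv":
        table.data.to_csv(path, index=False)
    elif fmt == "json":
        payload = {
            "schema_version": table.schema_version,
            "rows": json.loads(table.data.to_json(orient="records")),
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"unsupported table format '{fmt}'")


def read_table(path, format: str | None = None) -> ResultsTable:
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower() or "csv"
    if fmt == "csv":
        df = pd.read_csv(path)
        version = SCHEMA_VERSION
    elif fmt == "json":
        payload = json.loads(path.read_text())
        df = pd.DataFrame(payload["rows"])
        version = payload.get("schema_version", SCHEMA_VERSION)
    else:
        raise ValueError(f"unsupported table format '{fmt}'")
    return ResultsTable(df, schema_version=version)
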