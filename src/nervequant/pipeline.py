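"""End-to-end runs: wire the stages over input files, emit tidy tables and a manifest.

The manifest records the package version, the seed, a hash of the configuration,
digests of every input file, all stage parameters actually in force (with
pixel/micron pairs side by side) and the output paths, so a run can be
reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._util import log
from .config import RunConfig
from .io import CalibrationMissingError, ImageStack, ResultsTable, read_image, write_table

__all__ = ["RunManifest", "run_pipeline", "summarize_groups"]

STAGE_ORDER = ["segment", "puncta", "nodes", "orientation", "ph"]


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    seed: int
    parameters: dict
    inputs: dict[str, str]  # path -> sha256
    outputs: dict[str, str] = field(default_factory=dict)  # table name -> path
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=str))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _segment_stage(stack: ImageStack, config: RunConfig):
    from .segmentation import segment_field

    chan = config.require_channel("tubulin")
    img = stack.channel(chan)
    seg = config.segmentation
    masks, tmap = segment_field(
        img,
        stack.pixel_size_um,
        saturate_quantile=seg.saturate_quantile,
        min_object_area_um2=seg.min_object_area_um2,
        fill_hole_area_um2=seg.fill_hole_area_um2,
        min_thickness_px=seg.min_thickness_px,
        dilate_radius_px=seg.dilate_radius_px,
        soma_min_area_um2=seg.soma_min_area_um2,
        thickness_mode=seg.thickness_mode,
    )
    return masks, tmap


def _puncta_stage(stack: ImageStack, config: RunConfig, masks, field_id: str) -> pd.DataFrame:
    from .puncta import detect_puncta, puncta_table

    chan = config.require_channel("organelle")
    img = stack.channel(chan)
    p = config.puncta
    labels = detect_puncta(
        img,
        stack.pixel_size_um,
        q=p.saturate_quantile,
        gauss_sigma_px=p.gauss_sigma_px,
        gauss_weight=p.gauss_weight,
        min_size_px=p.min_size_px,
        min_size_um2=p.min_size_um2,
    )
    return puncta_table(labels, stack.pixel_size_um, masks=masks, field_id=field_id)


def _nodes_stage(stack: ImageStack, config: RunConfig, field_id: str) -> pd.DataFrame:
    from .nodes import analyze_node

    chan = config.require_channel("nav16")
    img = stack.channel(chan)
    m = analyze_node(
        img,
        stack.pixel_size_um,
        saturate_quantile=config.nodes.saturate_quantile,
        min_size_px=config.nodes.min_size_px,
    )
    if m is None:
        return pd.DataFrame(
            columns=["field_id", "object_id", "length_um", "fragments", "solidity",
                     "symmetry_dice", "bbox_angle_deg"]
        )
    return pd.DataFrame(
        [
            {
                "field_id": field_id,
                "object_id": m.node_id,
                "length_um": m.length_um,
                "fragments": m.fragments,
                "solidity": m.solidity,
                "symmetry_dice": m.symmetry_dice,
                "bbox_angle_deg": m.bbox.angle_deg,
            }
        ]
    )


def _orientation_stage(stack: ImageStack, config: RunConfig, field_id: str) -> pd.DataFrame:
    from .orientation import dominant_orientation

    chan = config.require_channel("nav16")
    img = stack.channel(chan)
    o = config.orientation
    hist, peak = dominant_orientation(
        img, sigma_grad_px=o.sigma_grad_px, sigma_window_px=o.sigma_window_px, bin_deg=o.bin_deg
    )
    return pd.DataFrame(
        [
            {
                "field_id": field_id,
                "object_id": 1,
                "peak_center_deg": peak.center_deg,
                "peak_sigma_deg": peak.sigma_deg,
                "peak_amplitude": peak.amplitude,
                "baseline": peak.baseline,
                "r_squared": peak.r_squared,
                "reliable": peak.reliable,
            }
        ]
    )


def _ph_stage(stack: ImageStack, config: RunConfig, curve, field_id: str) -> pd.DataFrame:
    from .ph import detect_contacts, estimate_background, measure_contact_ph
    from .puncta import detect_puncta

    short_c = config.require_channel("ex405")
    long_c = config.require_channel("ex475")
    lyso_c = config.require_channel("lysosome")
    i_short = stack.channel(short_c)
    i_long = stack.channel(long_c)
    i_lyso = stack.channel(lyso_c)
    p = config.ph
    mito_labels = detect_puncta(i_short, stack.pixel_size_um, min_size_px=4)
    lyso_labels = detect_puncta(i_lyso, stack.pixel_size_um, min_size_px=4)
    mito_mask = mito_labels > 0
    lyso_mask = lyso_labels > 0
    b_long = estimate_background(i_long, mito_mask | lyso_mask, p.background_dilate_px)
    b_short = estimate_background(i_short, mito_mask | lyso_mask, p.background_dilate_px)
    contacts = detect_contacts(
        mito_mask, lyso_mask, contact_radius_px=p.contact_radius_px,
        min_area_px=p.contact_min_area_px,
    )
    return measure_contact_ph(
        contacts, i_long, i_short, (b_long, b_short), curve,
        pixel_size_um=stack.pixel_size_um, field_id=field_id,
    )


def run_pipeline(
    config: RunConfig,
    inputs: list,
    out_dir,
    stages: list[str] | None = None,
    calibration_curve=None,
) -> RunManifest:
    """Execute the requested stages over the input files in dependency order.

    Writes one tidy CSV per analysis plus ``manifest.json``. A stage failure on
    one field aborts that field's downstream dependents but preserves completed
    outputs; the error is re-raised after outputs are flushed.
    """
    requested = list(stages or config.stages)
    unknown = set(requested) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGE_ORDER if s in requested]
    # validate channel roles before any computation
    needed = {"segment": ["tubulin"], "puncta": ["tubulin", "organelle"],
              "nodes": ["nav16"], "orientation": ["nav16"],
              "ph": ["ex405", "ex475", "lysosome"]}
    for s in stages:
        for role in needed[s]:
            config.require_channel(role)
    if "ph" in stages and calibration_curve is None:
        raise ValueError("the ph stage requires a calibration curve")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs = [Path(p) for p in inputs]
    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(config.manifest_params(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        package_version=__version__,
        seed=config.seed,
        parameters=config.manifest_params(),
        inputs={str(p): _sha256(p) for p in inputs},
    )
    tables: dict[str, list[pd.DataFrame]] = {s: [] for s in stages}
    error: Exception | None = None
    for path in inputs:
        field_id = path.stem
        try:
            try:
                stack = read_image(path)
            except CalibrationMissingError:
                stack = read_image(
                    path,
                    overrides={"pixel_size_um": config.pixel_size_um,
                               "z_step_um": config.z_step_um},
                )
        except Exception as exc:
            error = exc
            log.error("failed to read %s: %s", path, exc)
            continue
        masks = None
        for stage in stages:
            t0 = time.perf_counter()
            try:
                if stage == "segment":
                    masks, _ = _segment_stage(stack, config)
                    df = pd.DataFrame(
                        [{
                            "field_id": field_id, "object_id": 1,
                            "cell_area_px": int(masks.cell_mask.sum()),
                            "soma_area_px": int(masks.soma_mask.sum()),
                            "neurite_area_px": int(masks.neurite_mask.sum()),
                        }]
                    )
                elif stage == "puncta":
                    if "segment" in stages and masks is None:
                        log.warning("skipping puncta for %s: segmentation failed", field_id)
                        continue
                    df = _puncta_stage(stack, config, masks, field_id)
                elif stage == "nodes":
                    df = _nodes_stage(stack, config, field_id)
                elif stage == "orientation":
                    df = _orientation_stage(stack, config, field_id)
                else:
                    df = _ph_stage(stack, config, calibration_curve, field_id)
                tables[stage].append(df)
            except Exception as exc:
                error = exc
                log.error("stage %s failed on %s: %s", stage, field_id, exc)
                if stage == "segment":
                    masks = None  # downstream dependents abort for this field
            finally:
                dt = time.perf_counter() - t0
                manifest.stage_seconds[stage] = manifest.stage_seconds.get(stage, 0.0) + dt
                log.info("stage %-11s %-16s %6.2f s", stage, field_id, dt)

    for stage, dfs in tables.items():
        if not dfs:
            continue
        df = pd.concat(dfs, ignore_index=True)
        out = out_dir / f"{stage}.csv"
        write_table(ResultsTable(df), out, format="csv")
        manifest.outputs[stage] = str(out)
    manifest.to_json(out_dir / "manifest.json")
    if error is not None:
        raise RuntimeError("one or more pipeline stages failed; partial outputs kept") from error
    return manifest


def summarize_groups(table: pd.DataFrame, grouping: str) -> pd.DataFrame:
    """Descriptive per-group statistics (n, median, quartiles, mean, SD) — no p-values."""
    if grouping not in table.columns:
        raise ValueError(f"grouping column '{grouping}' not present")
    num_cols = [
        c for c in table.columns
        if c not in (grouping, "field_id", "object_id") and pd.api.types.is_numeric_dtype(table[c])
    ]
    rows = []
    groups = table.groupby(grouping, dropna=False) if len(table) else []
    for key, g in groups:
        for col in num_cols:
            vals = g[col].dropna().to_numpy(float)
            rows.append(
                {
                    grouping: key,
                    "metric": col,
                    "n": int(vals.size),
                    "median": float(np.median(vals)) if vals.size else np.nan,
                    "q25": float(np.percentile(vals, 25)) if vals.size else np.nan,
                    "q75": float(np.percentile(vals, 75)) if vals.size else np.nan,
                    "mean": float(vals.mean()) if vals.size else np.nan,
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=[grouping, "metric", "n", "median", "q25", "q75", "mean", "sd"])
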