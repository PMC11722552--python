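"""Run configuration: thresholds in pixel and micron units, channel roles, and the seed.

Every analysis default that traces back to a published pixel/micron value is kept in
both units here so the manifest can report the physical threshold actually applied.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

DEFAULT_PIXEL_SIZE_UM = 0.07  # eMN acquisitions; node stacks use 0.05


@dataclass
class SegmentationParams:
    saturate_quantile: float = 0.7
    min_object_area_um2: float = 3.5
    fill_hole_area_um2: float = 15.0
    min_thickness_px: int = 100
    dilate_radius_px: int = 5
    soma_min_area_um2: float = 3.5
    thickness_mode: str = "half"  # "half": nearest boundary hit; "full": whole chord


@dataclass
class PunctaParams:
    saturate_quantile: float = 0.85
    gauss_sigma_px: float = 5.0
    gauss_weight: float = 0.5
    min_size_px: int = 10
    min_size_um2: float | None = None  # set to use the micron filter instead
    nucleus_min_area_um2: float = 20.0


@dataclass
class NodeParams:
    saturate_quantile: float = 0.10
    min_size_px: int = 100
    min_size_um2: float | None = None
    axis_aligned_bbox: bool = False


@dataclass
class OrientationParams:
    sigma_grad_px: float = 1.0
    sigma_window_px: float = 2.0
    bin_deg: float = 1.0


@dataclass
class PhParams:
    z_cut: float = 2.5
    max_iter: int = 10
    contact_radius_px: int = 2
    contact_min_area_px: int = 4
    background_dilate_px: int = 3
    membrane_roi_um: tuple[float, float] = (2.0, 0.5)


@dataclass
class RunConfig:
    """Validated run configuration; the single source of thresholds and randomness."""

    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    z_step_um: float | None = None
    seed: int = 0
    channels: dict[str, str] = field(default_factory=dict)  # role -> channel name
    stages: list[str] = field(default_factory=lambda: ["segment", "puncta"])
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    puncta: PunctaParams = field(default_factory=PunctaParams)
    nodes: NodeParams = field(default_factory=NodeParams)
    orientation: OrientationParams = field(default_factory=OrientationParams)
    ph: PhParams = field(default_factory=PhParams)

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        for name in (
            "min_object_area_um2",
            "fill_hole_area_um2",
            "min_thickness_px",
            "soma_min_area_um2",
        ):
            if getattr(self.segmentation, name) <= 0:
                raise ValueError(f"segmentation.{name} must be positive")
        if self.puncta.min_size_px <= 0:
            raise ValueError("puncta.min_size_px must be positive")
        roles = list(self.channels.values())
        if len(set(roles)) != len(roles):
            raise ValueError("channel roles must map to distinct channels")

    def require_channel(self, role: str) -> str:
        if role not in self.channels:
            raise ValueError(
                f"channel role '{role}' is not mapped in the configuration "
                f"(have: {sorted(self.channels)})"
            )
        return self.channels[role]

    # -- unit bookkeeping -------------------------------------------------
    def manifest_params(self) -> dict:
        """All stage parameters actually in force, with pixel/micron pairs side by side."""
        px = self.pixel_size_um
        seg = self.segmentation
        return {
            "pixel_size_um": px,
            "z_step_um": self.z_step_um,
            "seed": self.seed,
            "channels": dict(self.channels),
            "segmentation": {
                **asdict(seg),
                "min_thickness_um": seg.min_thickness_px * px,
                "min_object_area_px": seg.min_object_area_um2 / px**2,
                "fill_hole_area_px": seg.fill_hole_area_um2 / px**2,
                "soma_min_area_px": seg.soma_min_area_um2 / px**2,
            },
            "puncta": {
                **asdict(self.puncta),
                "min_size_um2_equivalent": self.puncta.min_size_px * px**2,
            },
            "nodes": {
                **asdict(self.nodes),
                "min_size_um2_equivalent": self.nodes.min_size_px * px**2,
            },
            "orientation": asdict(self.orientation),
            "ph": asdict(self.ph),
        }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key, sub in (
            ("segmentation", SegmentationParams),
            ("puncta", PunctaParams),
            ("nodes", NodeParams),
            ("orientation", OrientationParams),
            ("ph", PhParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                d = kwargs[key]
                if key == "ph" and "membrane_roi_um" in d:
                    d["membrane_roi_um"] = tuple(d["membrane_roi_um"])
                kwargs[key] = sub(**d)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["ph"]["membrane_roi_um"] = list(d["ph"]["membrane_roi_um"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
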