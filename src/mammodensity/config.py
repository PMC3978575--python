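"""Pipeline configuration: every tunable of the imaging chain in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunables of the segmentation and density pipeline.

    border_percentile
        Whole-image intensity percentile above which an edge-adjacent
        row/column mean counts as scanner border.
    max_border_frac
        Cap on detected border width, as a fraction of the image dimension.
    min_breast_frac / max_breast_frac
        Plausible breast-area bounds as fractions of the image area;
        candidates outside are treated as segmentation failures.
    connectivity
        Pixel connectivity used everywhere (4-connected).
    median_radius
        Radius of the breast-restricted median filter.
    stretch_lo_pct / stretch_hi_pct
        Percentile clip points of the contrast stretch; 0/100 recovers a
        pure min-max stretch.
    criterion
        Name of the dense/fatty threshold criterion.
    """

    border_percentile: float = 99.0
    max_border_frac: float = 0.10
    min_breast_frac: float = 0.01
    max_breast_frac: float = 0.90
    connectivity: int = 4
    median_radius: int = 1
    stretch_lo_pct: float = 1.0
    stretch_hi_pct: float = 99.0
    criterion: str = "between_class_variance"

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config file; missing file or ``None`` yields defaults."""
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
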