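"""Pipeline configuration with the study's analysis constants as defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Analysis parameters shared by the pipeline stages.

    Defaults are the published analysis constants: a two-cycle boxcar
    high-pass, the 7.2 phase-degree-per-visual-degree conversion, a
    2.9-pixel scatter neighborhood capped at 20,000 pixels, and a 10-degree
    magnification span.
    """

    window_cycles: int = 2
    angle_conversion_factor: float = 7.2
    scatter_radius_px: float = 2.9
    scatter_max_pixels: int = 20000
    span_deg: float = 10.0
    vep_window_s: tuple[float, float] = (0.0, 0.25)
    erg_a_window_s: tuple[float, float] = (0.0, 0.05)
    erg_b_window_s: tuple[float, float] = (0.05, 0.2)
    erg_baseline_s: float = 0.05
    seed: int = 0
    out_dir: str = "results"
    overrides: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        d = asdict(self)
        for key in ("vep_window_s", "erg_a_window_s", "erg_b_window_s"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("vep_window_s", "erg_a_window_s", "erg_b_window_s"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        d = asdict(self)
        d.update({k: v for k, v in kwargs.items() if v is not None})
        return PipelineConfig(**d)
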