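"""Pipeline configuration: one JSON document drives every stage.

All tunables are surfaced here; stages read nothing but this object plus
their upstream artifacts, so a run is reproducible from the config and seed
alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .errors import ConfigError
from .mlra import DEFAULT_CV_SEED
from .synthetic_scene import SceneConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Resolved parameters for a full analysis run."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    #: "derived" or a fixed NDVI value (e.g. the field operating points 0.48/0.5)
    segmentation_threshold: str | float = "derived"
    roi_size: int = 50
    glcm_levels: int = 32
    glcm_window: int = 3
    r_threshold: float = 0.8
    mic_threshold: float = 0.8
    mic_alpha: float = 0.6
    mic_c: int = 15
    cv_folds: int = 10
    cv_seed: int = DEFAULT_CV_SEED
    models: tuple[str, ...] = ("PLSR", "ARS", "SVR", "GPR")
    gpr_restarts: int = 5
    sweep_range: tuple[float, float] = (702.0, 742.0)
    output_dir: str = "chlorotex_out"

    def __post_init__(self) -> None:
        if self.roi_size < 1:
            raise ConfigError("roi_size must be >= 1")
        if self.glcm_window % 2 == 0 or self.glcm_window < 1:
            raise ConfigError("glcm_window must be odd and >= 1")
        if self.glcm_levels < 2:
            raise ConfigError("glcm_levels must be >= 2")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        from .mlra import MODEL_NAMES

        bad = [m for m in self.models if m not in MODEL_NAMES]
        if bad:
            raise ConfigError(f"unknown models {bad}; valid: {MODEL_NAMES}")
        if isinstance(self.segmentation_threshold, str):
            if self.segmentation_threshold != "derived":
                raise ConfigError(
                    "segmentation_threshold must be 'derived' or a number"
                )
        elif not -1.0 <= float(self.segmentation_threshold) <= 1.0:
            raise ConfigError("segmentation_threshold must lie in [-1, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scene"] = self.scene.to_dict()
        d["models"] = list(self.models)
        d["sweep_range"] = list(self.sweep_range)
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "scene" in d:
            d["scene"] = SceneConfig.from_dict(d["scene"])
        if "models" in d:
            d["models"] = tuple(d["models"])
        if "sweep_range" in d:
            d["sweep_range"] = tuple(d["sweep_range"])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(f"invalid pipeline config: {exc}") from exc

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        try:
            payload = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        return cls.from_dict(payload)
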