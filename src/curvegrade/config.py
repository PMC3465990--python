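"""Pipeline configuration: one YAML-serializable object holding every
module's parameter group.  Unknown keys are rejected."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict

from .enhance import EnhanceParams
from .exudates import ExudateParams
from .faz import FazParams
from .microaneurysms import MaParams
from .optic_disc import OdParams
from .vessels import VesselParams

__all__ = ["PipelineConfig", "load_config"]


class _Group(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EnhanceConfig(_Group):
    clahe_clip: float = 0.01
    clahe_tiles: Tuple[int, int] = (8, 8)
    bg_sigma: float = 30.0
    stretch_window: int = 3

    def to_params(self) -> EnhanceParams:
        return EnhanceParams(**self.model_dump())


class CurveletConfig(_Group):
    n_scales: Optional[int] = None  # None: ceil(log2(min side)) - 3
    n_angles_coarse: int = 16
    od_amplify_power: float = 5.0


class VesselConfig(_Group):
    sigma: float = 2.0
    length: int = 9
    step_deg: float = 15.0
    enhance_power: float = 0.8
    highpass_gain: float = 2.0
    min_length: int = 50
    max_roundness: float = 0.25

    def to_params(self) -> VesselParams:
        return VesselParams(**self.model_dump())


class OdConfig(_Group):
    canny_sigma: float = 3.0
    canny_low_frac: float = 0.1
    canny_high_frac: float = 0.2
    min_area: int = 100
    max_area_frac: float = 0.05
    min_vessel_frac: float = 0.05

    def to_params(self) -> OdParams:
        return OdParams(**self.model_dump())


class FazConfig(_Group):
    roi_radius_factor: float = 2.5
    closing_radius: int = 8
    min_hull_fraction: float = 0.75
    macula_side: str = "auto"  # left | right | auto

    def to_params(self) -> FazParams:
        return FazParams(
            roi_radius_factor=self.roi_radius_factor,
            closing_radius=self.closing_radius,
            min_hull_fraction=self.min_hull_fraction,
        )


class MaConfig(_Group):
    background_radius: int = 10
    tophat_radius: int = 3
    threshold_frac: float = 0.1
    faz_margin: int = 10

    def to_params(self) -> MaParams:
        return MaParams(**self.model_dump())


class ExudateConfig(_Group):
    od_dilation: int = 5
    min_region: int = 5

    def to_params(self) -> ExudateParams:
        return ExudateParams(**self.model_dump())


class SvmConfig(_Group):
    C: float = 10.0
    train_frac: float = 0.3
    n_repeats: int = 10


class PhantomConfig(_Group):
    shape: Tuple[int, int] = (576, 720)
    noise_sigma: float = 0.01


class PipelineConfig(_Group):
    """Top-level configuration; every field has a documented default."""

    enhance: EnhanceConfig = EnhanceConfig()
    curvelet: CurveletConfig = CurveletConfig()
    vessels: VesselConfig = VesselConfig()
    optic_disc: OdConfig = OdConfig()
    faz: FazConfig = FazConfig()
    microaneurysms: MaConfig = MaConfig()
    exudates: ExudateConfig = ExudateConfig()
    svm: SvmConfig = SvmConfig()
    phantom: PhantomConfig = PhantomConfig()
    seed: int = 0
    verbosity: int = 1

    def hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)


def load_config(path=None) -> PipelineConfig:
    """Load a YAML config, or the defaults when ``path`` is None."""
    if path is None:
        return PipelineConfig()
    return PipelineConfig.from_yaml(path)
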