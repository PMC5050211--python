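"""Schema-validated run configuration (YAML-backed, pydantic models).

Every parameter has a typed default; unknown keys are rejected and all type
violations are reported together rather than stopping at the first.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .synthetic import MixtureParams, OpticsParams, SceneParams

__all__ = ["RunConfig", "validate_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unreadable run configuration."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PathsConfig(_Strict):
    out_dir: str = "biofilmcubes_out"
    input_stack: str | None = None
    input_events: str | None = None


class SceneConfig(_Strict):
    n_single: int = Field(default=1000, ge=0)
    n_aggregates: int = Field(default=6, ge=0)
    cells_per_aggregate: int = Field(default=150, ge=0)
    aggregate_radius_um: float = Field(default=5.0, gt=0)
    aggregate_zmax_um: float = Field(default=40.0, gt=0)
    singles_clearance_um: float = Field(default=2.0, ge=0)
    p_curli_given_aggregate: float = Field(default=0.9, ge=0, le=1)
    p_curli_given_single: float = Field(default=0.05, ge=0, le=1)
    p_flagella_given_single: float = Field(default=0.9, ge=0, le=1)
    p_flagella_given_aggregate: float = Field(default=0.0, ge=0, le=1)
    epsilon_double: float = Field(default=0.0, ge=0, le=1)
    rho_sigmaS: float = Field(default=0.8, ge=-1, le=1)
    p_sigmaS_high_given_curli_off: float = Field(default=0.2, ge=0, le=1)
    sigmaS_low_level: float = Field(default=0.05, ge=0)
    timer_ratio_aggregate: float = Field(default=2.0, gt=0)
    timer_ratio_single: float = Field(default=0.5, gt=0)
    timer_ratio_pellicle: float = Field(default=1.5, gt=0)
    pellicle: bool = False
    n_pellicle: int = Field(default=400, ge=0)
    pellicle_thickness_um: float = Field(default=12.0, gt=0)
    domain_size_um: tuple[float, float, float] = (64.0, 64.0, 64.0)

    def to_params(self) -> SceneParams:
        d = self.model_dump()
        d.pop("domain_size_um")
        return SceneParams(**d)


class OpticsConfig(_Strict):
    voxel_spacing_um: tuple[float, float, float] = (1.0, 0.5, 0.5)
    psf_sigma_um: tuple[float, float, float] = (0.4, 0.15, 0.15)
    on_level: float = Field(default=150.0, ge=0)
    off_level: float = Field(default=0.0, ge=0)
    read_noise_sd: float = Field(default=2.0, ge=0)
    poisson_noise: bool = True
    background_level: float = Field(default=10.0, ge=0)

    def to_params(self, channels: list[str], seed: int = 0) -> OpticsParams:
        return OpticsParams(
            voxel_spacing_um=self.voxel_spacing_um,
            psf_sigma_um=self.psf_sigma_um,
            amplitude_per_state={c: (self.on_level, self.off_level) for c in channels},
            read_noise_sd=self.read_noise_sd,
            poisson_noise=self.poisson_noise,
            background_level=self.background_level,
            seed=seed,
        )


class MixtureConfig(_Strict):
    f_on: float = Field(default=0.30, ge=0, le=1)
    mu_off: float = 0.0
    sd_off: float = Field(default=60.0, gt=0)
    mu_on: float = 8.0
    sd_on: float = Field(default=0.5, gt=0)
    n_events: int = Field(default=50_000, ge=1)

    def to_params(self, seed: int = 0) -> MixtureParams:
        return MixtureParams(seed=seed, **self.model_dump())


class SyntheticConfig(_Strict):
    scene: SceneConfig = SceneConfig()
    optics: OpticsConfig = OpticsConfig()
    mixture: MixtureConfig = MixtureConfig()
    channels: list[str] = ["constitutive", "curli", "flagella"]


class SegmentationConfig(_Strict):
    smooth_radius_vox: int = Field(default=1, ge=0)
    n_bins: int = Field(default=256, ge=8)
    channels: list[str] = ["curli", "flagella"]


class QuantificationConfig(_Strict):
    cube_side_vox: int = Field(default=5, ge=1)
    min_occupancy: int = Field(default=1, ge=1)
    density_radius_um: float = Field(default=3.0, gt=0)
    roughness_window_px: int = Field(default=11, ge=3)
    z_bin_um: float = Field(default=2.0, gt=0)
    min_overlap_vox: int = Field(default=1, ge=1)


class CytometryConfig(_Strict):
    cofactor: float = Field(default=150.0, gt=0)
    threshold: float | None = None  # transformed scale; None = auto (Otsu)
    channel: str = "value"


class RunConfig(_Strict):
    """Full pipeline configuration with validated defaults."""

    paths: PathsConfig = PathsConfig()
    synthetic: SyntheticConfig = SyntheticConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    quantification: QuantificationConfig = QuantificationConfig()
    cytometry: CytometryConfig = CytometryConfig()
    seed: int = 0
    log_level: str = "INFO"


def validate_config(path: str | Path | None = None) -> RunConfig:
    """Load, default and schema-check a YAML config file.

    An empty (or absent) file yields the all-defaults configuration.  Unknown
    keys and type violations raise :class:`ConfigError` listing every
    problem, not just the first.
    """
    data = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        text = path.read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping; got {type(data).__name__}")
    try:
        return RunConfig.model_validate(data)
    except Exception as exc:  # pydantic ValidationError lists all issues
        raise ConfigError(str(exc)) from exc
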