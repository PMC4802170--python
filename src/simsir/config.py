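"""Reconstruction configuration: blocks, presets, canonical YAML round-trip.

A :class:`ReconConfig` gathers everything the two-stage pipeline needs --
acquisition geometry, optics, estimation knobs, filter settings and output
options -- and validates the cross-block consistency rules (frame counts,
band/phase solvability) before any computation starts.  Serialization is
canonical (sorted keys), so write -> read -> write is byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .bands import Ordering
from .estimate import EstimationOptions
from .otf import OtfSpec, read_otf_file
from .reconstruct import DETAIL_LEVELS, FilterSettings

__all__ = ["ConfigError", "ReconConfig", "preset", "PRESET_NAMES"]


class ConfigError(ValueError):
    pass


_ORDERING_TOKENS = {
    "phase_inner_angle_outer": Ordering.PHASE_INNER_ANGLE_OUTER,
    "angle_inner_phase_outer": Ordering.ANGLE_INNER_PHASE_OUTER,
}


@dataclass
class AcquisitionBlock:
    n_angles: int = 3
    n_phases: int = 3
    n_bands: int = 2
    ordering: str = "phase_inner_angle_outer"
    pixel_size_nm: float = 80.0


@dataclass
class OpticsBlock:
    na: float = 1.2
    lambda_em_nm: float = 680.0
    otf_file: Optional[str] = None
    attenuation_strength: float = 0.99
    attenuation_fwhm_cyc_per_um: float = 1.2


@dataclass
class EstimationBlock:
    exclusion_radius_factor: float = 0.4
    iterations: int = 3
    zoom: float = 10.0
    fade_px: Optional[int] = None
    wicker: bool = False


@dataclass
class FilterBlock:
    wiener_w: float = 0.05
    apodization: str = "cosine_bell"
    apod_cutoff_multiplier: float = 1.0
    attenuation_enabled: bool = False
    modulation_min: float = 0.15


@dataclass
class OutputBlock:
    detail: str = "none"
    out_dir: str = "."
    clip_zero: bool = False


@dataclass
class ReconConfig:
    acquisition: AcquisitionBlock = field(default_factory=AcquisitionBlock)
    optics: OpticsBlock = field(default_factory=OpticsBlock)
    estimation: EstimationBlock = field(default_factory=EstimationBlock)
    filters: FilterBlock = field(default_factory=FilterBlock)
    output: OutputBlock = field(default_factory=OutputBlock)

    # -- validation ---------------------------------------------------------
    def validate(self) -> "ReconConfig":
        a = self.acquisition
        if a.n_bands not in (2, 3):
            raise ConfigError(f"n_bands must be 2 or 3, got {a.n_bands}")
        if a.n_phases < 2 * a.n_bands - 1:
            raise ConfigError(
                f"{a.n_phases} phases cannot separate {2 * a.n_bands - 1} components"
            )
        if a.n_angles < 1:
            raise ConfigError("need at least one pattern orientation")
        if a.pixel_size_nm <= 0:
            raise ConfigError("pixel_size_nm must be positive")
        if a.ordering not in _ORDERING_TOKENS:
            raise ConfigError(
                f"unknown ordering {a.ordering!r}; known: {sorted(_ORDERING_TOKENS)}"
            )
        if self.output.detail not in DETAIL_LEVELS:
            raise ConfigError(f"detail must be one of {DETAIL_LEVELS}")
        if self.optics.na <= 0 or self.optics.lambda_em_nm <= 0:
            raise ConfigError("na and lambda_em_nm must be positive")
        if not 0 < self.filters.wiener_w <= 1:
            raise ConfigError("wiener_w must lie in (0, 1]")
        return self

    # -- derived objects ----------------------------------------------------
    @property
    def ordering(self) -> Ordering:
        return _ORDERING_TOKENS[self.acquisition.ordering]

    @property
    def frames_per_reconstruction(self) -> int:
        return self.acquisition.n_angles * self.acquisition.n_phases

    def otf_spec(self) -> OtfSpec:
        o = self.optics
        if o.otf_file:
            spec = read_otf_file(o.otf_file, na=o.na, lambda_em_nm=o.lambda_em_nm)
            spec.attenuation_strength = o.attenuation_strength
            spec.attenuation_fwhm_cyc_per_um = o.attenuation_fwhm_cyc_per_um
            return spec
        return OtfSpec(
            na=o.na,
            lambda_em_nm=o.lambda_em_nm,
            attenuation_strength=o.attenuation_strength,
            attenuation_fwhm_cyc_per_um=o.attenuation_fwhm_cyc_per_um,
        )

    def estimation_options(self) -> EstimationOptions:
        e = self.estimation
        return EstimationOptions(
            exclusion_radius_factor=e.exclusion_radius_factor,
            iterations=e.iterations,
            zoom=e.zoom,
            fade_px=e.fade_px,
            wicker=e.wicker,
        )

    def filter_settings(self) -> FilterSettings:
        f = self.filters
        return FilterSettings(
            wiener_w=f.wiener_w,
            apodization=f.apodization,
            apod_cutoff_multiplier=f.apod_cutoff_multiplier,
            attenuation_enabled=f.attenuation_enabled,
            modulation_min=f.modulation_min,
            fade_px=self.estimation.fade_px,
            detail=self.output.detail,
        )

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ReconConfig":
        blocks = {}
        for f in dataclasses.fields(cls):
            sub = d.get(f.name, {})
            block_cls = f.default_factory  # type: ignore[assignment]
            known = {x.name for x in dataclasses.fields(block_cls)}
            unknown = set(sub) - known
            if unknown:
                raise ConfigError(f"unknown keys in block {f.name!r}: {sorted(unknown)}")
            blocks[f.name] = block_cls(**sub)
        return cls(**blocks).validate()

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ReconConfig":
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError("configuration root must be a mapping")
        return cls.from_dict(data)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def read(cls, path: str | Path) -> "ReconConfig":
        return cls.from_yaml(Path(path).read_text())

    def with_overrides(self, **kv) -> "ReconConfig":
        """Apply flat ``block.key`` or bare-key overrides (None values skipped)."""
        d = self.to_dict()
        index = {
            key: block for block, sub in d.items() for key in sub
        }
        for key, value in kv.items():
            if value is None:
                continue
            if "." in key:
                block, sub = key.split(".", 1)
            else:
                block, sub = index.get(key), key
            if block not in d or sub not in d[block]:
                raise ConfigError(f"unknown configuration key {key!r}")
            d[block][sub] = value
        return ReconConfig.from_dict(d)


#: Documented machine presets.  OMX: 3 angles x 5 phases, three-beam,
#: phase-inner frame order.  Elyra: 3 angles (5 allowed via override) x
#: 5 phases, three-beam, angle-inner order (a documented assumption, easily
#: overridden).  twobeam-generic: 3 angles x 3 phases, two-beam.
_PRESETS: dict[str, dict] = {
    "omx": dict(n_angles=3, n_phases=5, n_bands=3, ordering="phase_inner_angle_outer"),
    "elyra": dict(n_angles=3, n_phases=5, n_bands=3, ordering="angle_inner_phase_outer"),
    "twobeam-generic": dict(n_angles=3, n_phases=3, n_bands=2,
                            ordering="phase_inner_angle_outer"),
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def preset(name: str) -> ReconConfig:
    """Configuration preset for a known microscope platform."""
    if name not in _PRESETS:
        raise ConfigError(f"unknown preset {name!r}; known presets: {', '.join(PRESET_NAMES)}")
    cfg = ReconConfig()
    for key, value in _PRESETS[name].items():
        setattr(cfg.acquisition, key, value)
    return cfg.validate()
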