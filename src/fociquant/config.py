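"""Simulation and analysis configuration."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

__all__ = ["SimulationConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Raised for invalid or inconsistent configuration values."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-colour synthetic movie generator.

    Intensities are in arbitrary camera units (a.u.); a molecule imaged for
    ``reference_exposure_ms`` contributes an integrated intensity of
    ``I_single_au``, scaling linearly with exposure.  All randomness is
    controlled by ``seed``; identical seed and config give bit-identical
    output.
    """

    # --- detector / geometry -------------------------------------------
    pixel_size_nm: float = 100.0
    field_height_px: int = 256
    field_width_px: int = 256
    bit_depth: int = 16
    camera_offset_au: float = 100.0
    read_noise_sd_au: float = 3.0

    # --- acquisition schedules -----------------------------------------
    frame_interval_rapid_s: float = 0.034
    n_frames_rapid: int = 300
    timelapse_interval_min: float = 5.0
    timelapse_duration_min: float = 180.0
    exposure_bf_ms: float = 34.0
    exposure_yfp_ms: float = 50.0
    exposure_red_ms: float = 100.0
    channel_lag_s: float = 2.0
    reference_exposure_ms: float = 34.0

    # --- photophysics ---------------------------------------------------
    D_free_um2_s: float = 100.0
    D_bound_um2_s: float = 1e-5
    tau_bleach_s: float = 6.0
    tau_autofluor_s: float = 60.0
    I_single_au: float = 1850.0
    I_single_red_au: float = 3000.0
    return_rate_per_s: float = 1e-3
    psf_sigma_px: float = 1.3
    autofluor_amplitude_au: float = 100.0
    free_substeps: int = 20

    # --- expression time course ----------------------------------------
    N_baseline: float = 20.0
    N_plateau: float = 280.0
    onset_min: float = 20.0
    plateau_min: float = 90.0

    # --- binding classes -----------------------------------------------
    f_tight: float = 0.05
    f_loose: float = 0.05
    f_dispersed: float = 0.60
    loose_offset_sigma_nm: float = 300.0
    replisome_foci_per_cell: int = 4
    localisation_noise_nm: float = 30.0
    foci_density_per_um2: float = 0.6
    coloc_switch_min: float = 100.0
    coloc_drop_factor: float = 0.0

    # --- cell geometry / filamentation ---------------------------------
    cell_width_um: float = 1.0
    cell_length_mean_um: float = 3.0
    cell_length_sd_um: float = 0.4
    filament_volume_cap: float = 2.5
    filament_ref_min: float = 120.0

    seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            "pixel_size_nm", "frame_interval_rapid_s", "timelapse_interval_min",
            "timelapse_duration_min", "exposure_bf_ms", "exposure_yfp_ms",
            "exposure_red_ms", "channel_lag_s", "reference_exposure_ms",
            "D_free_um2_s", "D_bound_um2_s", "tau_bleach_s", "tau_autofluor_s",
            "I_single_au", "I_single_red_au", "psf_sigma_px", "cell_width_um",
            "cell_length_mean_um", "filament_volume_cap", "filament_ref_min",
            "N_baseline", "N_plateau",
        ]
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be strictly positive")
        non_negative = [
            "camera_offset_au", "read_noise_sd_au", "return_rate_per_s",
            "autofluor_amplitude_au", "loose_offset_sigma_nm",
            "localisation_noise_nm", "cell_length_sd_um", "foci_density_per_um2",
            "coloc_drop_factor",
        ]
        for name in non_negative:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in ("n_frames_rapid", "field_height_px", "field_width_px",
                     "free_substeps"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("f_tight", "f_loose", "f_dispersed"):
            frac = getattr(self, name)
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.f_tight + self.f_loose + self.f_dispersed > 1.0 + 1e-12:
            raise ConfigError("binding-class fractions must sum to <= 1")
        if self.plateau_min <= self.onset_min:
            raise ConfigError("plateau_min must exceed onset_min")
        if self.replisome_foci_per_cell < 0:
            raise ConfigError("replisome_foci_per_cell must be >= 0")

    @property
    def f_free(self) -> float:
        return max(0.0, 1.0 - self.f_tight - self.f_loose - self.f_dispersed)

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path: str | Path) -> SimulationConfig:
    """Read a YAML config file; the ``simulation`` section maps to
    :class:`SimulationConfig` fields (a flat file is also accepted)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    section = raw.get("simulation", raw)
    if not isinstance(section, dict):
        raise ConfigError("'simulation' section must be a mapping")
    return SimulationConfig.from_dict(section)
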