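"""Structured run configuration.

One YAML document configures a full pipeline run.  Unknown keys are
errors (not warnings) so that typos cannot silently change a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, fields as dc_fields

import yaml

from rootflow.geometry import PRESETS, RootParameters

__all__ = ["ConfigError", "RunConfig", "load_config"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Validated pipeline configuration (defaults reproduce the standard
    measurement protocol: 13 phases at 0.03 s, 16 replicates, 72 bpm,
    20 l/min peak)."""

    presets: list[str] = dc_field(default_factory=lambda: ["NS", "S", "M", "L"])
    root: dict | None = None  # explicit RootParameters instead of presets
    seed: int = 0
    out_dir: str = "rootflow_out"
    grid_spacing_mm: float = 1.5
    n_phases: int = 13
    dt_s: float = 0.03
    n_replicates: int = 16
    waveform: dict = dc_field(default_factory=dict)
    jet: dict = dc_field(default_factory=dict)
    rho_kgm3: float = 1200.0
    nu_mm2s: float = 4.7
    rho_p_kgm3: float = 1180.0
    d_p_um: float = 42.0
    valve_height_mm: float = 14.5
    A_poa_mm2: dict | None = None  # per-label override of the POA assignment
    planimetry_enabled: bool = True
    planimetry_noise_sd: float = 0.03
    save_fields: bool = False

    def __post_init__(self) -> None:
        for name in ("grid_spacing_mm", "dt_s", "rho_kgm3", "nu_mm2s",
                     "rho_p_kgm3", "d_p_um", "valve_height_mm"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_replicates < 2:
            raise ConfigError("N < 2: need at least two replicates for statistics")
        if self.n_phases < 1:
            raise ConfigError("need at least one phase")
        for label in self.presets:
            if self.root is None and label not in PRESETS:
                raise ConfigError(f"unknown preset {label!r}")
        T = self.waveform.get("T_s", 60.0 / 72.0)
        if self.n_phases * self.dt_s > T:
            raise ConfigError("protocol inconsistent: n_phases * dt exceeds the period")

    def root_parameters(self) -> list[RootParameters]:
        if self.root is not None:
            r = dict(self.root)
            try:
                return [
                    RootParameters(
                        label=r.get("label", "custom"),
                        r_a=r["r_a_mm"],
                        alpha_s=r.get("alpha_s"),
                        alpha_co=r.get("alpha_co"),
                        alpha_stj=r["alpha_stj"],
                        beta1=r["beta1"],
                        beta2=r["beta2"],
                        has_sinus=r.get("has_sinus", True),
                    )
                ]
            except (KeyError, ValueError) as exc:
                raise ConfigError(f"invalid root parameters: {exc}") from exc
        return [PRESETS[label] for label in self.presets]


_WAVEFORM_KEYS = {"T_s", "Q_max_lmin", "f_sys", "shape", "f_ramp", "t_open_s"}
_JET_KEYS = {
    "r_jet", "layer_thickness", "core_length", "rf_amp", "rf_asym",
    "swirl_amp", "ring_circulation", "ring_core_radius", "ring_release_time",
    "ring_advection_speed", "sigma_u", "jitter", "smooth_voxels",
}


def load_config(path_or_dict) -> RunConfig:
    """Load and validate a run configuration from a YAML file path or a
    dict.  Unknown keys raise :class:`ConfigError`."""
    if isinstance(path_or_dict, dict):
        data = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config document must be a mapping")
    known = {f.name for f in dc_fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key, allowed in [("waveform", _WAVEFORM_KEYS), ("jet", _JET_KEYS)]:
        sub = data.get(key) or {}
        bad = set(sub) - allowed
        if bad:
            raise ConfigError(f"unknown {key} keys: {sorted(bad)}")
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
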