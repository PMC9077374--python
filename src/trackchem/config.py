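"""Simulation configuration: schema, YAML round-trip, validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import chem, tracks

__all__ = ["SimulationConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    pass


#: Default history counts by mode; the gamma figure counts independent
#: single-spur histories (see docs/methods.md for the segment equivalence).
DEFAULT_HISTORIES = {"gamma": 2000, "tritium": 30}


@dataclass
class SimulationConfig:
    mode: str = "gamma"                 # gamma | tritium
    azide_M: float = 0.0
    o2_M: float = 2.5e-4                # air-saturated water
    pH: float = 7.0
    n_histories: int | None = None
    seed: int = 0
    gamma_history: str = "spur"         # spur | segment
    t_start_ps: float = 1.0
    t_end_ps: float = 1e7
    n_times: int = 120
    r_max_nm: float = 300.0
    segment_length_um: float = 150.0
    electron_energy_keV: float = 7.8
    LET: float | None = None
    enable_protonation_channel: bool = False
    g_1ps: dict = field(default_factory=lambda: dict(tracks.DEFAULT_G_1PS))
    sigma_electron_nm: float = 3.6
    sigma_heavy_nm: float = 1.0
    mean_spur_energy_eV: float = 40.0
    network_override: str | None = None  # path to a YAML network file
    rate_overrides: dict = field(default_factory=dict)
    outdir: str | None = None

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.mode not in ("gamma", "tritium"):
            raise ConfigError(f"mode must be gamma or tritium, got {self.mode!r}")
        if self.gamma_history not in ("spur", "segment"):
            raise ConfigError("gamma_history must be 'spur' or 'segment'")
        if self.azide_M < 0 or self.o2_M < 0:
            raise ConfigError("concentrations must be >= 0")
        if not 0 <= self.pH <= 14:
            raise ConfigError("pH out of range")
        if self.t_end_ps <= self.t_start_ps or self.t_start_ps <= 0:
            raise ConfigError("need 0 < t_start_ps < t_end_ps")
        if self.n_times < 2:
            raise ConfigError("n_times must be >= 2")
        if self.n_histories is not None and self.n_histories < 1:
            raise ConfigError("n_histories must be >= 1")
        if self.sigma_electron_nm <= 0 or self.sigma_heavy_nm <= 0:
            raise ConfigError("spur widths must be > 0")
        if self.r_max_nm <= 0:
            raise ConfigError("r_max_nm must be > 0")

    # -- derived objects ---------------------------------------------------
    def histories(self) -> int:
        return self.n_histories or DEFAULT_HISTORIES[self.mode]

    def mode_params(self) -> tracks.TrackModeParams:
        return tracks.TrackModeParams(
            mode=self.mode, LET=self.LET,
            segment_length_um=self.segment_length_um,
            electron_energy_keV=self.electron_energy_keV,
            n_histories=self.n_histories)

    def spur_params(self) -> tracks.SpurModelParams:
        return tracks.SpurModelParams(
            g_1ps=dict(self.g_1ps),
            sigma={"electron": self.sigma_electron_nm,
                   "heavy": self.sigma_heavy_nm},
            mean_spur_energy=self.mean_spur_energy_eV)

    def network(self) -> chem.ReactionNetwork:
        if self.network_override:
            net = chem.ReactionNetwork.from_yaml(
                Path(self.network_override).read_text())
        else:
            net = chem.default_network()
        for rid, k in self.rate_overrides.items():
            net = net.with_rate(rid, float(k))
        return net

    def simulate_kwargs(self) -> dict:
        return dict(
            network=self.network(), mode=self.mode_params(),
            spur=self.spur_params(), azide_M=self.azide_M, o2_M=self.o2_M,
            pH=self.pH, n_histories=self.histories(), seed=self.seed,
            t_start_ps=self.t_start_ps, t_end_ps=self.t_end_ps,
            n_times=self.n_times, r_max_nm=self.r_max_nm,
            gamma_history=self.gamma_history,
            enable_protonation_channel=self.enable_protonation_channel)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        d = yaml.safe_load(text)
        if not isinstance(d, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(d)


def load_config(path) -> SimulationConfig:
    return SimulationConfig.from_yaml(Path(path).read_text())
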