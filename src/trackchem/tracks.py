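"""Synthetic 1-ps initial track configurations.

This module stands in for the physical/physicochemical stages of a full
track-structure code: it produces the spatial snapshot of radiolytic species
at 1 ps, which is both the end of the sub-picosecond chemistry and the start
of diffusion.  Two radiation qualities are emulated:

* ``gamma`` - a ~0.3 eV/nm track segment of a fast (300 MeV) proton, the
  standard surrogate for Co-60 gamma / fast-electron irradiation: widely
  spaced, spherical spurs along a straight path (mean spacing
  mean_spur_energy/LET ~ 130 nm), each an isotropic Gaussian cluster.
* ``tritium`` - the complete track of a 7.8 keV beta electron (mean LET
  ~5.9 eV/nm): the same energy-loss events packed ~20x closer, so the
  clusters overlap into a quasi-cylindrical column ~1.3 um long.

The species inventory of a single energy-loss event is controlled by the
1-ps yields g (molecules/100 eV); correlated ion pairs are created together
so each event is exactly charge neutral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpurModelParams",
    "TrackModeParams",
    "InitialConfiguration",
    "default_spur_params",
    "sample_spur_energy",
    "sample_spur",
    "generate_spur_history",
    "generate_gamma_segment",
    "generate_tritium_track",
    "generate_configuration",
    "plot_configuration",
]

#: Default 1-ps yields, molecules/100 eV.  g(H2) = 0.34 is the fixed
#: physicochemical-stage hydrogen; the others are standard 25 C picosecond
#: yields.  g(H3O+) = g(e_aq-) + g(OH-) so the expected inventory is charge
#: neutral (each hydrated electron and each hydroxide is created together
#: with a hydronium partner).
DEFAULT_G_1PS = {
    "e_aq-": 4.2,
    "OH": 5.0,
    "H": 0.6,
    "H2": 0.34,
    "H3O+": 4.7,
    "OH-": 0.5,
    "H2O2": 0.2,
}

#: Species drawn independently (Poisson); the hydronium count is slaved to
#: the anion counts for exact per-spur neutrality.
_INDEPENDENT = ("OH", "H", "H2", "H2O2")
_PAIRED_ANIONS = ("e_aq-", "OH-")


@dataclass
class SpurModelParams:
    """Geometry and inventory of a single energy-loss event at 1 ps.

    sigma maps a species class to the standard deviation (nm) of the
    isotropic Gaussian position distribution: hydrated electrons thermalize
    much farther from the ionization site than the heavy fragments, so they
    get their own, wider class.  The electron-class width is the calibrated
    free parameter of the model (see docs/methods.md).
    """

    g_1ps: dict = field(default_factory=lambda: dict(DEFAULT_G_1PS))
    #: electron-class width calibrated once so the azide-free low-LET plateau
    #: reproduces the 25 C escape yield 0.45 molecules/100 eV (see
    #: scripts/calibrate_spurs.py and docs/methods.md)
    sigma: dict = field(default_factory=lambda: {"electron": 3.6, "heavy": 1.0})
    species_class: dict = field(default_factory=lambda: {"e_aq-": "electron"})
    mean_spur_energy: float = 40.0  # eV
    spur_energy_min: float = 6.6    # eV, lowest event that makes chemistry
    spur_energy_max: float = 100.0  # eV
    spur_energy_scale: float = 52.0  # exponential scale before truncation

    def __post_init__(self):
        if any(g < 0 for g in self.g_1ps.values()):
            raise ValueError("1-ps yields must be >= 0")
        if any(s <= 0 for s in self.sigma.values()):
            raise ValueError("spur widths must be > 0")
        if self.mean_spur_energy <= 0:
            raise ValueError("mean spur energy must be > 0")
        ge = self.g_1ps.get("e_aq-", 0.0) + self.g_1ps.get("OH-", 0.0)
        gp = self.g_1ps.get("H3O+", 0.0)
        if not math.isclose(ge, gp, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError(
                "charge neutrality in expectation requires "
                "g(H3O+) == g(e_aq-) + g(OH-); got "
                f"{gp} vs {ge}")

    def sigma_of(self, species: str) -> float:
        return self.sigma[self.species_class.get(species, "heavy")]


@dataclass
class TrackModeParams:
    """Radiation quality of the generated configurations."""

    mode: str = "gamma"            # "gamma" | "tritium"
    LET: float | None = None       # eV/nm; defaults by mode
    segment_length_um: float = 150.0  # gamma track-segment length
    electron_energy_keV: float = 7.8  # tritium effective initial energy
    n_histories: int | None = None    # defaults chosen by the config layer

    def __post_init__(self):
        if self.mode not in ("gamma", "tritium"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.LET is None:
            self.LET = 0.3 if self.mode == "gamma" else 5.9
        if self.LET <= 0 or self.segment_length_um <= 0 or self.electron_energy_keV <= 0:
            raise ValueError("LET, segment length and electron energy must be > 0")


@dataclass
class InitialConfiguration:
    """The 1-ps snapshot of one track history."""

    species: list            # names, length N
    positions: np.ndarray    # (N, 3) nm
    deposited_energy: float  # eV
    birth_time_ps: float = 1.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.species) != len(self.positions):
            raise ValueError("species/positions length mismatch")
        if self.deposited_energy <= 0:
            raise ValueError("deposited energy must be > 0")
        # a snapshot may hold zero particles (sub-threshold event): its
        # deposited energy still counts towards the ensemble yields

    def __len__(self):
        return len(self.species)

    def net_charge(self, network) -> int:
        return sum(network.species[s].charge for s in self.species)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "species": self.species,
            "x_nm": self.positions[:, 0],
            "y_nm": self.positions[:, 1],
            "z_nm": self.positions[:, 2],
        })

    def save_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path, deposited_energy: float) -> "InitialConfiguration":
        df = pd.read_csv(path)
        return cls(list(df["species"]), df[["x_nm", "y_nm", "z_nm"]].to_numpy(),
                   deposited_energy)


def default_spur_params() -> SpurModelParams:
    return SpurModelParams()


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def sample_spur_energy(params: SpurModelParams, rng: np.random.Generator,
                       size=None):
    """Spur energy from an exponential truncated to [min, max] eV.

    With the default scale (52 eV) on [6.6, 100] eV the mean is ~40 eV, a
    conventional spur-energy spectrum shape.
    """
    a, b, th = params.spur_energy_min, params.spur_energy_max, params.spur_energy_scale
    u = rng.random(size)
    return a - th * np.log1p(-u * (1.0 - math.exp(-(b - a) / th)))


def sample_spur(energy: float, params: SpurModelParams, rng: np.random.Generator,
                center=(0.0, 0.0, 0.0)):
    """Draw the species inventory and positions of one energy-loss event.

    Counts are Poisson with mean g*E/100; each e_aq- and each OH- is created
    together with an H3O+ partner, so the event is exactly charge neutral.
    Positions are isotropic Gaussians about the event centre with the
    species-class width.
    """
    if energy <= 0:
        raise ValueError("spur energy must be > 0")
    names: list = []
    for sp in _INDEPENDENT:
        g = params.g_1ps.get(sp, 0.0)
        if g > 0:
            names += [sp] * int(rng.poisson(g * energy / 100.0))
    for sp in _PAIRED_ANIONS:
        g = params.g_1ps.get(sp, 0.0)
        if g > 0:
            n = int(rng.poisson(g * energy / 100.0))
            names += [sp] * n + ["H3O+"] * n
    if not names:
        return [], np.empty((0, 3))
    sigmas = np.array([params.sigma_of(s) for s in names])
    pos = np.asarray(center, dtype=float) + rng.standard_normal((len(names), 3)) * sigmas[:, None]
    return names, pos


def generate_spur_history(params: SpurModelParams, rng: np.random.Generator
                          ) -> InitialConfiguration:
    """One isolated spur with its energy drawn from the spur spectrum.

    The default low-LET history unit: at 0.3 eV/nm the mean spacing between
    spurs (~130 nm) makes cross-spur chemistry negligible, so an ensemble of
    independent spurs reproduces segment yields at a fraction of the cost.
    """
    e = float(sample_spur_energy(params, rng))
    names, pos = sample_spur(e, params, rng)
    # a low-energy event may produce no tracked species; its energy still
    # belongs in the ensemble denominator, so empty snapshots are kept
    return InitialConfiguration(names, pos, e)


def generate_gamma_segment(mode: TrackModeParams, spur: SpurModelParams,
                           rng: np.random.Generator) -> InitialConfiguration:
    """A low-LET track segment: spurs on a straight line along y.

    The first spur sits at the origin; subsequent inter-spur spacings are
    exponential with mean (spur energy)/LET, so the mean energy deposited
    per unit length equals the LET.
    """
    if mode.mode != "gamma":
        raise ValueError("mode must be gamma")
    length_nm = mode.segment_length_um * 1e3
    names: list = []
    chunks = []
    y = 0.0
    e_total = 0.0
    while True:
        e = float(sample_spur_energy(spur, rng))
        n, p = sample_spur(e, spur, rng, center=(0.0, y, 0.0))
        names += n
        if len(n):
            chunks.append(p)
        e_total += e
        y += float(rng.exponential(e / mode.LET))
        if y > length_nm:
            break
    pos = np.concatenate(chunks) if chunks else np.empty((0, 3))
    return InitialConfiguration(names, pos, e_total)


def generate_tritium_track(mode: TrackModeParams, spur: SpurModelParams,
                           rng: np.random.Generator) -> InitialConfiguration:
    """A complete 7.8 keV beta-electron track.

    Energy-loss events are drawn from the spur spectrum until the electron
    energy is exhausted (the last event takes the remainder), and placed
    along a straight path with exponential spacings of mean e/LET, giving a
    total path length ~ E/LET (~1.3 um) and a locally constant mean LET.
    """
    if mode.mode != "tritium":
        raise ValueError("mode must be tritium")
    e_total = mode.electron_energy_keV * 1e3
    names: list = []
    chunks = []
    y = 0.0
    remaining = e_total
    while remaining > 0:
        e = float(sample_spur_energy(spur, rng))
        e = min(e, remaining)
        n, p = sample_spur(e, spur, rng, center=(0.0, y, 0.0)) if e > 0 else ([], None)
        names += n
        if len(n):
            chunks.append(p)
        remaining -= e
        y += float(rng.exponential(e / mode.LET))
    pos = np.concatenate(chunks) if chunks else np.empty((0, 3))
    return InitialConfiguration(names, pos, e_total)


def generate_configuration(mode: TrackModeParams, spur: SpurModelParams,
                           rng: np.random.Generator,
                           gamma_history: str = "spur") -> InitialConfiguration:
    """Dispatch one history's initial configuration for the given mode."""
    if mode.mode == "tritium":
        return generate_tritium_track(mode, spur, rng)
    if gamma_history == "segment":
        return generate_gamma_segment(mode, spur, rng)
    return generate_spur_history(spur, rng)


def plot_configuration(config: InitialConfiguration, ax=None, **scatter_kw):
    """2-D (x, y) projection of a track snapshot (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(config.positions[:, 0], config.positions[:, 1], s=4, **scatter_kw)
    ax.set_xlabel("x (nm)")
    ax.set_ylabel("y (nm)")
    ax.set_aspect("equal")
    return ax
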