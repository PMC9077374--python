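"""Synthetic validation fixtures shared by the test suite and `validate`.

The six-particle cluster below is a synthetic construction (not derived from
any measured track): three particles of a fictitious species A and three of
species B, with two competing diffusion-controlled channels A+B and A+A whose
encounter radii (1.0 and 0.8 nm) and diffusion coefficients are chosen so
that both channels fire with sizeable, well-separated probabilities within
a 10-ns window.  It is used for the IRT-versus-Brownian-dynamics
equivalence check.
"""

from __future__ import annotations

import numpy as np

from .chem import ReactionNetwork, Species, Reaction, smoluchowski_rate
from .tracks import InitialConfiguration

__all__ = ["fixture_network", "fixture_cluster", "FIXTURE_GRID_PS"]

#: Comparison times (ps) for the IRT <-> BD equivalence check.
FIXTURE_GRID_PS = (100.0, 300.0, 1000.0, 3000.0, 10000.0)

_D_FIX = 0.005 / 1e2  # 0.005 nm^2/ps expressed in cm^2/s

# positions (nm) of the synthetic cluster; separations of several nm keep
# the pairwise competition moderate, where the IRT independent-pairs
# approximation is accurate at the resolution of the comparison
_CLUSTER_XYZ = np.array([
    ("A", 0.0, 0.0, 0.0),
    ("A", 8.0, 0.0, 0.0),
    ("A", 0.0, 10.0, 0.0),
    ("B", 5.0, 4.0, 2.0),
    ("B", -6.0, 3.0, -4.0),
    ("B", 2.0, -7.0, 4.0),
], dtype=object)


def fixture_network() -> ReactionNetwork:
    """Two competing fully diffusion-controlled channels with inert products."""
    species = {
        "A": Species("A", 0, _D_FIX, {}),
        "B": Species("B", 0, _D_FIX, {}),
        "PAB": Species("PAB", 0, _D_FIX, {}),
        "PAA": Species("PAA", 0, _D_FIX, {}),
    }
    k_ab = smoluchowski_rate(1.0, 2 * _D_FIX)   # R = 1.0 nm
    k_aa = smoluchowski_rate(0.8, 2 * _D_FIX)   # R = 0.8 nm
    reactions = [
        Reaction("F1", ("A", "B"), ("PAB",), k_ab),
        Reaction("F2", ("A", "A"), ("PAA",), k_aa),
    ]
    return ReactionNetwork(species, reactions)


def fixture_cluster() -> InitialConfiguration:
    names = [row[0] for row in _CLUSTER_XYZ]
    pos = np.array([[row[1], row[2], row[3]] for row in _CLUSTER_XYZ],
                   dtype=float)
    return InitialConfiguration(names, pos, deposited_energy=100.0)
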