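"""Internal unit system and conversion constants.

The simulation works in nanometres and picoseconds; rate constants and
diffusion coefficients are quoted in the literature units (M^-1 s^-1 and
cm^2 s^-1) and converted exactly once, here.
"""

AVOGADRO = 6.02214076e23  # 1/mol

#: Water molarity at 25 C (mol/L); used to fold the solvent into
#: intrinsically first-order channels written with a bimolecular constant.
WATER_MOLARITY = 55.34

#: M^-1 s^-1  ->  nm^3 ps^-1 per molecule pair.
#: 1 L = 1e24 nm^3 and 1 s = 1e12 ps, so k/N_A [L/s] = k * 1e12/N_A [nm^3/ps].
K_BIMOL_TO_NM3_PS = 1e12 / AVOGADRO

#: cm^2 s^-1 -> nm^2 ps^-1  (1 cm^2 = 1e14 nm^2, 1 s = 1e12 ps).
D_CM2_S_TO_NM2_PS = 1e2

#: s^-1 -> ps^-1
PER_S_TO_PER_PS = 1e-12

PS_PER_S = 1e12


def k_bimolecular_nm3_ps(k_molar_per_s: float) -> float:
    """Convert a bimolecular rate constant from M^-1 s^-1 to nm^3/ps per pair."""
    return k_molar_per_s * K_BIMOL_TO_NM3_PS


def diffusion_nm2_ps(d_cm2_s: float) -> float:
    """Convert a diffusion coefficient from cm^2/s to nm^2/ps."""
    return d_cm2_s * D_CM2_S_TO_NM2_PS


def rate_per_ps(rate_per_s: float) -> float:
    """Convert a first-order rate from s^-1 to ps^-1."""
    return rate_per_s * PER_S_TO_PER_PS
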