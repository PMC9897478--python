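"""Per-element physical constants used throughout the package.

Coherent neutron scattering lengths are the Sears compilation values (fm);
displaced volumes are Fraser/Traub-style atomic-group volumes (A^3) keyed by
``<ELEMENT><n attached H>``; van der Waals radii are the Bondi set (A).
All tables are plain dicts so users can extend or override them.
"""

from __future__ import annotations

# Coherent neutron scattering length, fm (1 fm = 1e-13 cm).
NEUTRON_B: dict[str, float] = {
    "H": -3.7390,
    "D": 6.671,
    "C": 6.6460,
    "N": 9.36,
    "O": 5.803,
    "S": 2.847,
    "P": 5.13,
    "NA": 3.63,
    "MG": 5.375,
    "CL": 9.5770,
    "K": 3.67,
    "CA": 4.70,
    "MN": -3.73,
    "FE": 9.45,
    "CU": 7.718,
    "ZN": 5.680,
    "SE": 7.970,
    "BR": 6.795,
    "I": 5.28,
}

# Atomic masses, g/mol.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "NA": 22.990,
    "MG": 24.305,
    "CL": 35.45,
    "K": 39.098,
    "CA": 40.078,
    "MN": 54.938,
    "FE": 55.845,
    "CU": 63.546,
    "ZN": 65.38,
    "SE": 78.971,
    "BR": 79.904,
    "I": 126.904,
}

# Displaced atomic-group volumes, A^3, keyed by element + number of attached H.
# Values follow the Fraser & Traub group volumes as used in solution-scattering
# practice (CRYSOL-style); bare-element fallbacks below.
GROUP_VOLUME: dict[str, float] = {
    "H0": 5.15,
    "D0": 5.15,
    "C0": 16.44,
    "C1": 21.59,
    "C2": 26.74,
    "C3": 31.89,
    "N0": 2.49,
    "N1": 7.64,
    "N2": 12.79,
    "N3": 17.94,
    "O0": 9.13,
    "O1": 14.28,
    "O2": 29.90,  # water
    "S0": 19.86,
    "S1": 25.01,
    "P0": 5.81,
}

# Fallback displaced volume per element when no group entry applies (A^3).
ELEMENT_VOLUME: dict[str, float] = {
    "H": 5.15,
    "D": 5.15,
    "C": 16.44,
    "N": 2.49,
    "O": 9.13,
    "S": 19.86,
    "P": 5.81,
    "NA": 4.45,
    "MG": 1.56,
    "CL": 24.84,
    "K": 11.01,
    "CA": 4.19,
    "MN": 9.0,
    "FE": 7.99,
    "CU": 8.78,
    "ZN": 9.85,
    "SE": 28.73,
    "BR": 31.54,
    "I": 44.6,
}

# Bondi van der Waals radii, A.
VDW_RADIUS: dict[str, float] = {
    "H": 1.20,
    "D": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "NA": 2.27,
    "MG": 1.73,
    "CL": 1.75,
    "K": 2.75,
    "CA": 2.31,
    "FE": 2.00,
    "ZN": 1.39,
    "SE": 1.90,
    "BR": 1.85,
    "I": 1.98,
}

DEFAULT_VDW_RADIUS = 1.70
DEFAULT_MASS = 12.011

# Water: scattering length of one solvent molecule, fm, and molecular volume, A^3.
B_H2O = 2.0 * NEUTRON_B["H"] + NEUTRON_B["O"]
B_D2O = 2.0 * NEUTRON_B["D"] + NEUTRON_B["O"]
WATER_VOLUME = 29.9

AVOGADRO = 6.02214076e23


def solvent_scattering_length_density(d2o_fraction: float) -> float:
    """Scattering-length density of an H2O/D2O mixture, fm / A^3."""
    if not 0.0 <= d2o_fraction <= 1.0:
        raise ValueError(f"d2o_fraction must be in [0, 1], got {d2o_fraction}")
    b = d2o_fraction * B_D2O + (1.0 - d2o_fraction) * B_H2O
    return b / WATER_VOLUME


def mass_of(element: str) -> float:
    return ATOMIC_MASS.get(element.upper(), DEFAULT_MASS)


def vdw_radius_of(element: str) -> float:
    return VDW_RADIUS.get(element.upper(), DEFAULT_VDW_RADIUS)
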