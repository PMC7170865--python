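"""Physical constants and unit conversions.

Internally everything is SI: lengths in m, times in s, diffusion
coefficients in m^2 s^-1.  Concentrations at the interface are molar
(mol L^-1); the ``1e3`` factors below convert between litres and m^3.
"""

N_A = 6.02214076e23
"""Avogadro constant, mol^-1 (2019 SI exact value)."""


def molar_to_per_m3(c: float) -> float:
    """mol L^-1 -> molecules per m^3."""
    return c * 1e3 * N_A


def counts_to_molar(n, volume_m3: float):
    """Molecule count(s) in a box of ``volume_m3`` -> mol L^-1."""
    return n / (1e3 * N_A * volume_m3)


def molar_to_counts(c: float, volume_m3: float) -> int:
    """mol L^-1 -> whole-molecule count, round to nearest."""
    return int(round(c * 1e3 * N_A * volume_m3))
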