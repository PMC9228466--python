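"""Unit conventions and conversion constants.

Internal units throughout the package: lengths in Å, times in ps.
Diffusion coefficients are *reported* in the conventional 1e-5 cm²/s
(the unit used for surface self-diffusion of small molecules), while all
arithmetic on trajectories is done in Å²/ps.

The single conversion implemented here:

    1e-5 cm²/s = 1e-5 · 1e16 Å²/s = 1e11 Å²/s = 0.1 Å²/ps
"""

# Å²/ps per (1e-5 cm²/s)
A2_PER_PS_PER_REPORTED = 0.1


def diffusion_to_internal(d_reported: float) -> float:
    """Convert a diffusion coefficient from 1e-5 cm²/s to Å²/ps."""
    return d_reported * A2_PER_PS_PER_REPORTED


def diffusion_to_reported(d_a2_per_ps: float) -> float:
    """Convert a diffusion coefficient from Å²/ps to 1e-5 cm²/s."""
    return d_a2_per_ps / A2_PER_PS_PER_REPORTED


# Standard atomic weights (a.u.), CIAAW conventional values.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Cl": 35.45,
}


def molar_mass(composition: dict[str, int]) -> float:
    """Molar mass in a.u. from an element -> count mapping.

    >>> round(molar_mass({"C": 8, "H": 11, "N": 1, "O": 2}), 2)  # dopamine
    153.18
    """
    return sum(ATOMIC_MASSES[el] * n for el, n in composition.items())
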