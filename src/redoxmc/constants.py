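"""Physical constants, in the unit system used throughout the package.

Lengths are in angstroms, charges in elementary charges, energies in
kcal/mol, potentials in mV (vs SHE where anchored by a reference couple).
"""

#: Boltzmann constant, kcal mol^-1 K^-1
KBOLTZ = 0.0019872041

#: kT at 298 K, kcal/mol
KT_298 = 0.5922

#: Faraday constant, kcal mol^-1 V^-1
FARADAY = 23.061

#: Coulomb constant, kcal A mol^-1 e^-2  (q1*q2*COULOMB_K/(eps*r) is kcal/mol)
COULOMB_K = 332.0636

DEFAULT_TEMPERATURE = 298.0


def kt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy kT in kcal/mol (0.5922 at 298 K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    if abs(temperature - 298.0) < 1e-9:
        return KT_298
    return KBOLTZ * temperature


def debye_kappa2(ionic_strength: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Screening coefficient kappa-bar^2 (A^-2) for the linearized PB equation.

    Defined so that in bulk solvent  eps_w * lap(phi) = kappa2 * phi,
    with phi in the internal e/A potential units.  For 0.15 M 1:1 salt in
    water at 298 K this reproduces a Debye length of ~7.9 A.
    """
    if ionic_strength < 0:
        raise ValueError("ionic_strength must be >= 0")
    import math

    c = ionic_strength * 6.02214076e-4  # ions per A^3 per species
    return 8.0 * math.pi * COULOMB_K * c / kt(temperature)
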