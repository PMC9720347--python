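"""Physical constants and unit conversions used throughout the package.

Internal unit system: lengths in Å, times in ps, energies in kcal/mol,
diffusivities in Å²/ns (the conventional unit for membrane-normal
diffusivity profiles).  Conversions to reporting units (cm/s for
permeability, fmol/s and molecules/s for flux) happen at the edges.
"""

#: Boltzmann constant, kcal mol^-1 K^-1 (CODATA value in chemical units).
KB_KCAL_MOL_K = 0.0019872041

#: Avogadro's number, mol^-1.
AVOGADRO = 6.02214076e23

#: 1 Å/ns expressed in cm/s  (1e-8 cm per 1e-9 s).
ANG_PER_NS_TO_CM_PER_S = 10.0

#: 1 Å²/ns expressed in Å²/ps.
ANG2_PER_NS_TO_ANG2_PER_PS = 1.0e-3

#: 1 μm² expressed in cm².
UM2_TO_CM2 = 1.0e-8

#: 1 mM expressed in mol/cm³.
MM_TO_MOL_PER_CM3 = 1.0e-6

#: 1 mol/s expressed in fmol/s.
MOL_TO_FMOL = 1.0e15


def kt(temperature: float) -> float:
    """Thermal energy k_B·T in kcal/mol at ``temperature`` kelvin."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL_MOL_K * temperature


def beta(temperature: float) -> float:
    """Inverse thermal energy 1/(k_B·T) in mol/kcal."""
    return 1.0 / kt(temperature)
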