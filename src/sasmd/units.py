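"""Unit conventions and conversion constants.

Internal units throughout the package: energy kJ/mol, length nm, time ps,
force kJ/mol/nm, spring constant kJ/mol/nm^2, friction kJ/mol/nm^2*ps.
Reports convert forces to pN.
"""

#: 1 kJ/mol/nm expressed in piconewton (per molecule).
KJ_MOL_NM_TO_PN = 1.66054

#: Boltzmann constant, kJ/mol/K.
KB = 0.0083144621


def to_pN(force_kj_mol_nm: float) -> float:
    """Convert a force from internal units (kJ/mol/nm) to pN."""
    return force_kj_mol_nm * KJ_MOL_NM_TO_PN


def from_pN(force_pn: float) -> float:
    """Convert a force from pN to internal units (kJ/mol/nm)."""
    return force_pn / KJ_MOL_NM_TO_PN
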