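"""Physical constants and material parameters for poly(γ-benzyl-L-glutamate).

All values in SI unless the name says otherwise.  The PBLG-specific entries
(repeat-unit molar mass, helical rise, residue dipole, repeat-unit molar
volume) are the standard literature values for the 18/5 α-helix.
"""

#: Vacuum permittivity, F m^-1.
EPS0 = 8.854e-12

#: Boltzmann constant, J K^-1.
KB = 1.380649e-23

#: Gas constant, J mol^-1 K^-1.
R = 8.314462618

#: Avogadro constant, mol^-1.
NA = 6.02214076e23

#: One debye, C m.
DEBYE = 3.33564e-30

#: Molar mass of the BLG repeat unit, g mol^-1.
M0_BLG = 219.2

#: Rise per repeat unit along the α-helix axis, nm.
HELIX_RISE_NM = 0.15

#: Axial dipole moment per helical residue, debye.
MU_PER_RESIDUE_HELIX_D = 3.4

#: Molar volume of the PBLG repeat unit, cm^3 mol^-1 (pressure-work context).
DELTAV_RU_CM3_MOL = 171.0


def _check() -> None:
    for name, v in globals().items():
        if name.isupper() and isinstance(v, float):
            assert v > 0, name


_check()
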