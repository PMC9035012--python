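"""Unit conventions shared by every module.

All quantities follow the GROMOS convention: lengths in nm, times in ps,
energies in kJ·mol⁻¹, masses in u (g·mol⁻¹), temperatures in K.  Derived
units follow: forces in kJ·mol⁻¹·nm⁻¹, velocities in nm·ps⁻¹, friction
coefficients in ps⁻¹.
"""

#: Boltzmann's constant in kJ·mol⁻¹·K⁻¹.
KB = 0.00831451

#: nm per Ångström, for the PDB boundary.
NM_PER_ANGSTROM = 0.1

#: Degrees per radian.
import math as _math

DEG = _math.pi / 180.0
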