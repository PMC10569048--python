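"""Physical constants in the package's internal unit system.

Internal units everywhere: length Å, time ps, charge e, mass amu
(g/mol), energy kJ/mol, temperature K.  All unit conversion happens at
I/O boundaries; analysis code never converts.
"""

#: Boltzmann constant, kJ/mol/K (molar gas constant).
KB = 8.314462618e-3

#: Avogadro constant, 1/mol.
N_AVOGADRO = 6.02214076e23

#: Coulomb constant k_e = 1/(4 pi eps0), kJ Å / (mol e^2).
#: A +1e/+1e pair at 1 Å stores 1389.35 kJ/mol.
KE_COULOMB = 1389.35457644382

#: Planck constant, kJ ps / mol.
H_PLANCK = 0.399031002270895

#: Multiply m[amu] * v[Å/ps]^2 by this to get energy in kJ/mol.
#: (1 amu Å^2/ps^2 = 0.01 kJ/mol)
MVSQ_TO_KJMOL = 0.01

#: 1 Å^3 in litres, for molar concentrations.
A3_TO_L = 1.0e-27

#: kT at 300 K, kJ/mol.
KT300 = KB * 300.0
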