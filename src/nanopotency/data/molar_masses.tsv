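chemical_formula	molar_mass_g_per_mol	metal	metal_atoms_per_formula
ZnO	81.38	Zn	1
CuO	79.55	Cu	1
NiO	74.69	Ni	1
MnO2	86.94	Mn	1
Al2O3	101.96	Al	2
Fe2O3	159.69	Fe	2
TiO2	79.87	Ti	1
ZnCl2	136.30	Zn	1
MnSO4.H2O	169.02	Mn	1
NiCl2.6H2O	237.69	Ni	1
AlCl3.6H2O	241.43	Al	1
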