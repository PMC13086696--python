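compound	chemical_formula	metal	metal_atoms_per_formula	form_code	pps_nm	solubility_pct	ssa_m2_per_g
ZnCl2	ZnCl2	Zn	1	1
MnSO4	MnSO4.H2O	Mn	1	1
NiCl2	NiCl2.6H2O	Ni	1	1
AlCl3	AlCl3.6H2O	Al	1	1
ZnO NP	ZnO	Zn	1	2	21.65	19.30	27.27
CuO NP	CuO	Cu	1	2	55.35	51.60	10.34
MnO2 NP	MnO2	Mn	1	2	24.59	3.87	42.16
NiO NP	NiO	Ni	1	2	24.57	1.81	36.60
Al2O3 NP	Al2O3	Al	2	2	17.30	0.73	145.29
Fe2O3 NP	Fe2O3	Fe	2	2	22.04		44.88
TiO2 NP	TiO2	Ti	1	2	23.80	0.05	52.73
ZnO MP	ZnO	Zn	1	3	1000.00	11.80	5.85
CuO MP	CuO	Cu	1	3	5000.00	1.17	0.80
MnO2 MP	MnO2	Mn	1	3	5000.00	1.37	2.55
NiO MP	NiO	Ni	1	3	5000.00	0.07	2.52
Al2O3 MP	Al2O3	Al	2	3	950.00	0.02	22.32
Fe2O3 MP	Fe2O3	Fe	2	3	5000.00		9.52
TiO2 MP	TiO2	Ti	1	3	1500.00	0.02	10.76
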