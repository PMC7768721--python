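species	dG_f_kJ_mol	dH_f_kJ_mol	charge
NH4+	-79.31	-132.51	1
NO2-	-32.20	-104.60	-1
NO3-	-111.25	-207.30	-1
N2	18.18	-10.44	0
H2O	-237.18	-285.83	0
H+	0.00	0.00	1
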