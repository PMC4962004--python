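trait	breed	mean	sem	n
body_weight_kg	jinhua	29.33	0.88	3
body_weight_kg	yorkshire	47.07	1.93	3
thyroid_weight_g	jinhua	3.20	0.06	3
thyroid_weight_g	yorkshire	4.93	0.38	3
thyroid_index_g_kg	jinhua	0.109	0.004	3
thyroid_index_g_kg	yorkshire	0.105	0.009	3
serum_tt4_nmol_l	jinhua	30.36	0.76	3
serum_tt4_nmol_l	yorkshire	37.85	1.73	3
serum_tt3_nmol_l	jinhua	0.53	0.02	3
serum_tt3_nmol_l	yorkshire	1.00	0.12	3
serum_ft4_pmol_l	jinhua	9.34	0.20	3
serum_ft4_pmol_l	yorkshire	11.31	0.73	3
serum_ft3_pmol_l	jinhua	1.84	0.09	3
serum_ft3_pmol_l	yorkshire	2.58	0.33	3
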