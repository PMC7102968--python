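complex	construct	kd_nm	n	delta_h_kj_mol	delta_s_j_mol_k	printed_minus_tds_kj_mol	printed_dg_kj_mol
RNA_aptamer	TetR	5.6	0.96	-156.0	-365.2	108.8	-47.2
RNA_aptamer	TetR-Q38A	26.2	1.10	-152.8	-367.2	109.4	-43.4
RNA_aptamer	TetR-Y42A	13900	1.0	-74.6	-157.1	46.8	-27.8
tetO_DNA	TetR	51.1	1.17	57.7	336.4	-100.2	-42.5
tetO_DNA	TetR-Q38A	432.7	1.11	53.4	300.9	-89.7	-36.3
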