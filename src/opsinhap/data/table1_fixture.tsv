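haplotype	printed_haplotype	amino_acids	n	median_ser_os	mean_ser_os	pct_exon3_skipping	split_halves_rank
AACGGTGG	AACGGTGG	MVVVA	12	-3.16	-3.14	16	1
AACGGCAT	AACGGCAT	MVAIS	30	-1.62	-2.00	3	2.49
AACGGTAT	AACGGTAT	MVVIS	23	-2.01	-2.57	0	2.51
AACGGCAG	AACGGCAG	MVAIA	67	-1.05	-1.71	2	4.25
GCGGGCAG	GCGGGCAG	LVAIA	77	-0.97	-1.38	14	4.75
GCGGGCAT	GCGGGCAT	LVAIS	157	-0.99	-1.38	1	6
GCGATCAT	GCGATCAT	LIAIS	25	-1.10	-1.30	1	7
AAGGGCAT	AAGGGCAT	MVAIS	9	0.15	0.51	0	8.99
GCGGGTAT	GCGGGGAT	LVVIS	5	-1.06	-1.04	1	9
GCCGGCAT	GCCGGCAT	LVAIS	4	-0.05	-0.25	8	9.02
GCCGGCAG	GCCGGCAG	LVAIA	4	0.54	0.92	2	11
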