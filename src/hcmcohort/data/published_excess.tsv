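stratum	vclass	egypt_excess_pct	uk_excess_pct	egypt_gpos_prop_pct	uk_gpos_prop_pct
MYH7	nontruncating	13.95	9.68	30.26	32.88
MYH7	truncating	3.06	0.01	6.27	0.91
MYBPC3	nontruncating	4.45	6.73	13.65	26.94
MYBPC3	truncating	9.34	5.41	17.71	16.89
MLC	nontruncating	5.25	0.26	9.96	2.28
MLC	truncating	0.19	0.00	0.37	0.00
thin_filament	nontruncating	3.50	3.38	6.64	12.33
thin_filament	truncating	0.00	-0.09	0.00	0.00
CSRP3	nontruncating	1.70	0.49	3.69	1.83
CSRP3	truncating	0.72	0.00	1.85	0.00
JPH2	nontruncating	1.47	0.29	5.17	1.37
JPH2	truncating	0.00	0.00	0.00	0.00
ACTN2	nontruncating	-0.11	0.51	4.06	3.65
ACTN2	truncating	0.19	0.00	0.37	0.00
PLN	nontruncating	0.00	-0.23	0.00	0.46
PLN	truncating	0.00	0.15	0.00	0.46
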