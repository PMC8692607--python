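sample	group	origin	reads_after_trimming	reads_mapped	pct_on_target_printed	total_assembled_target_len	loci_with_sequence	pct_target_recovered
Aloe_aageodonta	Aloe	S	2399050	1268854	54.23	321066	189	92.5
Aloe_bakeri	Aloe	P	2416438	1285339	53.1	329211	188	94.8
Aloe_ballyi	Aloe	S	1602898	773633	48.3	334326	188	96.3
Aloe_brandhamii	Aloe	H	2789581	142523	4.5	149709	168	43.1
Aloe_comptonii	Aloe	S	1498657	805082	53.7	323970	188	93.3
Aloe_distans	Aloe	P	3640964	2043250	56.1	327033	189	94.2
Aloe_erinacea	Aloe	S	3876389	2318089	59.8	323070	188	93.1
Aloe_ferox	Aloe	S	2368852	1263235	53.3	327576	189	94.4
Aloe_flexilifolia	Aloe	S	2788225	1454756	52.2	327432	189	94.3
Aloe_framesii	Aloe	S	2542514	1380373	54.3	322503	187	92.9
Aloe_greatheadii	Aloe	S	2358342	1209120	51.3	321351	189	92.6
Aloe_jucunda	Aloe	P	2818267	1477635	52.4	324225	189	93.4
Aloe_juvenna	Aloe	P	1090090	557847	51.2	318018	188	91.6
Aloe_lateritia	Aloe	S	2542942	1261381	49.6	327498	187	94.3
Aloe_macrocarpa	Aloe	S	1512167	723207	47.8	322302	189	92.8
Aloe_marlothii	Aloe	P	3514483	1922219	54.7	329751	189	95.0
Aloe_mcloughlinii	Aloe	S	2773518	1520473	54.8	326418	189	94.0
Aloe_percrassa	Aloe	H	3696487	1978408	53.5	323346	187	93.1
Aloe_succotrina	Aloe	S	5184554	3133167	60.4	331827	189	95.6
Aloe_suffulta	Aloe	S	2324265	1145238	49.7	329352	188	94.9
Aloe_vaombe	Aloe	P	3163131	1712967	54.2	313962	188	90.4
Aloe_viguieri	Aloe	P	2560543	1434442	56.0	330045	189	95.1
Aloe_yemenica	Aloe	S	2920940	1561211	53.4	326742	188	94.1
Aloiampelos_ciliaris	relative	F	3279922	1790419	54.6	311208	189	89.6
Bulbine_frutescens	outgroup	P	3050140	454810	14.9	257868	183	74.3
Xanthorrhoea_preissii	outgroup	P	10785948	4880245	45.2	250695	183	72.2
Hemerocallis_flava	outgroup	P	2639965	504220	19.1	165225	152	47.6
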