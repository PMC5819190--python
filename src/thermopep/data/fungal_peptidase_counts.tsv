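species	group	total	Serine	Aspartic	Metallo	Threonine	Cysteine	Glutamic	Asparagine	Mixed	UNK
Aspergillus_niger	mesophilic	437	204	15	110	24	79	5	0	0	0
Chaetomium_globosum	mesophilic	469	177	29	123	26	110	4	0	0	0
Myceliophthora_sepedonium	mesophilic	494	194	29	129	31	106	4	0	1	0
Mucor_circinelloides	mesophilic	396	108	41	135	21	90	0	0	0	1
Penicillium_chrysogenum	mesophilic	397	137	33	129	22	73	2	0	0	1
Penicillium_roqueforti	mesophilic	820	381	36	203	36	146	4	4	0	10
Rhizopus_delemar	mesophilic	464	122	75	126	34	107	0	0	0	0
Talaromyces_stipitatus	mesophilic	686	180	164	145	105	82	9	0	0	1
Aspergillus_fumigatus	thermotolerant	349	137	9	101	22	77	2	0	1	0
Rhizopus_microsporus	thermotolerant	652	181	53	212	39	167	0	0	0	0
Chaetomium_thermophilum	thermophilic	277	85	22	74	26	66	4	0	0	0
Myceliophthora_fergusii	thermophilic	281	85	18	81	23	71	3	0	0	0
Myceliophthora_thermophila	thermophilic	320	108	23	86	26	73	4	0	0	0
Myriococcum_thermophilum	thermophilic	318	106	23	82	28	76	3	0	0	0
Rasamsonia_byssochlamydoides	thermophilic	311	115	16	84	24	70	2	0	0	0
Rhizomucor_pusillus	thermophilic	347	106	35	109	18	79	0	0	0	0
Thermoascus_crustaceus	thermophilic	326	122	21	87	23	72	1	0	0	0
Thermomucor_indicae-seudaticae	thermophilic	297	78	29	101	22	67	0	0	0	0
Thermomyces_dupontii	thermophilic	241	66	11	71	22	68	4	0	0	0
Thermomyces_lanuginosus	thermophilic	246	63	14	72	22	70	5	0	0	0
Thermomyces_stellatus	thermophilic	307	104	14	83	28	76	0	2	0	0
Thielavia_australiensis	thermophilic	293	89	22	78	26	76	1	0	1	0
Thielavia_terrestris	thermophilic	340	110	31	84	26	75	5	0	0	0
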