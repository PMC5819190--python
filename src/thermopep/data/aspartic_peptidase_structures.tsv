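species	group	mw_kda	pI	helices	strands	sheets	surface_area	volume	n_cavities
Aspergillus_fumigatus	mesophilic	49.99	5.88	6	25	3	12.76	44.29	8
Aspergillus_niger	mesophilic	46.72	4.56	6	27	4	12.67	43.50	5
Chaetomium_globosum	mesophilic	80.29	5.52	7	25	3	13.44	43.52	5
Myceliophthora_sepedonium	mesophilic	52.07	4.67	6	24	3	13.09	44.33	6
Chaetomium_thermophilum	thermophilic	49.38	7.82	3	25	3	13.49	43.72	5
Myceliophthora_fergusii	thermophilic	52.44	4.57	7	24	3	13.57	44.01	3
Myceliophthora_thermophila	thermophilic	52.45	4.39	7	24	3	13.57	44.01	3
Myriococcum_thermophilum	thermophilic	52.08	4.84	5	25	3	13.45	44.10	4
Rasamsonia_byssochlamydoides	thermophilic	45.41	4.73	8	26	3	12.45	42.15	4
Thermoascus_crustaceus	thermophilic	47.43	4.89	8	26	3	13.26	43.40	5
Thielavia_australiensis	thermophilic	45.57	7.22	6	25	4	12.89	43.62	2
Thielavia_terrestris	thermophilic	74.85	5.13	7	25	3	13.21	42.21	3
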