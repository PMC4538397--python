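# n_recorded_species = 1194
# Published reference table: the 18 biomass-hyperdominant species of eight
# Central African moist-forest sites (Kor=Korup, Ngov=Ngovayang, Mab=Mabounie,
# SE_Cam=South-East Cameroon, Mba=Mbaiki, Mal=Malebo, Yan=Yangambi,
# Itu=Ituri-Lenda). Values are the printed site-standardized regional figures.
species	family	agb_t_ha	pct	pct_cum	n_sites	sites
Gilbertiodendron dewevrei	Fabaceae	46.64	20.02	20.02	3	Mal, Yan, It
Klainedoxa gabonensis	Irvingiaceae	8.38	3.60	23.62	7	Kor, Mab, SE_Cam, Mal, Mbaiki, Yan, Itu
Coula edulis	Olacaceae	6.39	2.74	26.36	2	Kor, Mab, Ngov
Desbordesia glaucescens	Irvingiaceae	6.33	2.72	29.08	3	Kor, Mab, SE_Cam
Dialium pachyphyllum	Fabaceae	5.40	2.32	31.40	6	Kor, Ngov, Mab, SE_Cam, Mal, Yan
Lecomtedoxa klaineana	Sapotaceae	4.62	1.98	33.38	1	Kor
Oubanguia alata	Lecythidaceae	4.23	1.81	35.19	1	Kor
Strombosia pustulata	Olacaceae	4.22	1.81	37.00	6	Kor, Mab, SE_Cam, Mal, Yan, It
Lophira alata	Ochnaceae	4.18	1.79	38.80	2	Kor, Mab
Petersianthus macrocarpus	Lecythidaceae	4.14	1.78	40.58	6	Mab, SE_Cam, Mal, Yan, Itu, Mbaiki
Polyalthia cf.suaveolens	Annonaceae	4.1	1.76	42.34	7	Ngov, Mab, SE_Cam, Mba, Mal, Yan, Itu
Scorodophloeus zenkeri	Fabaceae	4.07	1.74	44.08	3	Mab, Mal, Yan
Julbernardia seretii	Fabaceae	3.33	1.43	45.51	3	Yan, Itu
Alstonia boonei	Apocynaceae	2.88	1.24	46.75	5	Kor, Mab, SE_Cam, Yan, Itu
Pentaclethra macrophylla	Fabaceae	2.81	1.21	47.95	5	Mab, SE_Cam, Mal, Yan, Itu
Erythrophleum suaveolens	Fabaceae	2.40	1.02	48.97	4	SE_Cam, Mal, Yan, Itu
Staudtia kamerunensis	Myristicaceae	2.30	0.99	49.96	8	all
Plagiostyles africana	Euphorbiaceae	2.30	0.99	50.95	3	Mab, Mal, Ngov
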