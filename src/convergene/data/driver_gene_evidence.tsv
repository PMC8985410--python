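gene	eqtl_count	gwas_count	ppi_partners	early_deg	abeta_r	abeta_sig	tau_r	tau_sig	cfg_printed
GJA1	2	2	PSEN1;MAPT;APOE	yes	0.388	p01	0.131	ns	5
FOXO1	1	0	PSEN2	yes	0.270	ns	0.526	p05	4
PRKX	3	NA	PSEN1	yes	0.352	p05	-0.023	ns	4
RPH3A	5	2	-	yes	-0.199	ns	-0.738	p01	4
CASP6	5	0	APP;PSEN1;PSEN2;MAPT	yes	0.482	p001	0.738	p01	4
CRMP1	1	3	MAPT	NA	-0.304	p05	-0.506	ns	4
RGS4	1	32	-	yes	-0.419	p01	-0.579	p05	4
NPTX2	1	1	-	yes	-0.688	p001	-0.783	p001	4
RPS27	1	0	PSEN2	yes	0.503	p001	0.662	p01	4
MEGF10	3	8	-	yes	0.559	p001	0.120	ns	4
AP2A1	1	0	APP;PSEN2;MAPT	yes	-0.277	ns	-0.585	p05	4
PITPNC1	10	1	-	yes	-0.128	ns	-0.638	p05	4
AGT	1	0	APP;PSEN1;APOE	yes	-0.359	p05	0.002	ns	4
AQP4	7	4	-	yes	0.800	p001	0.275	ns	4
MYT1L	3	12	-	yes	-0.488	p001	-0.583	p05	4
IQGAP1	1	0	PSEN1	yes	0.310	p05	0.282	ns	4
IGFBP7	8	0	MAPT;APOE	yes	0.353	p05	0.510	ns	4
CITED2	1	0	APP;PSEN1;APOE	yes	-0.433	p01	-0.772	p001	4
SMAD1	16	1	APP;APOE	NA	-0.332	p05	-0.497	ns	4
CDH7	0	1	PSEN1	yes	-0.345	p05	-0.691	p01	4
MSRB2	5	2	-	yes	0.32	p05	0.609	p05	4
DBI	1	1	-	yes	0.780	p001	0.718	p01	4
PELI2	2	0	PSEN2	yes	0.591	p001	-0.107	ns	4
AVEN	1	1	-	yes	0.525	p001	0.008	ns	4
F13A1	7	3	APP;APOE	NA	0.195	ns	0.623	p05	4
SLA	1	0	PSEN1;MAPT	yes	0.114	ns	0.662	p01	4
ADAMTS20	2	17	-	yes	0.085	ns	0.587	p05	4
RARB	6	2	PSEN2	yes	-0.064	ns	-0.387	ns	4
SDC2	8	3	PSEN1;PSEN2;MAPT;APOE	yes	0.041	ns	0.086	ns	4
DCN	8	0	APP;PSEN1;MAPT;APOE	yes	-0.416	p01	0.546	p05	4
CCR5	1	0	APP	yes	0.769	p001	0.616	p05	4
GPRC5B	2	41	-	yes	0.307	p05	-0.248	ns	4
IRF5	1	0	APP;PSEN1;PSEN2;MAPT;APOE	yes	0.879	p001	0.839	p001	4
IGFBP7	8	0	MAPT;APOE	yes	0.353	p05	0.510	ns	4
CXCL12	1	0	APP;PSEN2;MAPT;APOE	yes	0.432	p01	-0.069	ns	4
CREM	1	0	PSEN1;MAPT;APOE	yes	-0.439	p01	-0.396	ns	4
EHHADH	14	0	MAPT;APOE	yes	0.438	p01	-0.022	ns	4
SLC1A3	7	1	-	yes	0.651	p001	0.494	ns	4
VAV3	0	5	MAPT	yes	0.319	p05	-0.284	ns	4
IL15	2	18	-	yes	0.623	p001	0.685	p01	4
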