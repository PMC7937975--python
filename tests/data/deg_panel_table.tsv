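gene_id	tmm_blue	tmm_orange	log_fold_change	category
BZ1-2	0.31	294.55	-9.81	ABP
DFR-2	0.15	99.80	-9.29	ABP
IEMT1-2	0.05	9.34	-7.59	nonABP
CYP84A-2	0.08	2.25	-4.74	nonABP
LaMYB61	0.20	5.27	-4.68	regulatory
AS1	4.98	90.89	-4.20	nonABP
CYP84A-1	0.66	4.72	-2.84	nonABP
Beta-glucosidase-7	0.19	1.29	-2.69	nonABP
Beta-glucosidase-1	15.47	83.41	-2.45	nonABP
Beta-glucosidase-8	0.47	2.44	-2.42	nonABP
PRDX6	0.28	1.29	-2.17	nonABP
IEMT1-1	7.42	24.85	-1.77	nonABP
CYP84A-3	0.87	2.84	-1.72	nonABP
Beta-glucosidase-5	0.66	2.01	-1.63	nonABP
Fl. 3-O-methyl.	7.26	21.53	-1.59	nonABP
Beta-glucosidase-6	6.94	20.24	-1.56	nonABP
Beta-glucosidase-4	1.75	4.14	-1.26	nonABP
PKR-2	1.66	3.80	-1.20	nonABP
DFR-1	406.80	193.69	1.06	ABP
CCR-1	50.45	22.93	1.12	nonABP
BZ1-1	58.20	25.46	1.18	ABP
F3'5'H	655.06	267.30	1.28	ABP
DICGT-1	39.46	14.95	1.39	nonABP
GT1	6.88	2.47	1.47	ABP
3GT	20.51	7.14	1.50	ABP
CCR-2	7.64	2.40	1.66	nonABP
uidA	15.59	4.82	1.68	nonABP
FLS	503.38	144.86	1.77	nonABP
ATTSM1-2	28.12	7.53	1.89	nonABP
Beta-glucosidase-2	3.36	0.85	1.96	nonABP
ATTSM1-1	18.57	3.84	2.26	nonABP
Beta-glucosidase-3	12.76	2.62	2.26	nonABP
OMT	145.81	27.40	2.39	ABP
UGT72E	17.68	2.26	2.94	nonABP
DICGT-2	46.75	5.20	3.16	nonABP
UGT73C6	5.89	0.51	3.50	nonABP
PKR-1	12.16	0.40	4.88	nonABP
LAR	3.28	0.09	5.25	nonABP
Caffeoyl CoA O-methyl.	1.27	0.00	7.65	nonABP
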