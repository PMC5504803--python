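gene_symbol	p_value	q_value	log2_fc	status
ALCAM	5.90E-04	4.91E-02	-2.12	Downregulated
CAV1	2.98E-04	4.91E-02	-1.72	Downregulated
VIM	4.09E-04	4.91E-02	-1.61	Downregulated
MYH9	4.04E-04	4.91E-02	1.58	Upregulated
SH3BGRL3	2.68E-04	4.91E-02	2.70	Upregulated
EIF4B	5.78E-04	4.91E-02	2.77	Upregulated
CAST	3.55E-04	4.91E-02	3.09	Upregulated
DDX21	4.16E-04	4.91E-02	3.20	Upregulated
CKMT1A	3.36E-04	4.91E-02	3.46	Upregulated
TXNDC17	4.92E-04	4.91E-02	1.69	RC-77 T/E only
KRT19	7.77E-04	5.40E-02	-2.49	Downregulated
TF	7.29E-04	5.40E-02	-2.30	Downregulated
ITGA6	1.44E-03	5.40E-02	-1.93	Downregulated
LAMC2	9.86E-04	5.40E-02	-1.72	Downregulated
CD59	9.15E-04	5.40E-02	-1.65	Downregulated
FDFT1	1.23E-03	5.40E-02	-1.31	Downregulated
FLNA	1.06E-03	5.40E-02	1.21	Upregulated
HADH	1.61E-03	5.40E-02	1.22	Upregulated
XRCC5	1.42E-03	5.40E-02	1.35	Upregulated
PTMA	1.49E-03	5.40E-02	1.65	Upregulated
ACOT7	1.37E-03	5.40E-02	1.74	Upregulated
HMGA1	1.58E-03	5.40E-02	1.79	Upregulated
DHX15	1.10E-03	5.40E-02	2.10	Upregulated
SAFB	1.59E-03	5.40E-02	2.27	Upregulated
TPR	1.62E-03	5.40E-02	3.52	Upregulated
HBA1	1.80E-03	5.54E-02	-1.87	RC-77 N/E only
PML	1.77E-03	5.54E-02	1.69	RC-77 T/E only
RRBP1	1.89E-03	5.63E-02	1.64	Upregulated
AHCY	2.00E-03	5.75E-02	1.68	Upregulated
IFI16	2.37E-03	6.59E-02	1.39	Upregulated
PCK2	2.51E-03	6.75E-02	3.04	Upregulated
SFN	2.60E-03	6.76E-02	1.49	Upregulated
LMNB1	3.04E-03	7.26E-02	-0.87	Downregulated
ACTN1	3.05E-03	7.26E-02	1.06	Upregulated
HMGA2	2.95E-03	7.26E-02	2.19	Upregulated
VDAC1	4.59E-03	7.67E-02	-1.00	Downregulated
ITGB1	3.48E-03	7.67E-02	-0.92	Downregulated
HMGN2	4.22E-03	7.67E-02	1.34	Upregulated
PDLIM1	4.40E-03	7.67E-02	1.61	Upregulated
CCT5	4.72E-03	7.67E-02	1.66	Upregulated
ANPEP	5.25E-03	7.67E-02	-2.38	RC-77 N/E only
PFDN2	4.96E-03	7.67E-02	1.35	RC-77 T/E only
RPS24	4.96E-03	7.67E-02	1.35	RC-77 T/E only
SRSF1	4.96E-03	7.67E-02	1.35	RC-77 T/E only
ESD	5.05E-03	7.67E-02	1.42	RC-77 T/E only
EWSR1	5.15E-03	7.67E-02	1.47	RC-77 T/E only
HDGF	5.15E-03	7.67E-02	1.47	RC-77 T/E only
HMGN1	4.96E-03	7.67E-02	1.47	RC-77 T/E only
MTAP	4.96E-03	7.67E-02	1.47	RC-77 T/E only
PSAT1	5.15E-03	7.67E-02	1.53	RC-77 T/E only
RPL10	4.99E-03	7.67E-02	1.53	RC-77 T/E only
PSME3	5.22E-03	7.67E-02	1.58	RC-77 T/E only
RPS11	4.99E-03	7.67E-02	1.64	RC-77 T/E only
RTCB	5.25E-03	7.67E-02	1.64	RC-77 T/E only
ADAR	5.25E-03	7.67E-02	1.92	RC-77 T/E only
EIF3I	5.22E-03	7.67E-02	1.96	RC-77 T/E only
RPL35	5.18E-03	7.67E-02	2.08	RC-77 T/E only
COX5A	5.74E-03	8.24E-02	-1.38	Downregulated
CTNNB1	5.93E-03	8.37E-02	1.40	Upregulated
KRT8	6.14E-03	8.52E-02	-1.79	Downregulated
CD44	6.44E-03	8.60E-02	-0.77	Downregulated
SERBP1	6.51E-03	8.60E-02	1.58	Upregulated
RPL6	6.38E-03	8.60E-02	2.14	Upregulated
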