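gene_id	antibody_id	compartment	fraction_bin	intensity	category
CLEC3A	SYN-AB-CLEC3A	whole_urothelium	3	2	tissue_enhanced
DHRS2	SYN-AB-DHRS2	whole_urothelium	3	2	group_enriched
HOXA1	SYN-AB-HOXA1	whole_urothelium	3	2	tissue_enhanced
PADI3	SYN-AB-PADI3	whole_urothelium	3	2	group_enriched
DUOXA2	SYN-AB-DUOXA2	whole_urothelium	3	2	tissue_enhanced
BMP3	SYN-AB-BMP3	whole_urothelium	3	2	tissue_enhanced
TRPA1	SYN-AB-TRPA1	whole_urothelium	3	2	tissue_enhanced
HPGD	SYN-AB-HPGD	whole_urothelium	3	2	tissue_enhanced
RBFOX3	SYN-AB-RBFOX3	whole_urothelium	3	2	group_enriched
ACER2	SYN-AB-ACER2	whole_urothelium	3	2	tissue_enhanced
CCR8	SYN-AB-CCR8	whole_urothelium	3	2	tissue_enhanced
CYP1A1	SYN-AB-CYP1A1	whole_urothelium	3	2	group_enriched
PTGS2	SYN-AB-PTGS2	whole_urothelium	3	2	tissue_enhanced
OSTN	SYN-AB-OSTN	whole_urothelium	3	2	tissue_enhanced
UPK1B	SYN-AB-UPK1B	whole_urothelium	3	2	tissue_enhanced
IL24	SYN-AB-IL24	whole_urothelium	3	2	group_enriched
MYO3B	SYN-AB-MYO3B	whole_urothelium	3	2	tissue_enhanced
SHH	SYN-AB-SHH	whole_urothelium	3	2	tissue_enhanced
CTHRC1	SYN-AB-CTHRC1	whole_urothelium	3	2	tissue_enhanced
CHRDL2	SYN-AB-CHRDL2	whole_urothelium	3	2	group_enriched
UPK1A	SYN-AB-UPK1A	umbrella	3	3	group_enriched
UPK2	SYN-AB-UPK2	umbrella	3	3	tissue_enriched
UPK3A	SYN-AB-UPK3A	umbrella	3	3	group_enriched
UPK3B	SYN-AB-UPK3B	umbrella	3	3	group_enriched
KRT17	SYN-AB-KRT17	intermediate_basal	2	2	tissue_enhanced
PCP4L1	SYN-AB-PCP4L1	intermediate_basal	2	2	tissue_enhanced
ATP1A4	SYN-AB-ATP1A4	intermediate_basal	2	2	tissue_enhanced
CYP24A1	SYN-AB-CYP24A1	other	2	1	tissue_enhanced
DKK1	SYN-AB-DKK1	other	2	1	tissue_enhanced
ALG1L	SYN-AB-ALG1L	other	2	1	tissue_enhanced
FSTL4	SYN-AB-FSTL4	other	2	1	tissue_enhanced
FOXQ1	SYN-AB-FOXQ1	other	2	1	tissue_enhanced
EDARADD	SYN-AB-EDARADD	other	2	1	tissue_enhanced
CXCL5	SYN-AB-CXCL5	other	2	1	tissue_enhanced
SERPINB4	SYN-AB-SERPINB4	other	2	1	group_enriched
SNX31	SYN-AB-SNX31	other	2	1	group_enriched
GREM1	SYN-AB-GREM1	other	2	1	tissue_enhanced
SYNGENE-A01	SYN-AB-SYNGENE-A01	other	2	1	group_enriched
SYNGENE-A02	SYN-AB-SYNGENE-A02	other	2	1	group_enriched
SYNGENE-A03	SYN-AB-SYNGENE-A03	other	2	1	group_enriched
SYNGENE-A04	SYN-AB-SYNGENE-A04	other	2	1	group_enriched
SYNGENE-A05	SYN-AB-SYNGENE-A05	other	2	1	group_enriched
SYNGENE-A06	SYN-AB-SYNGENE-A06	other	2	1	group_enriched
SYNGENE-A07	SYN-AB-SYNGENE-A07	other	2	1	group_enriched
SYNGENE-A08	SYN-AB-SYNGENE-A08	other	2	1	group_enriched
SYNGENE-A09	SYN-AB-SYNGENE-A09	other	2	1	tissue_enhanced
SYNGENE-A10	SYN-AB-SYNGENE-A10	other	2	1	tissue_enhanced
SYNGENE-A11	SYN-AB-SYNGENE-A11	other	2	1	tissue_enhanced
SYNGENE-A12	SYN-AB-SYNGENE-A12	other	2	1	tissue_enhanced
SYNGENE-A13	SYN-AB-SYNGENE-A13	other	2	1	tissue_enhanced
SYNGENE-A14	SYN-AB-SYNGENE-A14	other	2	1	tissue_enhanced
SYNGENE-A15	SYN-AB-SYNGENE-A15	other	2	1	tissue_enhanced
SYNGENE-A16	SYN-AB-SYNGENE-A16	other	2	1	tissue_enhanced
SYNGENE-A17	SYN-AB-SYNGENE-A17	other	2	1	tissue_enhanced
SYNGENE-A18	SYN-AB-SYNGENE-A18	other	2	1	tissue_enhanced
SYNGENE-A19	SYN-AB-SYNGENE-A19	other	2	1	tissue_enhanced
SYNGENE-A20	SYN-AB-SYNGENE-A20	other	2	1	tissue_enhanced
SYNGENE-A21	SYN-AB-SYNGENE-A21	other	2	1	tissue_enhanced
SYNGENE-A22	SYN-AB-SYNGENE-A22	other	2	1	tissue_enhanced
SYNGENE-A23	SYN-AB-SYNGENE-A23	other	2	1	tissue_enhanced
SYNGENE-A24	SYN-AB-SYNGENE-A24	other	2	1	tissue_enhanced
SYNGENE-A25	SYN-AB-SYNGENE-A25	other	2	1	tissue_enhanced
SYNGENE-A26	SYN-AB-SYNGENE-A26	other	2	1	tissue_enhanced
SYNGENE-A27	SYN-AB-SYNGENE-A27	other	2	1	tissue_enhanced
SYNGENE-A28	SYN-AB-SYNGENE-A28	other	2	1	tissue_enhanced
SYNGENE-A29	SYN-AB-SYNGENE-A29	other	2	1	tissue_enhanced
SYNGENE-A30	SYN-AB-SYNGENE-A30	other	2	1	tissue_enhanced
SYNGENE-A31	SYN-AB-SYNGENE-A31	other	2	1	tissue_enhanced
SYNGENE-A32	SYN-AB-SYNGENE-A32	other	2	1	tissue_enhanced
SYNGENE-A33	SYN-AB-SYNGENE-A33	other	2	1	tissue_enhanced
SYNGENE-A34	SYN-AB-SYNGENE-A34	other	2	1	tissue_enhanced
SYNGENE-A35	SYN-AB-SYNGENE-A35	other	2	1	tissue_enhanced
SYNGENE-N01	SYN-AB-SYNGENE-N01	not_analyzed			group_enriched
SYNGENE-N02	SYN-AB-SYNGENE-N02	not_analyzed			group_enriched
SYNGENE-N03	SYN-AB-SYNGENE-N03	not_analyzed			group_enriched
SYNGENE-N04	SYN-AB-SYNGENE-N04	not_analyzed			group_enriched
SYNGENE-N05	SYN-AB-SYNGENE-N05	not_analyzed			tissue_enhanced
SYNGENE-N06	SYN-AB-SYNGENE-N06	not_analyzed			tissue_enhanced
SYNGENE-N07	SYN-AB-SYNGENE-N07	not_analyzed			tissue_enhanced
SYNGENE-N08	SYN-AB-SYNGENE-N08	not_analyzed			tissue_enhanced
SYNGENE-N09	SYN-AB-SYNGENE-N09	not_analyzed			tissue_enhanced
SYNGENE-N10	SYN-AB-SYNGENE-N10	not_analyzed			tissue_enhanced
SYNGENE-N11	SYN-AB-SYNGENE-N11	not_analyzed			tissue_enhanced
SYNGENE-N12	SYN-AB-SYNGENE-N12	not_analyzed			tissue_enhanced
SYNGENE-N13	SYN-AB-SYNGENE-N13	not_analyzed			tissue_enhanced
SYNGENE-N14	SYN-AB-SYNGENE-N14	not_analyzed			tissue_enhanced
SYNGENE-N15	SYN-AB-SYNGENE-N15	not_analyzed			tissue_enhanced
SYNGENE-N16	SYN-AB-SYNGENE-N16	not_analyzed			tissue_enhanced
SYNGENE-N17	SYN-AB-SYNGENE-N17	not_analyzed			tissue_enhanced
SYNGENE-N18	SYN-AB-SYNGENE-N18	not_analyzed			tissue_enhanced
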