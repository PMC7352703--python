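gene_name	chrom	pos	known_editome	aaf_ctr	aaf_lps	annotation
FAM214A	1	119024113	1	0.611, 0.474, 0.222	0.571, 0.333, 0.167	intron_variant
FAM214A	1	119024125	1	0.471, 0.389, 0.125	0.333, 0.154, 0.214	intron_variant
SPPL2A	1	121133488	0	0.0, 0.071, 0.0	0.273, 0.333, 0.167	3_prime_UTR_variant
SPPL2A	1	121133557	0	0.304, 0.367, 0.333	0.5, 0.419, 0.263	3_prime_UTR_variant
SPPL2A	1	121133571	0	0.36, 0.447, 0.147	0.2, 0.289, 0.261	3_prime_UTR_variant
ENSSSCG00000004985	1	169701294	0	0.143, 0.154, 0.0	0.375, 0.083, 0.0	3_prime_UTR_variant
DHRS7	1	189153076	1	0.125, 0.111, 0.25	0.182, 0.2, 0.071	3_prime_UTR_variant
DHRS7	1	189153088	1	0.059, 0.125, 0.286	0.1, 0.25, 0.0	3_prime_UTR_variant
DENND4C	1	203449165	0	0.333, 0.1, 0.2	0.0, 0.0, 0.0	downstream_gene_variant
DENND4C	1	203449178	0	0.333, 0.222, 0.2	0.111, 0.0, 0.0	downstream_gene_variant
HDHD3	1	254011510	0	0.25, 0.167, 0.5	0.5, 0.167, 0.667	upstream_gene_variant
RC3H2	1	263824986	0	0.444, 0.4, 0.333	0.444, 0.25, 0.0	upstream_gene_variant
ENSSSCG00000038757	1	66466635	0	0.167, 0.25, 0.4	0.333, 0.5, 0.429	intron_variant
ENSSSCG00000038757	1	66466642	0	0.429, 0.333, 0.2	0.5, 0.571, 0.167	intron_variant
ENSSSCG00000038757	1	66466658	0	0.25, 0.5, 0.0	0.333, 0.25, 0.0	intron_variant
TRAF3IP2	1	77485788	0	0.167, 0.182, 0.571	0.143, 0.0, 0.143	downstream_gene_variant
ARL14EP	2	30295149	0	0.167, 0.167, 0.143	0.444, 0.0, 0.375	3_prime_UTR_variant
ARL14EP	2	30295163	0	0.1, 0.0, 0.167	0.111, 0.2, 0.0	3_prime_UTR_variant
TMEM161A	2	58744433	0	0.3, 0.3, 0.286	0.125, 0.0, 0.0	3_prime_UTR_variant
GNG3	2	9050458	0	0.333, 0.1, 0.143	0.077, 0.0, 0.0	downstream_gene_variant
RPS15A	3	26783904	0	0.0, 0.375, 0.043	0.188, 0.0, 0.143	3_prime_UTR_variant
ZNF484	3	41895871	1	0.375, 0.071, 0.429	0.3, 0.0, 0.333	3_prime_UTR_variant
CRIPT	3	93916337	1	0.438, 0.4, 0.333	0.4, 0.333, 0.25	splice_region_variant&intron_variant
ENSSSCG00000021180	4	36847416	1	0.563, 0.571, 0.333	0.375, 0.435, 0.333	intron_variant
RDH10	4	62570908	0	0.0, 0.571, 0.375	0.577, 0.543, 0.391	3_prime_UTR_variant
SFT2D2	4	82714164	0	0.143, 0.214, 0.333	0.25, 0.222, 0.0	intron_variant
SFT2D2	4	82714165	0	0.5, 0.462, 0.667	0.5, 0.667, 0.0	intron_variant
SFT2D2	4	82714213	1	0.545, 0.609, 0.6	0.214, 0.5, 0.308	intron_variant
SFT2D2	4	82714216	1	0.667, 0.227, 0.182	0.267, 0.25, 0.308	intron_variant
SFT2D2	4	82714221	1	0.538, 0.364, 0.167	0.176, 0.304, 0.2	intron_variant
SFT2D2	4	82714222	1	0.154, 0.091, 0.0	0.235, 0.167, 0.067	intron_variant
ATF6	4	88593317	1	0.4, 0.667, 0.2	0.364, 0.25, 0.333	3_prime_UTR_variant
ENSSSCG00000040782	4	98777743	0	0.125, 0.182, 0.4	0.0, 0.636, 0.111	downstream_gene_variant
ENSSSCG00000040782	4	98777751	0	0.385, 0.5, 0.667	0.333, 0.375, 0.444	downstream_gene_variant
KIAA1551	5	42263049	0	0.2, 0.0, 0.143	0.167, 0.364, 0.0	downstream_gene_variant
KIAA1551	5	42263098	0	0.333, 0.222, 0.143	0.182, 0.0, 0.0	downstream_gene_variant
ENSSSCG00000027085	6	39367588	1	0.286, 0.259, 0.158	0.261, 0.4, 0.222	3_prime_UTR_variant
CATSPERG	6	47279285	0	0.091, 0.25, 0.0	0.429, 0.111, 0.105	intron_variant
ENSSSCG00000033351	6	62013919	1	0.25, 0.25, 0.286	0.111, 0.0, 0.071	3_prime_UTR_variant
PLOD1	6	72021487	1	0.286, 0.25, 0.25	0.455, 0.375, 0.25	downstream_gene_variant
PLA2G7	7	41487728	0	0.059, 0.2, 0.059	0.286, 0.0, 0.111	3_prime_UTR_variant
FCF1	7	97961485	0	0.2, 0.0, 0.375	0.5, 0.429, 0.333	downstream_gene_variant
NDUFC1	8	87702830	0	0.182, 0.0, 0.176	0.333, 0.125, 0.333	3_prime_UTR_variant
PPP1R15B	9	65058149	0	0.346, 0.393, 0.344	0.373, 0.221, 0.342	3_prime_UTR_variant
PPP1R15B	9	65058152	1	0.156, 0.226, 0.121	0.25, 0.107, 0.158	3_prime_UTR_variant
AAED1	10	25443226	1	0.217, 0.194, 0.333	0.167, 0.139, 0.077	3_prime_UTR_variant
AAED1	10	25443245	1	0.36, 0.385, 0.522	0.458, 0.395, 0.263	3_prime_UTR_variant
RSAD1	12	26775820	0	0.0, 0.111, 0.0	0.333, 0.143, 0.222	downstream_gene_variant
ENSSSCG00000011234	13	18421001	1	0.111, 0.2, 0.143	0.167, 0.077, 0.222	intron_variant
GFM1	13	98408126	0	0.25, 0.0, 0.429	0.333, 0.222, 0.25	upstream_gene_variant
GFM1	13	98408170	0	0.0, 0.077, 0.0	0.111, 0.273, 0.143	upstream_gene_variant
GFM1	13	98408190	0	0.375, 0.292, 0.333	0.111, 0.214, 0.143	upstream_gene_variant
ENSSSCG00000031589	14	60792171	0	0.167, 0.333, 0.333	0.182, 0.0, 0.0	downstream_gene_variant
ZNF277	18	33313035	0	0.143, 0.333, 0.429	0.2, 0.286, 0.182	intron_variant
ZNF277	18	33313036	1	0.286, 0.0, 0.429	0.0, 0.286, 0.231	intron_variant
ENSSSCG00000023820	18	50580239	1	0.571, 0.0, 0.0	0.273, 0.313, 0.179	downstream_gene_variant
ENSSSCG00000023820	18	50580258	1	0.571, 0.364, 0.6	0.625, 0.688, 0.318	downstream_gene_variant
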