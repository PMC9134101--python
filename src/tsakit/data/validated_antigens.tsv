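sequence	antigen_class	sample	endogenous_ratio	mean_intensity	sps_ms3_ratio	calibration_r2
RMLLSHTGK	aeTSA	RKO	ND	ND	ND	ND
LPHRALSGI	aeTSA	S1	-0.364	ND	ND	ND
GTNPTAAVK	aeTSA	S2	2.095	7238.425	12.174	1.000
LRHKLVLNR	aeTSA	S2	0.307	ND	ND	ND
RIGGVGVEK	aeTSA	S2	1.965	29256.450	6.740	1.000
SIIETVNSL	aeTSA	S2	0.288	ND	ND	ND
TVNTQQYNTK	aeTSA	S2	-0.021	ND	ND	ND
SVSHLHIFF	aeTSA	S3	-1.100	ND	ND	ND
TTLENLPQK	aeTSA	S4	0.134	3140.888	3.783	0.999
AQKLQVRI	aeTSA	S5	0.793	ND	ND	ND
GQIELSIYR	aeTSA	S5	0.328	ND	ND	ND
HGALSIRSI	aeTSA	S5	0.777	ND	ND	ND
RLMKFLPV	aeTSA	S5	0.171	ND	ND	ND
SLYISEERK	aeTSA	S5	0.046	ND	ND	ND
VQTAVLNV	aeTSA	S5	1.089	ND	ND	ND
VEAPHLPSF	aeTSA	S6	1.059	43782.842	41.318	1.000
RNRQVATAL	aeTSA	S6	1.090	12174.663	5.722	1.000
RNRQVATAL	not_assigned	S1	0.890	15514.238	3.507	1.000
KIGEVIVTK	mTSA	S2	2.506	70659.600	13.637	1.000
TRSTIILHL	mTSA	S3	1.381	34365.322	48.807	0.997
VLYRSVLLLK	noncanonical_TAA	S6	0.997	ND	ND	ND
TYKYVDINTF	canonical_TAA	S1	1.969	29834.369	8.226	0.998
RYLEKFYGL	canonical_TAA	S1	2.840	27614.243	7.661	0.997
RYLEKFYGL	canonical_TAA	S6	2.970	106928.288	16.090	0.999
KSINEFWNK	canonical_TAA	S2	2.212	56110.117	5.238	0.999
RIQLPVVSK	canonical_TAA	S4	1.083	7612.379	12.073	0.999
QMAGLRDTY	canonical_TAA	S3	1.140	36090.603	2.884	0.999
AQYDQASTKY	canonical_TAA	S4	1.452	ND	ND	ND
FVDNQYWRY	canonical_TAA	S4	0.721	5853.987	10.954	1.000
SANVSKVSF	canonical_TAA	S5	1.114	12780.925	2.321	0.999
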