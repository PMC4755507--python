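substrate_id	kinase	substrate	peptide	site	reported_p
SUB0001	CK2	Cell division cycle 34	APDEGSDLFYD	S203	3.52e-07
SUB0002	CaMK2	C ets 1 protein	VPSYDSFDSED	S285	6.95e-06
SUB0003	PKA	NFKB3	QLRRPSDRELS	S263	1.65e-05
SUB0004	EGFR	Ezrin	LRLQDYEEKTK	Y307	1.99e-05
SUB0005	PKC (alpha subunit)	c-Src	KPKDASQRRRS	S12	2.05e-05
SUB0006	EphB2	Ras-related protein	TIEDSYTKIAS	Y66	4.21e-05
SUB0007	PAK2	Ribosomal protein S6	RRRLSSLRAST	S236	5.32e-05
SUB0008	MAPKAP kinase 2	Serum response factor	LKRSLSEMEIG	S103	9.99e-06
SUB0009	Ribosomal S6 kinase 1	Protein phosphatase 1	RRGSDSSEDIY	S48	4.38e-05
SUB0010	PDGFR beta	SHP2	RKGHEYTNIKY	T353	1.27e-07
SUB0011	Ribosomal protein S6 kinase alpha 3	HMG14	EPKRRSARLSA	S7	4.89e-05
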