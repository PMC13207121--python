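participant	n_target_variants	n_target_genes	gene	family_pathway	patient_pathways
1	7	7	ADAM32	1	Cytoskeleton;ER quality control;Growth factor;Ion channel
1	7	7	DNAJB9	0	Cytoskeleton;ER quality control;Growth factor;Ion channel
1	7	7	EDEM2	0	Cytoskeleton;ER quality control;Growth factor;Ion channel
1	7	7	FGFBP1	0	Cytoskeleton;ER quality control;Growth factor;Ion channel
1	7	7	KCNH6	0	Cytoskeleton;ER quality control;Growth factor;Ion channel
1	7	7	MMP24	1	Cytoskeleton;ER quality control;Growth factor;Ion channel
1	7	7	SPTA1	0	Cytoskeleton;ER quality control;Growth factor;Ion channel
2	4	4	EMILIN2	0	Cardiac;ECM structural;Muscle
2	4	4	ITIH2	1	Cardiac;ECM structural;Muscle
2	4	4	NEBL	0	Cardiac;ECM structural;Muscle
2	4	4	TRDN	0	Cardiac;ECM structural;Muscle
3	5	5	EFNB2	1	Cytoskeleton;ECM structural;Membrane repair
3	5	5	FGD4	0	Cytoskeleton;ECM structural;Membrane repair
3	5	5	TECTA	0	Cytoskeleton;ECM structural;Membrane repair
3	5	5	TRIM72	0	Cytoskeleton;ECM structural;Membrane repair
3	5	5	VWA5B1	0	Cytoskeleton;ECM structural;Membrane repair
4	4	4	ASAP1	1	Cytoskeleton;Immune;TGF-beta/BMP
4	4	4	KCP	0	Cytoskeleton;Immune;TGF-beta/BMP
4	4	4	SSH2	0	Cytoskeleton;Immune;TGF-beta/BMP
4	4	4	TICAM2	0	Cytoskeleton;Immune;TGF-beta/BMP
5	3	3	NFASC	1	Ion channel;Wnt
5	3	3	RSPO4	0	Ion channel;Wnt
5	3	3	SCN5A	0	Ion channel;Wnt
6	5	5	ALPL	0	Coagulation;Cytoskeleton;Skeletal
6	5	5	F7	0	Coagulation;Cytoskeleton;Skeletal
6	5	5	GFAP	0	Coagulation;Cytoskeleton;Skeletal
6	5	5	ITIH6	1	Coagulation;Cytoskeleton;Skeletal
6	5	5	RLN1	1	Coagulation;Cytoskeleton;Skeletal
7	7	5	CLDN1	1	Cytoskeleton;ECM structural;Immune;Vascular
7	7	5	FCRL4	0	Cytoskeleton;ECM structural;Immune;Vascular
7	7	5	MEGF10	0	Cytoskeleton;ECM structural;Immune;Vascular
7	7	5	NOSTRIN	0	Cytoskeleton;ECM structural;Immune;Vascular
7	7	5	SHANK2	0	Cytoskeleton;ECM structural;Immune;Vascular
8	8	7	CGREF1	0	ECM structural;Immune;Wound healing
8	8	7	GSDME	0	ECM structural;Immune;Wound healing
8	8	7	IL36B	0	ECM structural;Immune;Wound healing
8	8	7	PCDHGA11	0	ECM structural;Immune;Wound healing
8	8	7	PLA2R1	1	ECM structural;Immune;Wound healing
8	8	7	PROM1	0	ECM structural;Immune;Wound healing
8	8	7	THSD4	1	ECM structural;Immune;Wound healing
9	8	8	ADAM7	1	Growth factor;Immune;Skeletal
9	8	8	AREG	0	Growth factor;Immune;Skeletal
9	8	8	ATRN	1	Growth factor;Immune;Skeletal
9	8	8	CLDN2	1	Growth factor;Immune;Skeletal
9	8	8	FCGBP	0	Growth factor;Immune;Skeletal
9	8	8	IL1A	0	Growth factor;Immune;Skeletal
9	8	8	SEMA4A	1	Growth factor;Immune;Skeletal
9	8	8	SLC26A2	0	Growth factor;Immune;Skeletal
10	8	8	ADAM33	1	ECM structural;Immune;Ion channel;Mitochondria;Muscle
10	8	8	CHRNA3	0	ECM structural;Immune;Ion channel;Mitochondria;Muscle
10	8	8	COX7C	0	ECM structural;Immune;Ion channel;Mitochondria;Muscle
10	8	8	MMP8	1	ECM structural;Immune;Ion channel;Mitochondria;Muscle
10	8	8	MYH8	0	ECM structural;Immune;Ion channel;Mitochondria;Muscle
10	8	8	PCDHGB4	0	ECM structural;Immune;Ion channel;Mitochondria;Muscle
10	8	8	PTPRM	1	ECM structural;Immune;Ion channel;Mitochondria;Muscle
10	8	8	VWA3B	0	ECM structural;Immune;Ion channel;Mitochondria;Muscle
11	2	2	KCP	0	Cytoskeleton;TGF-beta/BMP
11	2	2	SPTBN4	0	Cytoskeleton;TGF-beta/BMP
12	6	6	CMYA5	0	ECM structural;Immune;Muscle
12	6	6	GSDMA	0	ECM structural;Immune;Muscle
12	6	6	HMCN1	0	ECM structural;Immune;Muscle
12	6	6	PTPRQ	1	ECM structural;Immune;Muscle
12	6	6	SIGIRR	0	ECM structural;Immune;Muscle
12	6	6	TCIRG1	0	ECM structural;Immune;Muscle
13	4	4	PDGFRL	0	ECM structural;Growth factor;Ion channel
13	4	4	PKHD1L1	0	ECM structural;Growth factor;Ion channel
13	4	4	SCN3A	0	ECM structural;Growth factor;Ion channel
13	4	4	USH2A	0	ECM structural;Growth factor;Ion channel
14	7	7	ADAMTS7P1	1	Cytokine;Cytoskeleton;Ion channel
14	7	7	KCNQ4	0	Cytokine;Cytoskeleton;Ion channel
14	7	7	MYL6	0	Cytokine;Cytoskeleton;Ion channel
14	7	7	OSMR	0	Cytokine;Cytoskeleton;Ion channel
14	7	7	TIMP1	1	Cytokine;Cytoskeleton;Ion channel
14	7	7	TUBA3C	0	Cytokine;Cytoskeleton;Ion channel
14	7	7	WIPF3	0	Cytokine;Cytoskeleton;Ion channel
15	6	6	ANGPT2	0	Cardiac;Collagen processing;Cytoskeleton;Vascular
15	6	6	ANK2	0	Cardiac;Collagen processing;Cytoskeleton;Vascular
15	6	6	COBLL1	0	Cardiac;Collagen processing;Cytoskeleton;Vascular
15	6	6	ITGA4	1	Cardiac;Collagen processing;Cytoskeleton;Vascular
15	6	6	PIEZO1	1	Cardiac;Collagen processing;Cytoskeleton;Vascular
15	6	6	POMGNT1	0	Cardiac;Collagen processing;Cytoskeleton;Vascular
16	3	3	COL28A1	0	Cytoskeleton;ECM structural
16	3	3	PLS1	0	Cytoskeleton;ECM structural
16	3	3	XIRP2	0	Cytoskeleton;ECM structural
17	4	3	COL11A2	0	Collagen processing;Ion channel
17	4	3	POMT1	0	Collagen processing;Ion channel
17	4	3	TRPV6	0	Collagen processing;Ion channel
18	7	5	CAPN9	1	Collagen processing;Growth factor;Immune;Ion channel
18	7	5	FCGBP	0	Collagen processing;Growth factor;Immune;Ion channel
18	7	5	GLRB	0	Collagen processing;Growth factor;Immune;Ion channel
18	7	5	IRS1	0	Collagen processing;Growth factor;Immune;Ion channel
18	7	5	SEC23A	0	Collagen processing;Growth factor;Immune;Ion channel
19	6	6	CDH26	1	Ca2+ signaling;Cytoskeleton;Skeletal;TGF-beta/BMP
19	6	6	ITPR2	0	Ca2+ signaling;Cytoskeleton;Skeletal;TGF-beta/BMP
19	6	6	PDLIM5	0	Ca2+ signaling;Cytoskeleton;Skeletal;TGF-beta/BMP
19	6	6	SLC35D1	0	Ca2+ signaling;Cytoskeleton;Skeletal;TGF-beta/BMP
19	6	6	SOX9	0	Ca2+ signaling;Cytoskeleton;Skeletal;TGF-beta/BMP
19	6	6	XIRP2	0	Ca2+ signaling;Cytoskeleton;Skeletal;TGF-beta/BMP
20	3	3	HMMR	1	ECM structural;Muscle
20	3	3	HSPG2	0	ECM structural;Muscle
20	3	3	TTN	0	ECM structural;Muscle
21	5	5	CDC42BPB	0	Cytoskeleton;Immune
21	5	5	MMP7	1	Cytoskeleton;Immune
21	5	5	PCDHB10	0	Cytoskeleton;Immune
21	5	5	STAB2	1	Cytoskeleton;Immune
21	5	5	TGM6	1	Cytoskeleton;Immune
22	2	2	MYOM2	0	Ion channel;Muscle
22	2	2	SCN9A	0	Ion channel;Muscle
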