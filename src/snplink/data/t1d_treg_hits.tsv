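# Worked-example annotation table: 36 fine-mapped type 1 diabetes variants
# prioritised by the four-criterion regulatory T cell cascade, with their
# nearest gene (linear distance), overlapping chromHMM state, FANTOM5
# enhancer support and 3D-interacting genes (via Treg Hi-C contacts).
# Positions are 1-based (hg38); gene symbols are kept verbatim as curated
# (the spelling variant RMB17/RBM17 is preserved; see the loader's synonym
# map). "." = none recorded.
chrom	pos	rsid	nearest_locus	chromhmm_state	fantom5	interacting_genes
chr2	204700689	rs12990970	CTLA4	TssAFlnk	no	CD28,CTLA4,ICOS
chr2	204732714	rs231775	CTLA4	TssAFlnk	no	RAPH1,CD28,ICOS
chr2	204738919	rs3087243	CTLA4	EnhG	no	RAPH1
chr3	46327588	rs11718385	CCR3	Enh	no	XCR1,CCR2,CCR5AS,CCR5
chr3	46391390	rs6441972	CCR2	TssAFlnk	no	CCR3
chr3	46401032	rs3138042	CCR2	Enh	no	.
chr3	46411661	rs2856758	CCR5	Enh	no	SLC6A20,FYCO1,CXCR6,XCR1,LOC105377067,CCR3,CCR1,CCR2
chr3	46412259	rs1799988	CCR5	TssAFlnk	no	SLC6A20,FYCO1,CXCR6,XCR1,LOC105377067,CCR3,CCR1,CCR2
chr5	35852311	rs6890853	IL7R	TssAFlnk	no	SPEF2,LOC105374724,CAPSL
chr6	90948476	rs62408222	BACH2	Enh	no	BACH2,LOC105377891
chr6	90983850	rs905671	BACH2	Enh	yes	BACH2
chr6	90984035	rs943689	BACH2	Enh	yes	BACH2
chr6	90995980	rs614120	BACH2	TssAFlnk	yes	BACH2,LOC105377891
chr7	50462418	rs10216316	IKZF1	EnhG	no	SPATA48
chr7	50462498	rs10215297	IKZF1	EnhG	no	SPATA48
chr7	50465206	rs55981617	IKZF1	EnhG	no	SPATA48,ZPBP,IKZF1
chr7	50465654	rs12670555	IKZF1	EnhG	no	SPATA48,ZPBP,IKZF1
chr10	6088743	rs12722508	IL2RA	TssAFlnk	no	RMB17
chr10	6094697	rs61839660	IL2RA	TssAFlnk	no	IL2RA,RMB17,PFKFB3,LINC02649
chr10	6096667	rs12722496	IL2RA	.	yes	IL2RA,RBM17,PFKFB3,LINC02649
chr10	6107534	rs11597367	IL2RA	Enh	no	IL2RA,RBM17
chr12	9910720	rs3176793	CD69	TssA	no	LOC374443,CLEC2D
chr12	9912182	rs2160086	CD69	TssA	no	LOC374443,CLEC2D
chr12	9912730	rs3176789	CD69	TssA	no	LOC374443,CLEC2D,LOC105369728
chr12	9916640	rs3136559	CD69	Enh	no	LOC374443,CLEC2D,LOC105369728
chr12	9925758	rs1029992	CD69	Enh	no	.
chr12	9926064	rs1029991	CD69	Enh	no	.
chr12	9926397	rs1029990	CD69	Enh	yes	.
chr12	9926624	rs10844749	CD69	Enh	no	.
chr12	9926784	rs1540356	CD69	Enh	no	.
chr15	38903672	rs16967112	RASGRP1	Enh	yes	FAM98B,RASGRP1,LOC105370775,LOC105370780,LINC02694,FSIP1
chr15	38903884	rs56249992	RASGRP1	Enh	no	RASGRP1,FAM98B,LOC105370775,LOC105370780,LINC02694,FSIP1
chr16	11188949	rs71136618	CLEC16A	Enh	no	CLEC16A,LOC107984859,LOC105371082,RMI2,SOCS1
chr17	38755665	rs11656173	SMARCE1	Enh	yes	CCR7
chr18	12838767	rs17657058	PTPN2	Enh	no	LINC01882,PTPN2,SEH1L
chr22	30581722	rs5753037	HORMAD2	Enh	no	HORMAD2,LIF-AS1,LIF
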