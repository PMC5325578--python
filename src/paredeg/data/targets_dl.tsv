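miRNA	Target	C.Site	Location	Score	Category	TP100M	P-Value
mno-miR156c	XM_010088675.1	943	CDS	1	2	4	0
mno-miR156d	XM_010090407.1	493	CDS	2	2	87	0.006
mno-miR156d	XM_010092101.1	158	CDS	4.5	2	3	0.006
mno-miR156d	XM_010092348.1	757	CDS	2	2	87	0.006
mno-miR156d	XM_010092557.1	198	CDS	4	2	5	0.006
mno-miR156d	XM_010099345.1	87	CDS	4.5	2	2	0.006
mno-miR156d	XM_010101121.1	278	CDS	4	2	4	0.006
mno-miR156d	XM_010104394.1	1171	CDS	1	2	52	0.006
mno-miR156d	XM_010114085.1	988	CDS	2	2	10	0.006
mno-miR156f	XM_010090407.1	492	CDS	1	2	7	0
mno-miR156f	XM_010092348.1	756	CDS	1	2	7	0
mno-miR156f	XM_010104394.1	1170	CDS	2	2	10	0.004
mno-miR156g	XM_010090407.1	492	CDS	0	2	7	0
mno-miR156g	XM_010092101.1	157	CDS	2.5	4	1	0.01
mno-miR156g	XM_010105976.1	1681	CDS	4.5	4	1	0.01
mno-miR156g	XM_010110753.1	129	CDS	4.5	4	1	0.01
mno-miR156g	XM_010111722.1	158	CDS	4	4	1	0.01
mno-miR160b	XM_010105965.1	1316	CDS	1	2	4	0
mno-miR166c	XM_010099828.1	561	CDS	1	2	2	0
mno-miR166f	XM_010099828.1	560	CDS	2	0	126	0
mno-miR166f	XM_010100268.1	590	CDS	2	0	25	0.002
mno-miR171a	XM_010090594.1	1283	CDS	0.5	2	6	0
mno-miR172c	XM_010093529.1	16	CDS	4	0	5	0.02
mno-miR172e	XM_010114499.1	593	CDS	4	0	5	0.018
mno-miR319c	XM_010093013.1	964	CDS	3	4	1	0.03
mno-miR319c	XM_010098565.1	37	CDS	4.5	4	1	0.03
mno-miR319c	XM_010109976.1	1086	CDS	3	0	183	0
mno-miR319c	XM_010114597.1	300	CDS	3	3	2	0.004
mno-miR396b	XM_010111150.1	1142	CDS	4	1	2	0.04
mno-miR399d	XM_010100088.1	326	CDS	2.5	3	3	0
mno-miR399e	XM_010100088.1	326	CDS	3.5	3	3	0.002
mno-miR399f	XM_010100088.1	326	CDS	3	3	3	0.004
mno-miR408c	XM_010095399.1	2180	CDS	4	1	6	0.01
mno-miR4376	XM_010106326.1	22	CDS	3	2	5	0.002
mno-miR535	XM_010104394.1	1169	CDS	3	2	3	0.048
mno-miR828	XM_010089439.1	653	CDS	3	4	1	0.026
mno-miRn11-3p	XM_010095698.1	1333	CDS	3	2	4	0.016
mno-miRn114-5p	XM_010112092.1	102	CDS	4	1	3	0.016
mno-miRn118-5p	XM_010101413.1	2530	CDS	3	2	2	0.006
mno-miRn120-3p	XM_010090594.1	1283	CDS	1	2	6	0
mno-miRn121-3-5p	XM_010105099.1	692	CDS	4.5	0	10	0.042
mno-miRn122-5p	XM_010093417.1	591	CDS	4	3	2	0.034
mno-miRn14-1-5p	XM_010097134.1	1342	CDS	4.5	0	7	0.028
mno-miRn144-5p	XM_010102397.1	573	CDS	4.5	2	2	0.006
mno-miRn150-3p	XM_010114658.1	421	CDS	3.5	3	3	0.002
mno-miRn157-5p	XM_010110553.1	2398	CDS	4	0	11	0.032
mno-miRn166-3p	XM_010102826.1	998	CDS	3.5	0	6	0.002
mno-miRn17-1-5p	XM_010097045.1	984	CDS	3	4	1	0.044
mno-miRn17-1-5p	XM_010100274.1	1122	CDS	4.5	4	1	0.044
mno-miRn17-1-5p	XM_010105164.1	337	CDS	4.5	4	1	0.044
mno-miRn179-5p	XM_010102516.1	328	CDS	4	3	2	0.042
mno-miRn193-5p	XM_010113910.1	612	CDS	3.5	0	5	0.004
mno-miRn202-1-3p	XM_010092821.1	863	CDS	4.5	1	4	0.034
mno-miRn202-1-3p	XM_010093270.1	1167	CDS	3.5	3	2	0.004
mno-miRn2-1-5p	XM_010095892.1	1059	CDS	4.5	0	24	0.03
mno-miRn220-5p	XM_010113440.1	797	CDS	4	4	1	0.034
mno-miRn238-5p	XM_010104930.1	493	CDS	4	0	15	0.046
mno-miRn25-1-3p	XM_010113161.1	77	CDS	4	0	5	0.03
mno-miRn260-5p	XM_010110513.1	1280	CDS	4.5	1	4	0.024
mno-miRn37-3p	XM_010114015.1	477	CDS	4	4	1	0.048
mno-miRn46-5p	XM_010093108.1	3876	CDS	4.5	0	19	0.014
mno-miRn62-1-5p	XM_010092824.1	18	CDS	4.5	1	4	0.026
mno-miRn79-1-3p	XM_010091565.1	275	CDS	4	0	7	0.016
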