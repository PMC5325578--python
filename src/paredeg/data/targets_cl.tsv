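miRNA	Target	C.Site	Location	Score	Category	TP100M	P-Value
mno-miR156c	XM_010104394.1	1171	CDS	1	2	62	0
mno-miR160b	XM_010091672.1	1277	CDS	1	4	1	0
mno-miR162	XM_010112984.1	363	CDS	4	3	4	0.016
mno-miR164a	XM_010095292.1	652	CDS	3	4	1	0.026
mno-miR164a	XM_010099082.1	847	CDS	4.5	4	1	0.026
mno-miR166f	XM_010099828.1	560	CDS	2	0	202	0
mno-miR166f	XM_010100268.1	590	CDS	2	0	42	0
mno-miR166f	XM_010104104.1	587	CDS	2	0	5	0
mno-miR171a	XM_010090594.1	1283	CDS	0.5	2	2	0
mno-miR171c	XM_010112515.1	1256	CDS	1	2	2	0
mno-miR171d	XM_010112515.1	1253	CDS	1	2	2	0
mno-miR171e	XM_010112515.1	1253	CDS	2.5	2	2	0.002
mno-miR171h	XM_010112515.1	1253	CDS	2.5	2	2	0.004
mno-miR319c	XM_010109976.1	1086	CDS	3	0	101	0
mno-miR396b	XM_010088522.1	353	CDS	2	4	1	0.012
mno-miR396b	XM_010088832.1	342	CDS	4.5	4	1	0.012
mno-miR396b	XM_010091229.1	2641	CDS	4.5	4	1	0.012
mno-miR396b	XM_010091257.1	1117	CDS	4.5	4	1	0.012
mno-miR396b	XM_010092942.1	480	CDS	3.5	4	1	0.012
mno-miR396b	XM_010094796.1	248	CDS	4.5	4	1	0.012
mno-miR396b	XM_010097895.1	612	CDS	4	4	1	0.012
mno-miR396b	XM_010098038.1	90	CDS	4.5	4	1	0.012
mno-miR396b	XM_010099023.1	2606	CDS	4	4	1	0.012
mno-miR396b	XM_010099938.1	738	CDS	4.5	4	1	0.012
mno-miR396b	XM_010103804.1	840	CDS	3.5	4	1	0.012
mno-miR396b	XM_010104482.1	4656	CDS	4.5	4	1	0.012
mno-miR396b	XM_010104690.1	654	CDS	3.5	4	1	0.012
mno-miR396b	XM_010104691.1	777	CDS	3.5	4	1	0.012
mno-miR396b	XM_010106362.1	630	CDS	4	4	1	0.012
mno-miR396b	XM_010111944.1	992	CDS	4	4	1	0.012
mno-miR408c	XM_010105580.1	16	CDS	2	2	132	0.006
mno-miR4376	XM_010106326.1	22	CDS	3	4	1	0.012
mno-miR535	XM_010104394.1	1169	CDS	3	2	4	0.032
mno-miRn119-5p	XM_010114494.1	1031	CDS	4.5	1	3	0.03
mno-miRn120-3p	XM_010090594.1	1283	CDS	1	2	2	0
mno-miRn144-5p	XM_010102397.1	573	CDS	4.5	4	1	0.01
mno-miRn149-1-3p	XM_010096635.1	486	CDS	4.5	1	2	0.008
mno-miRn160-5p	XM_010094916.1	82	CDS	4.5	3	2	0.044
mno-miRn168-3p	XM_010091818.1	2177	CDS	4.5	1	3	0.048
mno-miRn171-1-3p	XM_010100675.1	920	CDS	4.5	3	2	0.032
mno-miRn175-5p	XM_010097012.1	36	CDS	4	0	3	0.01
mno-miRn178-1-3p	XM_010096254.1	531	CDS	4	3	2	0.04
mno-miRn178-1-3p	XM_010107694.1	147	CDS	4	3	2	0.04
mno-miRn200-3p	XM_010099010.1	2223	CDS	4	2	2	0.046
mno-miRn204-3p	XM_010089422.1	1789	CDS	2.5	4	1	0.006
mno-miRn204-3p	XM_010093987.1	3046	CDS	2.5	4	1	0.006
mno-miRn204-3p	XM_010106433.1	1396	CDS	4.5	4	1	0.006
mno-miRn205-5p	XM_010092962.1	254	CDS	3	4	1	0.048
mno-miRn205-5p	XM_010097789.1	586	CDS	4.5	4	1	0.048
mno-miRn205-5p	XM_010108021.1	551	CDS	3.5	4	1	0.048
mno-miRn207-3p	XM_010102455.1	1333	CDS	4.5	3	2	0.022
mno-miRn208-3p	XM_010090819.1	1125	CDS	4	0	3	0.018
mno-miRn219-3p	XM_010114286.1	358	CDS	4	1	2	0.032
mno-miRn32-1-3p	XM_010099111.1	2815	CDS	4.5	1	3	0.03
mno-miRn33-1-5p	XM_010099185.1	1347	CDS	4.5	1	2	0.032
mno-miRn33-1-5p	XM_010107920.1	1435	CDS	3.5	1	2	0.032
mno-miRn48-5p	XM_010102625.1	38	CDS	3.5	2	2	0.04
mno-miRn55-1-5p	XM_010102455.1	1333	CDS	4.5	3	2	0.032
mno-miRn67-3p	XM_010095642.1	1140	CDS	2	4	1	0.008
mno-miRn67-3p	XM_010099023.1	1649	CDS	4	4	1	0.008
mno-miRn67-3p	XM_010100444.1	34	CDS	4	4	1	0.008
mno-miRn67-3p	XM_010103502.1	405	CDS	4	4	1	0.008
mno-miRn67-3p	XM_010106088.1	2600	CDS	4	4	1	0.008
mno-miRn67-3p	XM_010108206.1	1549	CDS	4	4	1	0.008
mno-miRn69-3p	XM_010101296.1	870	CDS	4.5	1	3	0.024
mno-miRn70-1-5p	XM_010101296.1	870	CDS	3.5	1	4	0.002
mno-miRn74a-1-3p	XM_010090508.1	315	CDS	3.5	1	4	0.002
mno-miRn74b-3p	XM_010090508.1	315	CDS	4.5	1	4	0.028
mno-miRn81-3p	XM_010106888.1	853	CDS	3	4	1	0.02
mno-miRn99-3p	XM_010107049.1	24	CDS	3.5	2	5	0.046
mno-miRn99-3p	XM_010107437.1	74	CDS	4.5	2	10	0.046
mno-miRn99-3p	XM_010107438.1	74	CDS	4.5	2	10	0.046
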