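genome	orfs	genome_size_bp	gc_percent	unique_genes
APC1461	1987	2418994	60.0	60
APC1462	1992	2417784	60.2	4
APC1464	1918	2346522	60.0	3
APC1465	2032	2452211	59.6	6
APC1466	2026	2419982	59.8	0
APC1468	1994	2395158	60.1	12
APC1472	1927	2364041	60.1	3
APC1473	1874	2317071	59.8	6
APC1476	2151	2532540	60.0	1
APC1477	1761	2228807	59.8	0
APC1478	1766	2223352	59.8	1
APC1480	2084	2477750	59.9	6
APC1482	1899	2337438	60.1	17
APC1503	2189	2562703	59.7	23
APC1504	1883	2310288	60.2	14
DPC6316	1992	2393969	60.4	23
DPC6317	1987	2448630	60.2	8
DPC6320	1852	2330371	59.9	9
DPC6321	1941	2382360	59.9	24
DPC6323	1970	2396960	60.2	7
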