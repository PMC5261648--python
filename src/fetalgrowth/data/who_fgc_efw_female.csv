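# parameter=efw,unit=g,stratum=female,provenance=bundled-WHO
week,p5,p10,p25,p50,p75,p90,p95
14,73,77,82,89,96,102,107
15,92,97,104,113,121,129,135
16,116,122,131,141,152,162,170
17,145,152,164,176,189,202,211
18,180,188,202,217,233,248,261
19,221,231,248,266,285,304,319
20,269,281,302,322,346,369,387
21,324,339,364,388,417,444,466
22,388,405,435,464,499,530,557
23,461,481,516,551,592,629,660
24,542,567,608,649,697,740,776
25,634,663,710,758,815,865,907
26,735,769,823,880,946,1003,1051
27,846,886,948,1014,1090,1156,1210
28,967,1013,1083,1160,1247,1323,1383
29,1096,1150,1230,1319,1418,1505,1570
30,1234,1296,1386,1489,1601,1699,1770
31,1379,1451,1553,1670,1796,1907,1984
32,1530,1614,1728,1861,2002,2127,2209
33,1687,1783,1911,2060,2217,2358,2445
34,1847,1957,2101,2268,2440,2598,2690
35,2008,2135,2296,2481,2669,2846,2943
36,2169,2314,2494,2698,2902,3099,3201
37,2329,2493,2695,2917,3138,3357,3462
38,2484,2670,2896,3136,3373,3616,3725
39,2633,2843,3096,3354,3605,3875,3988
40,2775,3010,3294,3567,3832,4131,4247
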