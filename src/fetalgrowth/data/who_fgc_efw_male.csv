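# parameter=efw,unit=g,stratum=male,provenance=bundled-WHO
week,p5,p10,p25,p50,p75,p90,p95
14,75,79,84,92,99,105,109
15,96,100,107,116,126,134,139
16,121,127,136,146,158,169,175
17,152,158,170,183,197,210,219
18,188,196,210,226,243,260,271
19,232,241,258,277,298,320,333
20,282,293,314,337,362,389,405
21,341,354,380,407,436,469,489
22,408,424,454,487,522,561,586
23,484,503,539,578,619,666,695
24,570,592,635,681,730,785,818
25,666,692,742,795,853,917,956
26,772,803,860,923,990,1063,1109
27,888,924,989,1063,1141,1224,1276
28,1014,1055,1129,1215,1305,1399,1458
29,1149,1197,1281,1379,1482,1587,1654
30,1293,1349,1442,1555,1672,1788,1863
31,1445,1509,1613,1741,1874,2000,2085
32,1605,1677,1793,1937,2085,2224,2319
33,1770,1852,1980,2140,2306,2456,2562
34,1941,2032,2174,2350,2534,2694,2814
35,2114,2217,2372,2565,2767,2938,3072
36,2290,2404,2574,2783,3002,3185,3334
37,2466,2591,2777,3001,3238,3432,3598
38,2641,2778,2981,3218,3472,3676,3863
39,2813,2962,3183,3432,3701,3916,4125
40,2981,3142,3382,3639,3923,4149,4383
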