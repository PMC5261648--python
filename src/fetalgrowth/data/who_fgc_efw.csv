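# parameter=efw,unit=g,stratum=,provenance=bundled-WHO
week,p2.5,p5,p10,p25,p50,p75,p90,p95,p97.5
14,70,73,78,83,90,98,104,109,113
15,89,93,99,106,114,124,132,138,144
16,113,117,124,133,144,155,166,174,181
17,141,146,155,166,179,193,207,217,225
18,174,181,192,206,222,239,255,268,278
19,214,223,235,252,272,292,313,328,340
20,260,271,286,307,330,355,380,399,413
21,314,327,345,370,398,428,458,481,497
22,375,392,412,443,476,512,548,575,595
23,445,465,489,525,565,608,650,682,705
24,523,548,576,618,665,715,765,803,830
25,611,641,673,723,778,836,894,938,970
26,707,743,780,838,902,971,1038,1087,1125
27,813,855,898,964,1039,1118,1196,1251,1295
28,929,977,1026,1102,1189,1279,1368,1429,1481
29,1053,1108,1165,1251,1350,1453,1554,1622,1682
30,1185,1247,1313,1410,1523,1640,1753,1828,1897
31,1326,1394,1470,1579,1707,1838,1964,2046,2126
32,1473,1548,1635,1757,1901,2047,2187,2276,2367
33,1626,1708,1807,1942,2103,2266,2419,2516,2619
34,1785,1872,1985,2134,2312,2492,2659,2764,2880
35,1948,2038,2167,2330,2527,2723,2904,3018,3148
36,2113,2205,2352,2531,2745,2959,3153,3277,3422
37,2280,2372,2537,2733,2966,3195,3403,3538,3697
38,2446,2536,2723,2935,3186,3432,3652,3799,3973
39,2612,2696,2905,3135,3403,3664,3897,4058,4247
40,2775,2849,3084,3333,3617,3892,4135,4312,4515
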