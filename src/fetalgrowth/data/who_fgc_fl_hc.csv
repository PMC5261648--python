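# parameter=fl_hc,unit=,stratum=,provenance=bundled-WHO
week,p2.5,p5,p10,p25,p50,p75,p90,p95,p97.5
14,0.50,0.52,0.53,0.54,0.56,0.57,0.59,0.59,0.60
15,0.54,0.55,0.56,0.57,0.59,0.60,0.61,0.62,0.62
16,0.57,0.58,0.59,0.60,0.61,0.62,0.63,0.64,0.64
17,0.60,0.60,0.61,0.62,0.63,0.64,0.65,0.65,0.66
18,0.62,0.62,0.63,0.64,0.65,0.66,0.66,0.67,0.67
19,0.64,0.64,0.65,0.65,0.66,0.67,0.68,0.68,0.68
20,0.65,0.66,0.66,0.67,0.67,0.68,0.69,0.69,0.69
21,0.66,0.67,0.67,0.68,0.68,0.69,0.69,0.70,0.70
22,0.67,0.67,0.68,0.68,0.69,0.69,0.70,0.70,0.71
23,0.68,0.68,0.68,0.69,0.69,0.70,0.70,0.71,0.71
24,0.68,0.69,0.69,0.69,0.70,0.70,0.71,0.71,0.71
25,0.69,0.69,0.69,0.70,0.70,0.71,0.71,0.71,0.72
26,0.69,0.69,0.69,0.70,0.70,0.71,0.71,0.72,0.72
27,0.69,0.69,0.70,0.70,0.71,0.71,0.72,0.72,0.72
28,0.69,0.70,0.70,0.70,0.71,0.71,0.72,0.72,0.72
29,0.70,0.70,0.70,0.71,0.71,0.72,0.72,0.72,0.73
30,0.70,0.70,0.70,0.71,0.71,0.72,0.72,0.73,0.73
31,0.70,0.70,0.71,0.71,0.72,0.72,0.73,0.73,0.73
32,0.70,0.71,0.71,0.72,0.72,0.73,0.73,0.73,0.74
33,0.71,0.71,0.71,0.72,0.72,0.73,0.73,0.74,0.74
34,0.71,0.71,0.72,0.72,0.73,0.73,0.74,0.74,0.74
35,0.71,0.72,0.72,0.73,0.73,0.74,0.74,0.74,0.75
36,0.72,0.72,0.72,0.73,0.73,0.74,0.74,0.75,0.75
37,0.72,0.72,0.73,0.73,0.74,0.74,0.74,0.75,0.75
38,0.72,0.72,0.73,0.73,0.74,0.74,0.75,0.75,0.75
39,0.72,0.72,0.73,0.73,0.74,0.74,0.75,0.75,0.75
40,0.71,0.72,0.72,0.73,0.73,0.74,0.75,0.75,0.75
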