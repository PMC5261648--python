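# parameter=fl_bpd,unit=,stratum=,provenance=bundled-WHO
week,p2.5,p5,p10,p25,p50,p75,p90,p95,p97.5
14,0.71,0.72,0.74,0.76,0.78,0.80,0.82,0.83,0.84
15,0.75,0.76,0.77,0.79,0.81,0.83,0.84,0.85,0.86
16,0.79,0.80,0.81,0.82,0.84,0.85,0.87,0.88,0.88
17,0.82,0.82,0.83,0.85,0.86,0.87,0.89,0.89,0.90
18,0.84,0.85,0.85,0.87,0.88,0.89,0.90,0.91,0.91
19,0.86,0.86,0.87,0.88,0.89,0.90,0.91,0.92,0.92
20,0.87,0.88,0.88,0.89,0.90,0.91,0.92,0.93,0.93
21,0.88,0.89,0.89,0.90,0.91,0.92,0.93,0.93,0.94
22,0.89,0.89,0.90,0.91,0.92,0.92,0.93,0.94,0.94
23,0.89,0.90,0.90,0.91,0.92,0.93,0.94,0.94,0.95
24,0.90,0.90,0.91,0.91,0.92,0.93,0.94,0.94,0.95
25,0.90,0.90,0.91,0.92,0.92,0.93,0.94,0.94,0.95
26,0.90,0.91,0.91,0.92,0.93,0.93,0.94,0.95,0.95
27,0.90,0.91,0.91,0.92,0.93,0.93,0.94,0.95,0.95
28,0.90,0.91,0.91,0.92,0.93,0.94,0.94,0.95,0.95
29,0.90,0.91,0.91,0.92,0.93,0.94,0.94,0.95,0.95
30,0.91,0.91,0.91,0.92,0.93,0.94,0.94,0.95,0.95
31,0.91,0.91,0.92,0.92,0.93,0.94,0.95,0.95,0.95
32,0.91,0.91,0.92,0.93,0.93,0.94,0.95,0.95,0.96
33,0.91,0.92,0.92,0.93,0.94,0.94,0.95,0.96,0.96
34,0.92,0.92,0.92,0.93,0.94,0.95,0.95,0.96,0.96
35,0.92,0.92,0.93,0.93,0.94,0.95,0.95,0.96,0.96
36,0.92,0.93,0.93,0.94,0.94,0.95,0.96,0.96,0.97
37,0.92,0.93,0.93,0.94,0.94,0.95,0.96,0.96,0.97
38,0.92,0.93,0.93,0.94,0.95,0.95,0.96,0.96,0.97
39,0.92,0.92,0.93,0.94,0.94,0.95,0.96,0.96,0.97
40,0.91,0.92,0.92,0.93,0.94,0.95,0.96,0.96,0.97
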