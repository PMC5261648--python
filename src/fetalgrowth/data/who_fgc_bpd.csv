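# parameter=bpd,unit=mm,stratum=,provenance=bundled-WHO
week,p2.5,p5,p10,p25,p50,p75,p90,p95,p97.5
14,23,24,24,26,27,28,29,30,31
15,26,27,27,29,30,31,32,33,34
16,29,30,30,32,33,35,36,37,38
17,32,33,33,35,36,38,39,40,41
18,35,36,37,38,40,41,43,44,45
19,38,39,40,42,43,45,46,47,48
20,41,42,43,45,47,48,50,51,52
21,44,45,46,48,50,52,53,54,55
22,47,48,50,51,53,55,57,58,59
23,50,52,53,55,57,59,60,61,62
24,53,55,56,58,60,62,64,65,66
25,56,58,59,61,63,65,67,68,69
26,59,60,62,64,66,68,70,71,72
27,62,63,65,67,69,71,73,74,75
28,64,66,67,69,72,74,76,77,78
29,67,68,70,72,74,76,78,80,81
30,69,71,72,74,77,79,81,82,83
31,71,73,74,76,79,81,83,85,86
32,73,75,76,79,81,83,86,87,88
33,75,77,78,81,83,86,88,89,90
34,77,79,80,83,85,88,90,91,92
35,79,80,82,84,87,89,92,93,94
36,80,82,84,86,89,91,93,95,96
37,82,84,85,88,90,93,95,96,97
38,84,85,87,90,92,95,97,98,99
39,85,87,89,92,94,96,99,100,101
40,87,88,90,93,96,98,100,101,102
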