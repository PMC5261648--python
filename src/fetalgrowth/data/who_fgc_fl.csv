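# parameter=fl,unit=mm,stratum=,provenance=bundled-WHO
week,p2.5,p5,p10,p25,p50,p75,p90,p95,p97.5
14,10,10,11,12,13,14,15,16,17
15,12,13,14,15,16,17,18,19,20
16,15,16,17,18,19,20,22,22,23
17,19,19,20,21,22,24,25,26,26
18,22,22,23,24,26,27,28,29,30
19,25,26,26,28,29,30,31,32,33
20,28,29,30,31,32,33,35,35,36
21,31,32,33,34,35,36,38,38,39
22,34,35,35,37,38,39,40,41,42
23,36,37,38,39,41,42,43,44,45
24,39,40,41,42,43,45,46,47,47
25,41,42,43,44,46,47,48,49,50
26,43,44,45,46,48,49,51,51,52
27,46,46,47,49,50,52,53,54,55
28,48,48,49,51,52,54,55,56,57
29,50,50,51,53,54,56,57,58,59
30,51,52,53,55,56,58,60,60,61
31,53,54,55,57,59,60,62,63,64
32,55,56,57,59,61,62,64,65,66
33,57,58,60,61,63,65,66,67,68
34,59,60,61,63,65,67,68,69,70
35,61,62,63,65,67,69,70,71,73
36,63,64,65,67,69,70,72,73,75
37,65,66,67,68,70,72,74,75,76
38,66,67,68,70,72,74,75,77,78
39,67,68,69,70,73,75,76,78,79
40,68,68,69,70,73,75,77,78,79
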