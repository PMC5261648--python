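# parameter=hl,unit=mm,stratum=,provenance=bundled-WHO
week,p2.5,p5,p10,p25,p50,p75,p90,p95,p97.5
14,10,11,11,12,14,15,16,16,17
15,13,13,14,15,16,18,19,19,20
16,16,16,17,18,19,21,22,22,23
17,19,19,20,21,23,24,25,25,26
18,22,22,23,24,26,27,28,28,29
19,25,25,26,27,28,30,31,31,32
20,27,28,29,30,31,32,33,34,35
21,30,31,31,33,34,35,36,37,38
22,32,33,34,35,36,37,39,39,40
23,34,35,36,37,38,40,41,42,42
24,36,37,38,39,41,42,43,44,45
25,38,39,40,41,42,44,45,46,47
26,40,41,42,43,44,46,47,48,49
27,42,43,43,45,46,47,49,50,51
28,43,44,45,46,48,49,51,52,52
29,45,46,47,48,49,51,52,53,54
30,46,47,48,50,51,53,54,55,56
31,48,49,50,51,53,54,56,57,58
32,49,50,51,53,54,56,57,59,59
33,51,52,53,54,56,58,59,60,61
34,53,53,54,56,58,59,61,62,63
35,54,55,56,57,59,61,62,63,64
36,55,56,57,59,61,62,64,65,66
37,56,57,58,60,62,64,65,66,67
38,57,58,59,61,63,65,66,67,68
39,58,59,60,62,64,65,67,68,69
40,57,58,60,62,64,66,68,69,69
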