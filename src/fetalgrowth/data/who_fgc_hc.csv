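# parameter=hc,unit=mm,stratum=,provenance=bundled-WHO
week,p2.5,p5,p10,p25,p50,p75,p90,p95,p97.5
14,86,88,91,95,100,104,107,110,112
15,97,99,102,106,111,115,119,122,124
16,108,111,114,118,123,128,132,134,137
17,120,123,126,130,135,140,144,147,149
18,132,135,138,143,148,153,157,160,162
19,145,147,150,155,161,166,170,173,175
20,157,159,163,168,173,179,183,186,188
21,169,172,175,180,186,191,196,199,201
22,181,184,187,193,198,204,209,212,214
23,193,196,199,205,210,216,221,224,227
24,204,207,211,216,222,228,233,236,239
25,215,218,222,227,233,239,245,248,251
26,225,228,232,238,244,250,256,259,262
27,234,238,242,248,254,261,267,270,273
28,243,247,251,257,264,270,277,280,283
29,251,256,260,266,273,280,286,290,293
30,259,264,268,274,281,288,295,299,302
31,266,271,275,282,289,296,303,307,311
32,273,278,282,289,296,304,311,315,318
33,279,284,289,295,303,311,318,322,326
34,285,290,295,302,309,317,324,328,332
35,291,296,300,307,315,323,330,335,338
36,296,301,306,313,321,329,336,340,344
37,302,306,311,318,326,334,341,345,349
38,307,311,315,324,332,339,347,350,354
39,313,316,320,329,337,344,352,355,359
40,319,321,325,334,342,350,357,360,363
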