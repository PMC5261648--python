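# parameter=ac,unit=mm,stratum=,provenance=bundled-WHO
week,p2.5,p5,p10,p25,p50,p75,p90,p95,p97.5
14,69,71,73,77,81,86,89,92,95
15,79,81,83,87,92,96,100,103,106
16,89,91,93,98,103,108,112,115,118
17,99,102,104,109,114,119,124,127,130
18,110,113,116,121,126,131,136,139,142
19,121,124,127,132,138,143,148,152,155
20,132,136,139,144,150,155,161,164,167
21,143,147,150,156,162,168,173,177,180
22,154,159,162,167,173,180,186,189,193
23,165,170,173,179,185,192,198,202,205
24,176,181,184,190,197,203,210,214,217
25,186,191,195,201,208,215,222,226,229
26,196,201,205,212,219,226,233,238,241
27,206,211,215,222,230,237,245,249,253
28,215,220,225,232,240,248,256,260,264
29,224,229,234,242,250,258,266,271,276
30,233,238,243,251,260,269,277,282,287
31,241,246,252,260,269,279,287,292,298
32,249,254,260,269,279,288,298,303,308
33,257,262,269,278,288,298,308,313,319
34,265,270,277,287,298,308,318,324,330
35,273,279,286,297,307,318,329,335,342
36,282,287,294,306,317,329,340,346,353
37,290,296,304,316,328,340,352,358,365
38,299,306,313,326,338,351,364,371,378
39,309,316,324,337,350,363,377,384,392
40,319,327,335,349,363,377,391,399,406
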