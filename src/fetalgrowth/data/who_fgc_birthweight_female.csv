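# parameter=birthweight,unit=g,stratum=female,provenance=bundled-WHO
week,p5,p25,p50,p75,p90,p95
37,1968,2493,2786,2951,3181,3238
38,2315,2698,2990,3217,3451,3593
39,2575,2891,3173,3443,3682,3867
40,2748,3072,3336,3631,3871,4060
41,2835,3241,3479,3779,4021,4171
42,2834,3398,3601,3888,4130,4200
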