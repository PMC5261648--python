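# parameter=birthweight,unit=g,stratum=male,provenance=bundled-WHO
week,p5,p25,p50,p75,p90,p95
37,2062,2705,2919,3143,3450,3584
38,2451,2890,3153,3387,3666,3813
39,2723,3061,3354,3608,3871,4036
40,2880,3218,3519,3806,4067,4251
41,2921,3362,3650,3982,4253,4459
42,2845,3491,3747,4134,4428,4659
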