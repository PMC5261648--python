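6325cf11d435ea7ed8083f407ed88c341fcd14464aed39cbda5d080ae462526f  study_outcomes.csv
8277bfec77d53b41b98d20a84b8b02c143239996779413dfff45ef106b68bdb3  study_recruitment.csv
932aba48a5a2827124f5280bd0bc94e70497e203bbf964a7fcc4230f1e2102fe  who_fgc_ac.csv
1fb401aebee9c5a2cbab84b0e23876bbc4119bbc0cd241652d338d02019e1d1d  who_fgc_birthweight_female.csv
201415ac5a95c7a7b136ffd43f03b6f5b625feeb1781fa266be579cc21050cd3  who_fgc_birthweight_male.csv
e99913a1dad3ef7c82b3e4dd05c05d6037390a0d90a7f0342e45e0fbe6bf4cb7  who_fgc_bpd.csv
b8eee930b2027f011d240f1776e62168ac00b498309f3c54a68cd91180c686f7  who_fgc_efw.csv
0542c61c187d5f6885ae95a1c78207d540ab359a5e8ecf144785af09cebd2452  who_fgc_efw_female.csv
66d64e1f40e2f16468b761a7ed66a3b41384ddc1be0037043300df0c90e89a73  who_fgc_efw_male.csv
9eb20bbc618a13debf99842875d2e8e2691c23c1b3a4e1427650db6e205ce329  who_fgc_fl.csv
611bbeeb2f508ef8c7caa6aceee5488a9e505d290bf082ab34246067f2eb8411  who_fgc_fl_bpd.csv
31f85d686b4f64fc38e8cc0581408f224c9329f5783a37b18fe0303fe3d2a246  who_fgc_fl_hc.csv
12d8b97bb1e3a2429d4527ef26709d9349c391adafecc880cea9ee8bac810a5f  who_fgc_hc.csv
8910cd497a7c9af8642ed081dce7a2d54208c64e3d570bb157c344007a5089d8  who_fgc_hl.csv
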