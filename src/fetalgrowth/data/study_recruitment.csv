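country,recruited,consent_withdrawal,lost_to_followup,miscarriage_iud
Argentina,143,0,2,1
Brazil,157,4,2,3
D. R. Congo,157,15,6,10
Denmark,142,2,3,1
Egypt,180,25,11,9
France,109,1,9,2
Germany,141,0,2,0
India,146,0,7,3
Norway,140,2,1,1
Thailand,124,3,3,4
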