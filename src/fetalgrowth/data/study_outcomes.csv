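country,preterm_n,preterm_total
Argentina,12,140
Brazil,11,148
D. R. Congo,6,127
Denmark,8,137
Egypt,20,136
France,7,97
Germany,5,139
India,15,138
Norway,6,136
Thailand,9,114
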