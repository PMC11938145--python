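scenario,pr_straw,pr_biochar,pr_ele,pr_sell
Sw1,0.25,0.25,0.25,0.25
Sw2,0.55,0.20,0.15,0.10
Sw3,0.05,0.60,0.20,0.15
Sw4,0.14,0.06,0.50,0.30
Sw5,0.26,0.20,0.14,0.40
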