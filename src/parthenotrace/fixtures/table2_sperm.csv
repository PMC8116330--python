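component,mean_um,se_um
total,178.3,0.8
head,57.7,0.2
midpiece,19.9,0.2
flagellum,100.7,0.6
acrosome,3.0,0.1
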