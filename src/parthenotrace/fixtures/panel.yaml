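loci:
  - Cp1
  - Cpl80
  - Cpl150
  - Cpl471
  - Cpl930
  - Cpl1163
  - Cpl962
  - Cpl1161
  - Cpl1141
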