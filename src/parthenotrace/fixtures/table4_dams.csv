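individual_id,Cp1,Cpl80,Cpl150,Cpl471,Cpl930,Cpl1163,Cpl962,Cpl1161,Cpl1141
854,315/315,266/286,194/194,226/228,176/178,193/193,304/368,198/200,186/194
307,315/315,274/274,194/194,226/228,182/182,193/201,360/364,200/208,186/194
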