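individual_id,Cp1,Cpl80,Cpl150,Cpl471,Cpl930,Cpl1163,Cpl962,Cpl1161,Cpl1141
Female 1,289/315,266/282,200/202,226/228,178/182,201/-,356/-,194/210,186/194
Female 2,289/-,274/294,194/202,228/-,176/182,193/-,368/-,200/210,194/-
Female 3,289/289,266/282,194/-,228/-,176/182,201/-,364/-,198/210,186/194
Female 4,315/-,266/-,194/-,226/-,178/-,193/-,368/-,200/-,194/-
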