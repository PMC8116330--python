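individual_id,Cp1,Cpl80,Cpl150,Cpl471,Cpl930,Cpl1163,Cpl962,Cpl1161,Cpl1141
P1,315/315,266/266,202/202,226/226,182/182,201/201,356/356,194/194,194/194
P2,289/289,282/282,200/200,226/226,178/178,201/201,356/356,210/210,186/186
P3,289/289,266/266,202/202,228/228,182/182,201/201,356/356,194/194,194/194
P4,315/315,266/266,202/202,226/226,178/178,201/201,356/356,210/210,194/194
P5,289/289,294/294,194/194,228/228,182/182,193/193,368/368,210/210,194/194
P6,289/289,274/274,202/202,228/228,176/176,193/193,368/368,210/210,194/194
P7,289/289,294/294,202/202,228/228,182/182,193/193,368/368,200/200,194/194
P8,-/-,294/294,-/-,-/-,-/-,193/193,356/356,200/200,194/194
P9,289/289,282/282,194/194,228/228,182/182,201/201,-/-,210/210,186/186
P10,289/289,266/266,194/194,228/228,176/176,201/201,364/364,198/198,194/194
P11,289/289,266/266,194/194,228/228,182/182,201/201,364/364,210/210,194/194
P12,315/315,266/266,194/194,226/226,178/178,193/193,368/368,200/200,194/194
AI-P1,315/315,286/286,194/194,226/226,176/176,193/193,304/304,198/198,186/186
AI-P2,315/315,274/274,194/194,226/226,182/182,201/201,360/360,208/208,194/194
AI-P3,315/315,274/274,194/194,228/228,182/182,193/193,364/364,200/200,186/186
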