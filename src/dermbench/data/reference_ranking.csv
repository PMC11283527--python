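id,PS,rank
A2,0.943135,1
A10,0.914284,2
A1,0.911944,3
A9,0.909893,4
A35,0.907412,5
A4,0.907079,6
A6,0.893249,7
A5,0.893027,8
A43,0.886682,9
A12,0.885985,10
A3,0.881655,11
A11,0.86874,12
A8,0.867611,13
A7,0.854574,14
A42,0.81751,15
A50,0.809088,16
A51,0.804455,17
A48,0.803863,18
A49,0.801991,19
A41,0.79677,20
A23,0.788236,21
A44,0.78679,22
A40,0.784624,23
A22,0.784136,24
A21,0.782796,25
A47,0.777952,26
A46,0.777777,27
A24,0.770182,28
A45,0.758805,29
A13,0.756305,30
A16,0.751902,31
A14,0.751277,32
A15,0.73575,33
A18,0.731325,34
A17,0.715933,35
A19,0.708347,36
A26,0.645514,37
A28,0.640933,38
A36,0.640323,39
A25,0.63993,40
A38,0.637589,41
A27,0.637512,42
A37,0.63563,43
A33,0.614532,44
A30,0.607877,45
A32,0.607588,46
A31,0.603945,47
A20,0.603502,48
A29,0.598146,49
A39,0.564224,50
A34,0.45154,51
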