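quantity,ACC,SV,SP,PR,ER,FPR,FNR,NPV,F1S
c,1.321,1.427,1.349,1.203,2.672,2.719,2.901,1.579,1.512
weight,0.079,0.086,0.081,0.072,0.160,0.163,0.174,0.095,0.091
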