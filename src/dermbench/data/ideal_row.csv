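ACC,SV,SP,PR,ER,FPR,FNR,NPV,F1S
0.945,0.899,0.962,0.908,0.038,0.038,0.100,0.883,0.903
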