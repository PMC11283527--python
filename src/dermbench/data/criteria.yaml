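# Benefit/cost orientation of the nine evaluation metrics as used in the
# published benchmark.  NPV is treated as a cost criterion there; flip to
# benefit for the conventional orientation.
criteria:
  - {name: ACC, direction: benefit}
  - {name: SV, direction: benefit}
  - {name: SP, direction: benefit}
  - {name: PR, direction: benefit}
  - {name: ER, direction: cost}
  - {name: FPR, direction: cost}
  - {name: FNR, direction: cost}
  - {name: NPV, direction: cost}
  - {name: F1S, direction: benefit}
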