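# Control condition: heterogeneous network, default recall protocol.
condition:
  name: control
seed: 0
dt: 0.1
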