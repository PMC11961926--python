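# Chronic restraint stress: 16% loss of excitatory dendritic spines, which
# downscales every excitatory-neuron effective synapse count by 0.84.
condition:
  name: chronic
  fac: 0.16
seed: 0
dt: 0.1
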