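# Acute forced-swim stress: recurrent NMDA and AMPA currents scaled by the
# ratio of stressed to control EPSC amplitudes (425/197 and 98.8/58.6 pA).
condition:
  name: acute_swim
  scaling:
    beta_NMDA: 2.1573604060913705
    beta_AMPA: 1.686006825938567
seed: 0
dt: 0.1
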