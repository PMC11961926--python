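# Chronic stress with enhanced within-group E-E connectivity: the spine-loss
# condition compensated by stronger same-selectivity excitatory coupling.
# Tuned so that, with symmetric stimulation of all four groups, competition
# through cross-group inhibition typically leaves two groups sustaining
# delay-period firing (capacity 2 of a structural maximum of 4).
condition:
  name: chronic
  fac: 0.16
  scaling:
    ee_scale: 1.1
seed: 0
dt: 0.1
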