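can:
  g_can_2mv: 0.00032804687499999994
  g_can_4mv: 0.0006284759521484374
  g_can_default: 0.0006284759521484374
  g_can_max: 0.000883717112076465
  rate_scale: 36.7529296875
densities:
  cal:
    apical: 1.0e-05
    basal: 1.0e-05
    soma: 1.0e-05
  can:
    soma: 1.0
  can_ca:
    apical: 1.0e-05
    basal: 1.0e-05
    soma: 3.0e-05
  car:
    apical: 3.0e-05
    basal: 3.0e-05
    soma: 0.0008
  cat:
    apical: 1.0e-05
    basal: 1.0e-05
    soma: 1.0e-05
  fahp:
    apical: 0.001
    basal: 0.001
    soma: 0.008
  h:
    apical: 1.0e-05
    basal: 5.0e-06
    soma: 5.0e-06
  ka:
    apical: 0.03
    basal: 0.03
    soma: 0.025
  kd:
    soma: 0.0005
  kdr:
    apical: 0.01
    axon: 0.25
    basal: 0.01
    soma: 0.2
  naf:
    apical: 0.03
    axon: 0.3
    basal: 0.03
    soma: 0.12
  nap:
    apical: 5.0e-05
    basal: 5.0e-05
    soma: 0.00015
  sahp:
    apical: 2.0e-05
    basal: 2.0e-05
    soma: 0.0003
noise:
  amp_pa: 119.5625
  enabled: false
  rate_hz: 50.0
  width_ms: 2.0
passive:
  e_leak: -65.859375
  rm: 47.515625
pool: {}
syn:
  g_ampa: 0.583203125
  nmda_gain: 0.4976135253906251
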