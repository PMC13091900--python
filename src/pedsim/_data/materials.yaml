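# Default material registry for the foot model (units: MPa, g/mm^3, ms).
bone:
  E: 7300.0
  nu: 0.30
  density: 0.0015
soft_tissue_ogden:
  C: 0.0102
  alpha: 8.04
  nu: 0.475
  density: 0.000937
soft_tissue_prony:
  g1: 0.18
  g2: 0.12
  tau1: 570.0
  tau2: 6030.0
skin:
  C: 0.122
  alpha: 18.0
  nu: 0.475
  density: 0.000937
cartilage:
  E: 10.0
  nu: 0.40
  density: 0.002
ligament:
  E: 260.0
  nu: 0.40
  density: 0.001
plantar_aponeurosis:
  E: 412.02
  nu: 0.40
  density: 0.001
skin_thickness: 1.0
floor_friction_mu: 0.6
prony_on_full_stress: true
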