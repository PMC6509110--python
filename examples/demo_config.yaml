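# Demo: simulate a small filament acquisition, localize, deskew, render, FRC.
simulate:
  enabled: true
  kind: filament
  structure_params:
    polylines:
      - [[500, 500, 250], [5500, 5500, 450]]
      - [[800, 4500, 150], [5200, 1200, 350]]
    density_per_um: 80.0
  n_volumes: 10
blinking:
  k_on: 1.0
  k_off: 50.0
geometry:
  n_planes: 8
  img_shape: [64, 64]
drift:
  method: ""
npc:
  enabled: false
seeds:
  simulate: 1
  frc: 1
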