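# 1-D tissue-colonization simulation: a dense G0/G1 block (4800 cells/mm^2,
# x < 850 um) released on a 3000 um domain with no-flux walls, run at the
# calibrated posterior-mode parameters.
seed: 0
model:
  D: 1300.0      # um^2/h
  k1: 0.612      # 1/h
  k2: 0.457      # 1/h
  K1: 4965.0     # cells/mm^2
  K2: 5435.0     # cells/mm^2
crowding: {f: linear, g: linear}
grid: {geometry: cartesian1d, L: 3000.0, N: 300}
solver:
  method: fixed
  output_times: [0.0, 6.0, 12.0, 18.0, 24.0]
initial_condition:
  kind: block
  extent: 850.0
  smoothing: 0.0
  rho1: 4800.0
  rho2: 0.0
report:
  edge_threshold: 50.0
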