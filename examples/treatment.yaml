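# Example end-to-end configuration: synthetic perivascular liver tumor,
# 9-prong umbrella probe, staged temperature-controlled protocol, and a
# 5 x 5 perfusion uncertainty ensemble.
phantom:
  grid:
    shape: [32, 32, 32]
    spacing: [3.0, 3.0, 3.0]   # mm
  tumor:
    center: [46.5, 46.5, 46.5] # mm, grid center
    radius: 8.0                # mm
  vessels:
    - {p0: [60.5, -2.0, 46.5], p1: [60.5, 95.0, 46.5], radius: 3.0}
  crop_radius: 60.0            # mm sphere around the tumor
  properties:
    healthy: {perfusion: 2.0}
    tumor: {perfusion: 1.0}

needle:
  model: umbrella
  tip: [46.5, 46.5, 51.5]   # tumor center + 5 mm along the track
  shaft_point: [46.5, 46.5, 91.5]
  n_prongs: 9
  deploy_length: 10.0          # mm at full extension
  spread_deg: 70.0

protocol:
  gaussian_sigma_mm: 3.0
  phases:
    - {duration_s: 120, mode: temperature_controlled, power_W: 30, target_temp_C: 90, extension_fraction: 0.6}
    - {duration_s: 300, mode: temperature_controlled, power_W: 50, target_temp_C: 105, extension_fraction: 1.0}
    - {duration_s: 60, mode: cooldown, power_W: 0}

solver:
  dt: 2.0
  method: implicit
  record_every: 10

cell_death:
  death_threshold: 0.8

ensemble:
  p1: {name: tissue_perfusion, low: 0.6, high: 6.0, iterations: 5}
  p2: {name: tumor_perfusion, low: 0.3, high: 3.0, iterations: 5}
  outlier_depth_threshold: 0.1
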