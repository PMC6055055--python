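# Full synthetic pipeline run: two nitrogen levels, well-watered vs halved
# water supply. Execute with:  canopyflux run --config examples/run.yaml
out_dir: scratch/demo_run
seed: 7
latitude: 45.0
day_of_year: 180
cadence_s: 720
kl_dif: 0.96
leaf_angle: 15.0
treatments:
  - {name: N1_WW, lai: 1.8, sln0: 1.15, kn: 0.45, water_fraction: 1.0}
  - {name: N3_WW, lai: 2.6, sln0: 1.35, kn: 0.30, water_fraction: 1.0}
  - {name: N3_WS, lai: 2.6, sln0: 1.35, kn: 0.30, water_fraction: 0.5}
noise_vp_dif: 0.005   # kPa, logger noise on the vapor-pressure differential
noise_co2_dif: 0.5    # umol mol-1, logger noise on the CO2 differential
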