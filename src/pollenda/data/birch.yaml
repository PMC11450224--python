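# Pollen source-term parameters: birch (Betula)
name: birch
heatsum_type: daily-mean-T           # heat sum accumulated on daily mean temperature, unit K day
heatsum_uncertainty: 0.10
heat_accumulation_start: [3, 1]      # 1 March
cutoff_temperature_C: 3.5
n_total: 1.0e+8
n_total_uncertainty: 0.10
release_time_s: 3600.0
humidity_low_pct: 50.0
humidity_high_pct: 90.0
precip_threshold_mm_h: 0.5
wind_saturation_m_s: 5.0
wind_max_scale: 1.5
injection_height_m: [1.0, 50.0]
grain_diameter_um: 22.0
grain_density_kg_m3: 800.0
assimilation_window: [[3, 10], [7, 1]]   # 10 March - 1 July
lat_cut_south_deg: 40.0              # no birch assumed south of 40 N
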