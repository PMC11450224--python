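# Pollen source-term parameters: olive (Olea)
name: olive
heatsum_type: daily-mean-T
heatsum_uncertainty: 0.10
heat_accumulation_start: [1, 1]      # 1 January
cutoff_temperature_C: 0.0
n_total: 3.0e+8
n_total_uncertainty: 0.10
release_time_s: 3600.0
humidity_low_pct: 50.0
humidity_high_pct: 80.0
precip_threshold_mm_h: 0.5
wind_saturation_m_s: 5.0
wind_max_scale: 1.5
injection_height_m: [2.0, 50.0]
grain_diameter_um: 28.0
grain_density_kg_m3: 800.0
assimilation_window: [[4, 1], [7, 31]]   # 1 April - 31 July
lat_cut_south_deg: null
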