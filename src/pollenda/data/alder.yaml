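# Pollen source-term parameters: alder (Alnus)
name: alder
heatsum_type: hourly-mean-T          # heat sum accumulated on hourly mean temperature, unit K hour
heatsum_uncertainty: 0.10            # delta_H, fraction of the flowering-start threshold
heat_accumulation_start: [1, 1]      # 1 January, [month, day]
cutoff_temperature_C: 4.0
n_total: 1.0e+8                      # standard seasonal release, grains m-2 yr-1
n_total_uncertainty: 0.10            # delta_N, fraction
release_time_s: 3600.0               # tau, shortest release time (1 hour)
humidity_low_pct: 50.0
humidity_high_pct: 80.0
precip_threshold_mm_h: 0.5
wind_saturation_m_s: 5.0
wind_max_scale: 1.5
injection_height_m: [1.0, 50.0]
grain_diameter_um: 22.0
grain_density_kg_m3: 800.0
assimilation_window: [[1, 5], [5, 31]]   # 5 January - 31 May
lat_cut_south_deg: null
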