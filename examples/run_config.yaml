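# Minimal run configuration consumed by `grassflux simulate --config`.
field:
  label: example-field
  start: 2001-01-01
  end: 2002-12-31
species: ryegrass
seed: 11
soil:
  layers:
    - {thickness_m: 0.10, theta_s: 0.48, theta_fc: 0.38, theta_wp: 0.20, k_sat_m_d: 0.30, vg_alpha_per_m: 3.6, vg_n: 1.25}
    - {thickness_m: 0.20, theta_s: 0.48, theta_fc: 0.38, theta_wp: 0.20, k_sat_m_d: 0.15, vg_alpha_per_m: 3.6, vg_n: 1.25}
    - {thickness_m: 0.25, theta_s: 0.48, theta_fc: 0.38, theta_wp: 0.20, k_sat_m_d: 0.08, vg_alpha_per_m: 3.6, vg_n: 1.25}
    - {thickness_m: 0.30, theta_s: 0.48, theta_fc: 0.38, theta_wp: 0.20, k_sat_m_d: 0.05, vg_alpha_per_m: 3.6, vg_n: 1.25}
management:
  - {date: 2001-03-15, kind: fertilizer, amount_kg_n_ha: 60, product: ammonium_nitrate}
  - {date: 2001-06-05, kind: cut}
  - {date: 2002-03-15, kind: fertilizer, amount_kg_n_ha: 60, product: ammonium_nitrate}
  - {date: 2002-06-05, kind: cut}
stocking:
  - {start: 2001-06-20, end: 2001-09-20, head_count: 20, field_area_ha: 7.0, animal_type: beef}
  - {start: 2002-06-20, end: 2002-09-20, head_count: 20, field_area_ha: 7.0, animal_type: beef}
weather:
  synthetic: {years: 2, start_year: 2001}
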