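{
 "GCaL": 0.2,
 "GCaT": 0.12,
 "GNa": 7.8,
 "Gto1": 0.17,
 "GKr": 0.085,
 "GKs": 0.065,
 "GK1": 0.075,
 "GCab": 0.0012,
 "GNab": 0.0011,
 "GClb": 0.0006,
 "ImaxNCX": 1800.0,
 "ImaxNaK": 1.0,
 "ICaP_max": 0.14,
 "Jmaxup": 0.0053,
 "NRyRs": 198000.0,
 "Buff_factor": 1.0,
 "RyR_P": [
  0.2,
  0.22,
  1.0,
  1.0,
  1.0,
  8e-05,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  0.007
 ],
 "geometry": {
  "n_domains": 18,
  "v_cyto": 6.67e-13,
  "v_sr": 4e-14,
  "v_srs": 6.7e-15,
  "v_sl": 1.334e-14,
  "v_junct": 6.67e-16,
  "diffusion_coupling": 0.85
 }
}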