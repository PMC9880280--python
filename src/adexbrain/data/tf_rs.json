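{
 "population": "RS",
 "P": [
  -49.509795888479104,
  2.321384356350753,
  -5.488795240893557,
  -2.0179513285051294,
  0.5930550539035924,
  7.773629300899213,
  -7.729904849847333,
  1.8117761784287512,
  1.1906652547635819,
  -6.297169201978638
 ],
 "K_e": 400.0,
 "K_i": 100.0,
 "adex_params": {
  "c_m": 200.0,
  "g_L": 10.0,
  "E_L_e": -63.0,
  "E_L_i": -65.0,
  "Delta_e": 2.0,
  "Delta_i": 0.5,
  "v_thr": -50.0,
  "v_peak_e": -40.0,
  "v_peak_i": -47.5,
  "v_reset": -65.0,
  "T_refr": 5.0,
  "a": 0.0,
  "b": 0.0,
  "u_w": 500.0,
  "Q_e": 1.5,
  "Q_i": 5.0,
  "E_e": 0.0,
  "E_i": -80.0,
  "u_e": 5.0,
  "u_i": 5.0
 },
 "meta": {
  "nu_e_grid": [
   0.5,
   1.0,
   2.0,
   3.0,
   5.0,
   8.0,
   12.0,
   20.0,
   30.0,
   40.0
  ],
  "nu_i_grid": [
   0.5,
   1.0,
   2.0,
   3.0,
   5.0,
   8.0,
   12.0,
   20.0,
   30.0,
   40.0
  ],
  "W_grid": [
   0.0,
   40.0,
   80.0
  ],
  "sim_time_ms": 10000.0,
  "n_neurons": 20,
  "seed": 12345,
  "n_fit_points": 113,
  "rms_rate_error_hz": 0.28943251265592146,
  "rms_rate_error_all_hz": 7.889564088147088,
  "max_rate_error_hz": 22.162743938497925
 }
}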