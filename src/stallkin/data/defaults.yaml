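# Default constants and calibration for stallkin.
mechanics:
  # calibrated product 2*xi*kB*T (pN^2 nm^2); feasible interval against the
  # eight printed (force, torque) operating points is [444.08, 451.56)
  two_xi_kBT: 447.8
  temperature_K: 307.15          # 34 C reaction temperature
  kBT_pN_nm: 4.2587
  kBT_to_kcal_per_mol: 0.610     # at 307 K; 0.592 at 298 K
  init_force_ceiling_pN: 0.9     # above this, initiation is unreliable
kinetics:
  k0_per_s: 1.02e-6              # intrinsic zero-torque dissociation rate
  theta0_over_kBT: 0.1133        # rad per pN nm, intrinsic pathway
  theta_over_kBT: 0.0953         # rad per pN nm, RapA pathway
  Km_rapa_nM: 7.2
  kcat_per_s: 1.1e-3
  Km_atp_uM: 160.0
  initiation_rate_per_s: 0.01
  gamma_ref_pN_nm: 12.0          # torque of the concentration-series condition
trace:
  sampling_rate_Hz: 30.0
  noise_sd_nm: 10.0
  baseline_extension_nm: 500.0
  scrunch_drop_nm: 100.0
  elongation_drop_nm: 50.0
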