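# Default study scenario: four feeding occasions, ivermectin 0.1 ug/ml in
# every batch plus one CYP-modulator combination per batch (ketoconazole 5,
# rifampicin/ritonavir/piperonyl butoxide 10 ug/ml), destructive sampling at
# 0/6/12/24/36/48/72 h with 20 mosquitoes per cell.
seed: 1
design:
  combos: [KCZ, RIF, RTV, PBO]
  n_per_timepoint: 20
  blood_conc_ug_ml: 0.1
  lloq_ng: 0.005
  time_grid_h: [0, 6, 12, 24, 36, 48, 72]
truth:
  theta_dose_ng: 0.28
  theta_kel_ng_per_h: 0.0055
  theta_tlag_h: 18.5
  theta_tlag_add_rit_h: 11.4
  omega_dose: 0.075
  omega_kel: 0.25
  omega_iov_dose: 0.11
  sigma_prop: 0.02
  sigma_add_ng: 0.018
stages:
  simulate: true
  qc: true
  fit: true
  bootstrap: false     # enable for the full Table-style CI90 column (slow)
  vpc: true
  effects: true
n_bootstrap: 200
n_vpc: 200
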