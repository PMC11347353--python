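# Default synthetic study configuration.
#
# One labeled branch unit per month: the leaf pool receives an
# instantaneous pulse of excess 13C (0.2 atom-percent points above the
# natural background, the enrichment a 2 h feeding of 99 atom% 13CO2
# produces in the canopy) and drains into branches, fruit peels and
# seed kernels over a 72 h chase.  Each month's kinetics are stated as
# the allocation the noiseless model reaches at 72 h; the solver in
# pulsechase.simulate.transfer_rates_for_allocation converts them to
# first-order rates with 20% of exported carbon lost to respiration.
seed: 20210722
rc: 0.0112372
source_organ: leaves
background_delta13c: -27.0
pulse_excess_atom_percent: 0.2
respired_export_fraction: 0.2
timepoints_h: [0.0, 6.0, 24.0, 48.0, 72.0]
dt_h: 0.01
noise_sd_delta: 1.0
assay_noise_cv: 0.02
n_replicates: 4
n_expr_replicates: 3
expression_log_sigma: 0.25
organs:
  leaves:       {biomass_g: 40.0, carbon_fraction: 0.45}
  branches:     {biomass_g: 30.0, carbon_fraction: 0.47}
  peels:        {biomass_g: 25.0, carbon_fraction: 0.44}
  seed_kernels: {biomass_g: 15.0, carbon_fraction: 0.50}
months:
  Jul:
    target_allocation_percent:
      {branches: 7.77, leaves: 69.84, peels: 15.94, seed_kernels: 6.45}
  Aug:
    target_allocation_percent:
      {branches: 7.70, leaves: 54.55, peels: 16.54, seed_kernels: 21.21}
  Sep:
    target_allocation_percent:
      {branches: 13.17, leaves: 21.48, peels: 42.55, seed_kernels: 22.81}
  Oct:
    target_allocation_percent:
      {branches: 4.90, leaves: 3.78, peels: 26.86, seed_kernels: 64.47}
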