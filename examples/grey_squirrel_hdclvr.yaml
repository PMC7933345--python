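# HD-ClvR in a randomly mating grey-squirrel population:
# 1 homing gRNA, 4 cleave-and-rescue gRNAs, NHEJ rate 0.02,
# daisyfield of 30, single release of 100 animals, 10% yearly
# supplementation.  Run with:
#   hdclvr run examples/grey_squirrel_hdclvr.yaml --out traj.csv
drive:
  architecture: hdclvr
  n_grnas_homing: 1
  n_grnas_clvr: 4
  P_c: 0.95
  P_n: 0.02
  P_f: 0.667
  P_b: 0.2
  driving_y_skew: 0.95
  daisyfield_size: 30
  viability_mode: exact_two_copies
  clvr_target_mode: embryonic_lethal
life:
  K: 3000
  r_max: 1.16
  litter_size: 2.87
  generations_per_year: 2
schedule:
  initial_release: 100
  supplement_percent: 10.0
  supplement_interval_years: 1.0
  placement_strategy: middle
run:
  n_generations: 100
  n_replicates: 20
  master_seed: 1
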