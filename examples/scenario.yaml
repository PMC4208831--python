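# Example scenario configuration for `itxdel run-scenario --config ...`
#
# scenario: one of
#   fig2_scan       steady shed-antigen levels vs tumor volume
#   fig3_treatment  treated + control volume time courses
#   fig4_toggles    shedding off / on+backperm / on-without-backperm
#   fig4_compare    SS1P vs LMB-2 under matched growth parameters
#   fig5_sweep      endpoint volume vs surface antigen number R*
#   custom          plain simulation run
scenario: fig4_toggles
preset: SS1P

# any parameter field may be overridden by dotted path
overrides: {}
#  receptor.R_star: 5.0e5
#  blood.t_half_complex_blood_min: 120.0

# bolus schedule: [time_hr, dose_nM]
schedule:
  - [0.0, 62.0]
  - [48.0, 62.0]
  - [96.0, 62.0]

V0_mm3: 110.0      # tumor volume at the first dose
t_end_hr: 144.0    # two days after the third injection

# used by fig2_scan / fig5_sweep respectively
volumes: [10.0, 30.0, 100.0, 300.0, 1000.0]
r_star_grid: [1.0e3, 1.0e4, 1.0e5, 2.0e5, 5.0e5, 1.0e6, 1.0e7]
k_e_values: [0.08, 0.22]

# solver options (see itxdel.simulator.SolverOptions)
solver:
  n_shells: 25
  rtol: 1.0e-6

seed: 0
out_dir: scenario_out
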