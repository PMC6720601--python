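# Demo validation run: three muscle analytes with contrasting performance.
# Ground truths follow the reference per-analyte validation summary:
# sulfamethazine (well-behaved sulfonamide), cefquinome (high recovery,
# cross-talk risk with sulfamerazine), valnemulin (imprecise -> screening).
matrix: muscle
seed: 1
days: 3
replicates_per_day: 4
calibration_injections: 3
thresholds:
  max_deviation: 20.0
  cv_threshold: 20.0
  me_threshold: 20.0
  rt_window: 0.3
  mz_tol: 0.5
  rrt_limit: 2.5
scenarios:
  - analyte: sulfamethazine
    recovery_true: 0.85
    cv_r_true: 4.1
    cv_wr_true: 7.2
    matrix_effect_true: -1.0
    solvent_slope: 1200.0
    mrl: 100.0
  - analyte: cefquinome
    recovery_true: 0.97
    cv_r_true: 6.1
    cv_wr_true: 7.2
    matrix_effect_true: -4.0
    solvent_slope: 300.0
    mrl: 50.0
  - analyte: valnemulin
    recovery_true: 0.75
    cv_r_true: 19.0
    cv_wr_true: 31.0
    matrix_effect_true: -26.0
    solvent_slope: 800.0
    mrl: 50.0
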