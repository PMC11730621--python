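# paper_like observer preset
# Link-scale effect coefficients produced by gazesearch.simulate.calibrate_preset
# (seed=20260929, 250-subject pilots, 5 damped iterations) so that the realized
# standardized eye-metric regression coefficients match the preset's documented
# targets (see simulate.PAPER_LIKE_TARGETS and docs/methods.md).
# Regenerate with: calibrate_preset(seed=20260929)
p_skip_base = -0.8472978603872037
p_revisit_base = -1.3862943611198906
mu_dwell_log = 5.521460917862246
sigma_dwell_log = 0.45
subject_sd_skip = 0.4
subject_sd_revisit = 0.4
subject_sd_dwell = 0.2
subject_sd_motor = 60.0
transition_mean_ms = 45.0
transition_sd_ms = 15.0
motor_mean_ms = 500.0
motor_sd_ms = 100.0
beta_age_motor_ms = 100.0
revisit_gaze_scale = 0.7
fix_noise_sd = 10.0
p_split_fixation = 0.3
beta_skip.age = 0.10753967254247541
beta_skip.similarity = -0.14528832698900013
beta_skip.set_size = 0.3468115931476025
beta_skip.age_x_similarity = 0.11380639266058432
beta_skip.age_x_set_size = -0.0956998555222869
beta_revisit.age = 0.32811696235476007
beta_revisit.similarity = 0.38663849270318235
beta_revisit.set_size = -0.01527201218218936
beta_revisit.age_x_similarity = 0.03124774768636871
beta_revisit.age_x_set_size = -0.046267972393015395
beta_dwell.age = 0.13827114293442558
beta_dwell.similarity = 0.19399355007017566
beta_dwell.set_size = -0.09361371736002538
beta_dwell.age_x_similarity = 0.001078160357465246
beta_dwell.age_x_set_size = -0.014501472287145016
error_rate.absent.0.5 = 0.01
error_rate.absent.0.10 = 0.005
error_rate.absent.1.5 = 0.005
error_rate.absent.1.10 = 0.01
error_rate.present.0.5 = 0.06
error_rate.present.0.10 = 0.11
error_rate.present.1.5 = 0.08
error_rate.present.1.10 = 0.1
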