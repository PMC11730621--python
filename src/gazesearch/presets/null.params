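# null observer preset
# All covariate effects zero; between-subject variation and the RT assembly
# mechanism are retained.  Used for type-I-error calibration of the
# eye-metric regressions.
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
beta_skip.age = 0.0
beta_skip.similarity = 0.0
beta_skip.set_size = 0.0
beta_skip.age_x_similarity = 0.0
beta_skip.age_x_set_size = 0.0
beta_revisit.age = 0.0
beta_revisit.similarity = 0.0
beta_revisit.set_size = 0.0
beta_revisit.age_x_similarity = 0.0
beta_revisit.age_x_set_size = 0.0
beta_dwell.age = 0.0
beta_dwell.similarity = 0.0
beta_dwell.set_size = 0.0
beta_dwell.age_x_similarity = 0.0
beta_dwell.age_x_set_size = 0.0
error_rate.absent.0.5 = 0.01
error_rate.absent.0.10 = 0.005
error_rate.absent.1.5 = 0.005
error_rate.absent.1.10 = 0.01
error_rate.present.0.5 = 0.06
error_rate.present.0.10 = 0.11
error_rate.present.1.5 = 0.08
error_rate.present.1.10 = 0.1
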