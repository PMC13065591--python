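# Example ventrecon run configuration.
# Every key is optional; unknown keys are rejected.  Values shown are the
# defaults.  Use with any subcommand:  ventrecon extract --config config.yaml ...

format: csv-dir              # input/output table format: csv-dir | sqlite

# --- extraction -----------------------------------------------------------
gap_tolerance_hours: 8.0     # flowsheet rows farther apart start a new invasive interval
invasive_modes: [AC, PRVC, PS-invasive, SIMV]
noninvasive_modes: [CPAP, HFNC, NIPPV, nasal-IMV]

# --- clustering / pairing -------------------------------------------------
match_window_hours: 12.0     # single-linkage threshold for "same event"
min_episode_gap_minutes: 30.0  # extubation->reintubation gaps below this merge

# --- quality grading ------------------------------------------------------
concordance_a_hours: 1.0     # A band (closed); also the "matching source" tolerance
concordance_c_hours: 12.0    # C opens strictly beyond this spread
score_one_min_sources: 3     # matching sources needed for score 1
score_two_min_sources: 2     # ... for score 2

# --- outcome metrics ------------------------------------------------------
denominator_policy: episodes  # episodes | all_episodes | patients
exclude_locations: [perioperative]  # dropped from grade-distribution matrices

# --- synthetic cohort (simulate subcommand) -------------------------------
scenario:
  n_patients: 500
  seed: 0
  pediatric_fraction: 0.118
  reintubation_prob_48h: 0.018
  reintubation_prob_2to7d: 0.014
  p_arrive_intubated: 0.01
  p_death: 0.032
  p_tracheostomy: 0.0012
  p_noninvasive_interleave: 0.15
  mean_duration_hours_adult: 15.8
  mean_duration_hours_pediatric: 44.7
  duration_lognorm_sigma: 0.9
  charting_interval_minutes: 60
  death_undocumented_sources: [lda, anesthesia]
  source_documentation_probs: {flowsheet: 0.95, lda: 0.95, anesthesia: 0.75, procedure: 0.40}
  jitter_sd_minutes: {flowsheet: 30.0, lda: 10.0, anesthesia: 2.0, procedure: 60.0}
  location_mix:
    perioperative: 0.85
    ED: 0.03
    NICU: 0.02
    PICU: 0.01
    cardiac_ICU: 0.01
    adult_ICU: 0.05
    ward: 0.01
    other: 0.02
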