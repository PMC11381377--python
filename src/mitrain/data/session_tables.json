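{
  "description": "Per-subject summary scores of the ten-subject, two-session training study: class distance (CD) of the calibration features and questionnaire (Qn) means per process, plus the printed on-line accuracy tallies. Subjects S1-S5 had prior motor-imagery experience ('trained'); S6-S10 did not ('untrained').",
  "subjects": ["S1", "S2", "S3", "S4", "S5", "S6", "S7", "S8", "S9", "S10"],
  "trained": ["S1", "S2", "S3", "S4", "S5"],
  "untrained": ["S6", "S7", "S8", "S9", "S10"],
  "cd_calibration": {
    "non_feedback":   [0.46, 0.89, 1.19, 0.46, 1.18, 0.89, 0.78, 0.50, 0.56, 0.98],
    "trial_feedback": [0.51, 1.26, 0.69, 0.59, 1.31, 0.46, 0.49, 0.88, 0.60, 0.78]
  },
  "qn_calibration": {
    "non_feedback":   [3.67, 3.00, 3.00, 3.83, 3.00, 2.28, 2.56, 3.00, 2.06, 3.00],
    "trial_feedback": [3.00, 3.00, 3.00, 3.83, 3.00, 2.00, 2.72, 3.00, 1.44, 3.00]
  },
  "qn_testing": {
    "non_feedback":   [3.25, 3.25, 3.58, 4.25, 3.00, 2.58, 2.75, 3.00, 2.00, 3.00],
    "trial_feedback": [3.00, 3.25, 3.08, 4.50, 3.00, 2.00, 2.67, 3.00, 1.33, 3.00]
  },
  "benchmark_runs": {
    "comment": "Times the 70% on-line accuracy benchmark was reached, per session and testing-run stage, out of 2 sessions x 4 runs x 10 subjects.",
    "first_two_non_feedback": 5,
    "first_two_trial_feedback": 8,
    "last_two_non_feedback": 2,
    "last_two_trial_feedback": 6,
    "n_sessions": 2,
    "n_runs_per_session": 4,
    "n_subjects": 10
  },
  "online_ca_run_averages_pct": {
    "comment": "Average on-line accuracy (%) over the ten subjects for each of the four run slots in a stage (2 sessions x 2 runs): the first two testing runs use the 3-run model, the last two the 6-run model.",
    "first_two_runs": [49, 53, 59, 63],
    "last_two_runs": [46, 56, 66, 60]
  }
}
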