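"""End-to-end session pipeline.

Orchestrates, in the order the paradigm runs them: EOG blink-threshold
calibration → per-trial prompt feedback (trial-feedback sessions only) →
blink gating → variance-based artifact rejection → decoder fits after
the third and sixth calibration runs → decoding of the four testing runs
(the first two with the 3-run model, the last two with the 6-run model)
→ per-run class-distance evaluation and 10 x 10-fold off-line accuracy.

Every removed trial is logged with its reason, and the report echoes the
configuration so a rerun with the same config and seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np

from .artifacts import reject_high_variance
from .core import EpochedTrial, TimingScheme, TrainingSet, standard_montage
from .decoding import align_runs, csp_features, decode_trial, fit_decoder
from .eog import blink_feature, calibrate_threshold, is_dissatisfied
from .evaluation import cv_accuracy, run_evaluation
from .feedback import feedback_for_trial
from .preprocess import FilterSpec, extract_epoch, filter_trial
from .simulate import SimConfig, SimulatedSession, simulate_session

__all__ = ["prepare_run", "run_pipeline"]


def prepare_run(run, calibration, filter_spec=None, timing=None,
                with_feedback=False, montage=None, log=None):
    """Preprocess one calibration run: filter, feedback, gate, reject.

    Returns ``(epoched_survivors, run_report)``.  ``run_report`` records
    the per-trial feedback outcomes (if requested), the ids gated out by
    the blink rule, and the artifact-rejection report.
    """
    montage = montage or standard_montage()
    timing = timing or TimingScheme()
    filter_spec = filter_spec or FilterSpec()
    log = log if log is not None else []

    feedback_records = []
    gated_ids = []
    epoched = []
    for t in run:
        filtered = filter_trial(t.mi_samples, filter_spec)
        if with_feedback:
            fb = feedback_for_trial(filtered, t.label, montage, timing)
            feedback_records.append({
                "trial_id": t.trial_id, "label": t.label, "K": fb.K,
                "topoval_right": fb.topoval_right,
                "topoval_left": fb.topoval_left, "verdict": fb.verdict,
                "selected_map": fb.selected_map.tolist()})
        if is_dissatisfied(t.confirmation_eog, calibration):
            gated_ids.append(t.trial_id)
            log.append({"trial_id": t.trial_id, "stage": "blink-gate",
                        "action": "removed"})
            continue
        epoch = extract_epoch(filtered, timing.training_window_s,
                              timing.sampling_rate)
        epoched.append(EpochedTrial(samples=epoch, label=t.label,
                                    trial_id=t.trial_id, run_id=t.run_id))
    survivors, screen = reject_high_variance(epoched)
    for tid in screen.removed_trial_ids:
        log.append({"trial_id": tid, "stage": "variance-rejection",
                    "action": "removed"})
    report = {"n_trials": len(run), "n_after_gating": len(epoched),
              "n_final": len(survivors), "gated_ids": gated_ids,
              "rejection_thresholds": screen.threshold_history,
              "rejected_ids": screen.removed_trial_ids,
              "feedback": feedback_records}
    return survivors, report


def run_pipeline(config: SimConfig | None = None,
                 session: SimulatedSession | None = None,
                 with_feedback: bool = True,
                 filter_spec: FilterSpec | None = None,
                 cv_seed: int = 0) -> dict:
    """Run the full paradigm on a (simulated or loaded) session.

    Returns a JSON-serializable report: blink threshold, per-run
    preparation reports and class distances, both decoder fits, per-run
    testing accuracies, and the 10 x 10-fold off-line accuracy of the
    six-run training set.
    """
    if session is None:
        config = config or SimConfig()
        session = simulate_session(config)
    config = session.config
    filter_spec = filter_spec or FilterSpec()
    timing = TimingScheme()
    montage = standard_montage()
    log: list = []

    blink_feats = [blink_feature(t.trace) for t in session.eog_run if t.blink]
    calibration = calibrate_threshold(blink_feats)

    cleaned_runs = []
    run_reports = []
    training = TrainingSet()
    for run in session.calibration_runs:
        survivors, rep = prepare_run(run, calibration, filter_spec, timing,
                                     with_feedback=with_feedback,
                                     montage=montage, log=log)
        cleaned_runs.append(survivors)
        run_reports.append(rep)
        run_id = run[0].run_id
        training.trials.extend(survivors)
        training.n_after_gating[run_id] = rep["n_after_gating"]
        training.n_final[run_id] = rep["n_final"]

    # Run evaluation: class distance of each run's features under a model
    # fit on the runs available so far (alignment and CSP use no future runs).
    for r, rep in enumerate(run_reports):
        bundle_r = fit_decoder(cleaned_runs[:r + 1], filter_spec=filter_spec)
        aligned_r, labels_r, _ = align_runs([cleaned_runs[r]])
        feats = np.stack([csp_features(t.samples, bundle_r.spatial.filters)
                          for t in aligned_r])
        try:
            rep["class_distance"] = run_evaluation(feats, labels_r).cd
        except ValueError:
            rep["class_distance"] = None

    bundle3 = fit_decoder(cleaned_runs[:3], filter_spec=filter_spec)
    bundle6 = fit_decoder(cleaned_runs[:6], filter_spec=filter_spec)

    testing = []
    for i, run in enumerate(session.testing_runs):
        bundle = bundle3 if i < 2 else bundle6
        decoded = [decode_trial(t.mi_samples, bundle) for t in run]
        correct = sum(d.label == t.label for d, t in zip(decoded, run))
        testing.append({"run_id": run[0].run_id,
                        "model": "3-run" if i < 2 else "6-run",
                        "n_trials": len(run), "n_correct": int(correct),
                        "accuracy": correct / len(run),
                        "commands": [d.command for d in decoded]})
        log.extend({"trial_id": t.trial_id, "stage": "decode",
                    "action": d.command} for d, t in zip(decoded, run))

    aligned6, _, _ = align_runs(cleaned_runs[:6])
    cv = cv_accuracy(aligned6, seed=cv_seed)

    return {
        "config": {k: (v if not isinstance(v, np.generic) else v.item())
                   for k, v in asdict(config).items()},
        "filter_spec": asdict(filter_spec),
        "blink_threshold": calibration.threshold,
        "calibration_runs": run_reports,
        "testing_runs": testing,
        "offline_cv": {"mean": cv["mean"], "sd": cv["sd"]},
        "trial_log": log,
    }
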