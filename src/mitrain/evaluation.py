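r"""Run evaluation and session statistics.

**Class distance (CD).**  After each calibration run the six-dimensional
CSP features of that run are scored for separability.  With ``F_c`` the
d x N_c column matrix of class-c features,

    Sw = sum_c F_c (I - 1/N_c J) F_c'      (within-class scatter)
    Sb = sum_c N_c (mean_c - mean)(mean_c - mean)'   (between-class)
    CD = ||Sb||_1 / ||Sw||_1

where the default ``||.||_1`` is the entrywise sum of absolute values
(the induced 1-norm and the trace are available as alternatives; CD is
exactly invariant to global feature scaling under any of them).  For the
on-screen projection, the first and last CSP features of every trial are
exported as 2-D coordinates.

**Off-line accuracy.**  10 x 10-fold stratified cross-validation on the
aligned training trials; Riemannian alignment is done once per run
beforehand (it uses no labels, so there is no leakage), while CSP and
LDA are refit inside every fold.

**Session statistics.**  Paired two-tailed t-tests, Pearson correlation,
and the reproduction of the packaged per-subject tables (class distance
and questionnaire scores of the ten-subject study) with half-up rounding
to the printed precision: means to 2 decimals, p-values to 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
import json

import numpy as np
import pandas as pd
from scipy import stats

from .core import CLASS_LEFT, CLASS_RIGHT, EpochedTrial
from .decoding import csp_features, csp_fit, lda_fit

__all__ = [
    "RunEvalResult",
    "scatter_matrices",
    "class_distance",
    "run_evaluation",
    "cv_accuracy",
    "paired_ttest",
    "pearson",
    "round_half_up",
    "load_session_tables",
    "reproduce_tables",
]


@dataclass
class RunEvalResult:
    Sw: np.ndarray
    Sb: np.ndarray
    cd: float
    projection: pd.DataFrame  # columns: first, last, label


def scatter_matrices(features_by_class: dict[int, np.ndarray]
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Within- and between-class scatter of per-class feature columns.

    ``features_by_class`` maps class label to a d x N_c array (features
    as columns).
    """
    mats = {c: np.asarray(f, dtype=float) for c, f in features_by_class.items()}
    for c, f in mats.items():
        if f.ndim != 2 or f.shape[1] == 0:
            raise ValueError(f"class {c} has no feature columns")
    d = next(iter(mats.values())).shape[0]
    n_total = sum(f.shape[1] for f in mats.values())
    grand = sum(f.sum(axis=1) for f in mats.values()) / n_total

    sw = np.zeros((d, d))
    sb = np.zeros((d, d))
    for f in mats.values():
        nc = f.shape[1]
        center = np.eye(nc) - np.ones((nc, nc)) / nc
        sw += f @ center @ f.T
        mc = f.mean(axis=1)
        diff = (mc - grand)[:, None]
        sb += nc * (diff @ diff.T)
    return sw, sb


def _matrix_norm(m: np.ndarray, mode: str) -> float:
    if mode == "entrywise":
        return float(np.abs(m).sum())
    if mode == "induced1":
        return float(np.abs(m).sum(axis=0).max())
    if mode == "trace":
        return float(np.trace(m))
    raise ValueError(f"unknown norm mode: {mode!r}")


def class_distance(sw: np.ndarray, sb: np.ndarray,
                   norm_mode: str = "entrywise") -> float:
    """Between/within scatter-norm ratio; 0 when class means coincide."""
    denom = _matrix_norm(sw, norm_mode)
    if denom == 0:
        raise ValueError("within-class scatter is zero (degenerate run)")
    return _matrix_norm(sb, norm_mode) / denom


def run_evaluation(features: np.ndarray, labels: np.ndarray,
                   norm_mode: str = "entrywise") -> RunEvalResult:
    """Evaluate one calibration run's feature distribution.

    ``features`` is N x d (trials as rows).  Returns the scatter
    matrices, the class distance, and the 2-D (first, last) feature
    projection per trial.
    """
    f = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    by_class = {c: f[labels == c].T for c in (CLASS_RIGHT, CLASS_LEFT)}
    sw, sb = scatter_matrices(by_class)
    cd = class_distance(sw, sb, norm_mode)
    proj = pd.DataFrame({"first": f[:, 0], "last": f[:, -1], "label": labels})
    return RunEvalResult(Sw=sw, Sb=sb, cd=cd, projection=proj)


def cv_accuracy(aligned_trials: list[EpochedTrial], reps: int = 10,
                folds: int = 10, seed: int = 0, m_per_side: int = 3) -> dict:
    """Repeated stratified k-fold accuracy with CSP+LDA refit per fold.

    Trials must already be Riemannian-aligned (label-free, so done once
    at run level).  Returns mean, sd and the per-fold accuracies over
    ``reps x folds`` folds.
    """
    from sklearn.model_selection import StratifiedKFold

    labels = np.array([t.label for t in aligned_trials])
    for c in (CLASS_RIGHT, CLASS_LEFT):
        if np.sum(labels == c) < folds:
            raise ValueError("need at least `folds` trials per class")
    idx = np.arange(len(aligned_trials))
    per_fold = []
    for rep in range(reps):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=seed + rep)
        for train_idx, test_idx in skf.split(idx, labels):
            train = [aligned_trials[i] for i in train_idx]
            spatial = csp_fit(train, m_per_side=m_per_side)
            f_train = np.stack([csp_features(t.samples, spatial.filters)
                                for t in train])
            lda = lda_fit(f_train, labels[train_idx])
            correct = sum(
                lda.predict(csp_features(aligned_trials[i].samples,
                                         spatial.filters)) == labels[i]
                for i in test_idx)
            per_fold.append(correct / len(test_idx))
    per_fold = np.asarray(per_fold)
    return {"mean": float(per_fold.mean()), "sd": float(per_fold.std(ddof=1)),
            "per_fold": per_fold}


def paired_ttest(x, y) -> tuple[float, int, float]:
    """Two-tailed paired t-test; returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0):
        raise ValueError("zero-variance differences: paired t undefined")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), x.size - 1, float(res.pvalue)


def pearson(x, y) -> tuple[float, float, int]:
    """Sample Pearson correlation with two-tailed p; returns (r, p, N)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.shape != y.shape:
        raise ValueError("need two equal-length vectors of size >= 3")
    if np.allclose(x.std(), 0) or np.allclose(y.std(), 0):
        raise ValueError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(x.size)


def round_half_up(value: float, decimals: int) -> float:
    """Round half away from zero at the given number of decimals."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def load_session_tables() -> dict:
    """Packaged per-subject tables of the ten-subject two-session study."""
    with resources.files("mitrain.data").joinpath("session_tables.json").open() as fh:
        return json.load(fh)


def reproduce_tables() -> dict:
    """Recompute the session summary statistics from the packaged
    per-subject tables: trained/untrained/all means (2 d.p.) and the
    paired t-tests (p to 4 d.p.) comparing the two sessions, plus the
    printed on-line accuracy tallies (benchmark-run fraction and
    stage averages).
    """
    tables = load_session_tables()
    subjects = tables["subjects"]
    trained = [subjects.index(s) for s in tables["trained"]]
    untrained = [subjects.index(s) for s in tables["untrained"]]

    report: dict = {"means": {}, "paired_t": {}}
    for block in ("cd_calibration", "qn_calibration", "qn_testing"):
        non = np.asarray(tables[block]["non_feedback"])
        trial = np.asarray(tables[block]["trial_feedback"])
        for name, vals in (("non_feedback", non), ("trial_feedback", trial)):
            report["means"][f"{block}.{name}"] = {
                "trained": round_half_up(vals[trained].mean(), 2),
                "untrained": round_half_up(vals[untrained].mean(), 2),
                "all": round_half_up(vals.mean(), 2),
            }
        t, df, p = paired_ttest(non, trial)
        report["paired_t"][block] = {"t": t, "df": df, "p": round_half_up(p, 4)}

    bench = tables["benchmark_runs"]
    hits = (bench["first_two_non_feedback"] + bench["first_two_trial_feedback"]
            + bench["last_two_non_feedback"] + bench["last_two_trial_feedback"])
    total = bench["n_sessions"] * bench["n_runs_per_session"] * bench["n_subjects"]
    report["benchmark_fraction_pct"] = round_half_up(100.0 * hits / total, 2)

    ca = tables["online_ca_run_averages_pct"]
    report["online_ca_stage_avg_pct"] = {
        "first_two": round_half_up(np.mean(ca["first_two_runs"]), 2),
        "last_two": round_half_up(np.mean(ca["last_two_runs"]), 2),
    }
    return report
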