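"""Per-trial ERD/ERS prompt feedback.

After each training trial the paradigm shows the subject one of three
candidate scalp topographies of mean envelope deviation and a qualitative
verdict.  The chain is:

1. **Envelope transform** — re-reference the filtered 4-s MI window
   (common average over the 21 montage electrodes by default, or a
   nearest-neighbour surface Laplacian), band-pass to the rhythm band
   (8-30 Hz default), take the analytic-signal magnitude as envelope,
   and subtract each channel's mean envelope over the full window.  The
   result is a matrix of signed envelope deviations whose per-channel
   mean is zero, so both ERD (negative) and ERS (positive) deviations
   are guaranteed to occur.
2. **Segment averages** — average the deviations over the three nested
   segments (0.5-1.5, 0.5-2.5, 0.5-3.5 s), giving a 3 x 21 array ``R``.
3. **Map selection** — count, per segment, the electrodes whose deviation
   sign is physiologically correct for the trial's class (ERS over the
   ipsilateral group, ERD over the contralateral group).  A segment with
   correct signs on *both* hemispheres is preferred (metric = Nl + Nr,
   and a flag bars later single-hemisphere segments); otherwise a segment
   with only ipsilateral ERS scores its single-hemisphere count.  The
   earliest segment with the strictly largest metric wins; if no segment
   scores, the middle segment (K = 2) is shown by default.
4. **Topographic values** — for the selected segment, each class
   hypothesis scores the sum of correctly-signed deviations normalised by
   the hemisphere's extremum, so each electrode contributes a ratio in
   (0, 1] and each TopoVal lies in [0, 18] (9 electrodes per hemisphere).
5. **Verdict** — 'good' iff the true class's TopoVal attains the maximum
   (ties count as 'good'), else 'fight'.

Midline electrodes (FCz, Cz, CPz) never enter the hemispheric counts or
TopoVals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal
from scipy.signal import hilbert

from .core import CLASS_LEFT, CLASS_RIGHT, Montage, TimingScheme, standard_montage

__all__ = [
    "FeedbackOutcome",
    "envelope_transform",
    "segment_averages",
    "select_topomap",
    "topo_values",
    "evaluate_trial",
    "feedback_for_trial",
]


@dataclass
class FeedbackOutcome:
    """Everything the prompt-feedback screen needs for one trial."""

    K: int
    counts: list            # per-segment (Nl, Nr)
    topoval_right: float    # TopoVal under the right-hand (class 1) hypothesis
    topoval_left: float     # TopoVal under the left-hand (class 2) hypothesis
    verdict: str
    selected_map: np.ndarray  # the 21 R values of segment K (plot-ready)


def _laplacian_reference(x: np.ndarray, montage: Montage) -> np.ndarray:
    coords = montage.coordinates()
    labels = montage.all_labels
    xs = np.array([coords[l][0] for l in labels])
    ys = np.array([coords[l][1] for l in labels])
    out = np.empty_like(x)
    for j in range(len(labels)):
        # nearest neighbours: same row adjacent columns + same column adjacent rows
        d = np.hypot(xs - xs[j], ys - ys[j])
        d[j] = np.inf
        nbr = np.argsort(d)[:4]
        out[:, j] = x[:, j] - x[:, nbr].mean(axis=1)
    return out


def envelope_transform(mi_samples: np.ndarray,
                       montage: Montage | None = None,
                       reference_mode: str = "car",
                       band_hz: tuple[float, float] = (8.0, 30.0),
                       sampling_rate: float = 256.0) -> np.ndarray:
    """Signed envelope deviations of the filtered 4-s MI window.

    ``reference_mode``: ``"car"`` (common average over the montage
    electrodes, default), ``"laplacian"`` (nearest-neighbour surface
    Laplacian) or ``"identity"`` (no re-referencing).
    """
    x = np.asarray(mi_samples, dtype=float)
    if x.ndim != 2:
        raise ValueError("mi_samples must be 2-D (samples x channels)")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples")
    montage = montage or standard_montage()

    if reference_mode == "car":
        x = x - x.mean(axis=1, keepdims=True)
    elif reference_mode == "laplacian":
        x = _laplacian_reference(x, montage)
    elif reference_mode != "identity":
        raise ValueError(f"unknown reference_mode: {reference_mode!r}")

    sos = _signal.butter(4, band_hz, btype="bandpass", fs=sampling_rate, output="sos")
    narrow = _signal.sosfiltfilt(sos, x, axis=0)
    env = np.abs(hilbert(narrow, axis=0))
    return env - env.mean(axis=0, keepdims=True)


def segment_averages(env: np.ndarray,
                     timing: TimingScheme | None = None) -> np.ndarray:
    """Mean envelope deviation per feedback segment: a 3 x n_channels array
    ``R`` with ``R[k, j]`` the mean over segment k at electrode j."""
    timing = timing or TimingScheme()
    env = np.asarray(env, dtype=float)
    rows = timing.segment_rows()
    return np.stack([env[lo:hi].mean(axis=0) for lo, hi in rows])


def _correct_counts(rk: np.ndarray, label: int, montage: Montage) -> tuple[int, int]:
    """(Nl, Nr): correctly-signed electrode counts on the left/right groups."""
    left = rk[montage.left_indices]
    right = rk[montage.right_indices]
    if label == CLASS_LEFT:     # left hand: ERS left (positive), ERD right (negative)
        return int(np.sum(left > 0)), int(np.sum(right < 0))
    if label == CLASS_RIGHT:    # right hand: ERD left (negative), ERS right (positive)
        return int(np.sum(left < 0)), int(np.sum(right > 0))
    raise ValueError(f"invalid class label: {label!r}")


def select_topomap(R: np.ndarray, label: int,
                   montage: Montage | None = None) -> tuple[int, list]:
    """Pick the representative segment K (1-based) and return the
    per-segment correct-electrode counts.

    Both-hemisphere segments (Nl > 0 and Nr > 0) score ``Nl + Nr`` and set
    a flag that bars later single-hemisphere candidates; a segment with
    only ipsilateral ERS scores its single count while the flag is unset.
    Strictly-greater comparison means the earliest best segment wins; if
    nothing scores, K = 2.
    """
    montage = montage or standard_montage()
    R = np.asarray(R, dtype=float)
    best_metric = 0
    flag = 0
    K = 0
    counts = []
    for k in range(R.shape[0]):
        nl, nr = _correct_counts(R[k], label, montage)
        counts.append((nl, nr))
        metric = 0
        if nl > 0 and nr > 0:
            metric = nl + nr
            flag = 1
        elif label == CLASS_LEFT and nl > 0 and flag == 0:
            metric = nl
        elif label == CLASS_RIGHT and nr > 0 and flag == 0:
            metric = nr
        if metric > best_metric:
            best_metric = metric
            K = k + 1
    if best_metric == 0:
        K = 2
    return K, counts


def topo_values(rk: np.ndarray,
                montage: Montage | None = None) -> tuple[float, float]:
    """(TopoVal1, TopoVal2): extremum-normalised hemispheric scores of the
    selected segment under the right-hand / left-hand class hypotheses.

    Each hypothesis sums, over its correctly-signed electrodes only, the
    deviation divided by that hemisphere's sign-restricted extremum; an
    empty sign set contributes 0, so each TopoVal lies in [0, 18].
    """
    montage = montage or standard_montage()
    rk = np.asarray(rk, dtype=float)
    left = rk[montage.left_indices]
    right = rk[montage.right_indices]

    def _term(vals: np.ndarray, positive: bool) -> float:
        sel = vals[vals > 0] if positive else vals[vals < 0]
        if sel.size == 0:
            return 0.0
        extremum = sel.max() if positive else sel.min()
        return float(np.sum(sel) / extremum)

    topoval1 = _term(left, positive=False) + _term(right, positive=True)
    topoval2 = _term(left, positive=True) + _term(right, positive=False)
    return topoval1, topoval2


def evaluate_trial(topoval_right: float, topoval_left: float, label: int) -> str:
    """'good' iff the true class's TopoVal attains the maximum (ties are
    'good'), else 'fight'."""
    if label == CLASS_RIGHT:
        return "good" if topoval_right >= topoval_left else "fight"
    if label == CLASS_LEFT:
        return "good" if topoval_left >= topoval_right else "fight"
    raise ValueError(f"invalid class label: {label!r}")


def feedback_for_trial(filtered_mi: np.ndarray, label: int,
                       montage: Montage | None = None,
                       timing: TimingScheme | None = None,
                       reference_mode: str = "car",
                       band_hz: tuple[float, float] = (8.0, 30.0)) -> FeedbackOutcome:
    """Full prompt-feedback chain for one (already band-pass filtered) trial."""
    montage = montage or standard_montage()
    timing = timing or TimingScheme()
    env = envelope_transform(filtered_mi, montage=montage,
                             reference_mode=reference_mode, band_hz=band_hz,
                             sampling_rate=timing.sampling_rate)
    R = segment_averages(env, timing)
    K, counts = select_topomap(R, label, montage)
    tv1, tv2 = topo_values(R[K - 1], montage)
    verdict = evaluate_trial(tv1, tv2, label)
    return FeedbackOutcome(K=K, counts=counts, topoval_right=tv1,
                           topoval_left=tv2, verdict=verdict,
                           selected_map=R[K - 1].copy())
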