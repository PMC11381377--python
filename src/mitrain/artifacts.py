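"""Variance-based rejection of high-variance training trials.

After blink gating, trials whose per-channel variance is excessive are
removed by an iterated percentile rule:

1. Compute each trial's per-channel variance (unbiased, mean-removed).
2. Screen out channels at which strictly more than 10% of trials have
   variance below 0.5 uV^2 — such channels are flat/disconnected and
   would drag the pooled percentiles down.  The screen is computed once,
   before the loop.
3. Loop: pool the retained-channel variances of the remaining trials
   into one vector ``Var``; set
   ``threshold = P90(Var) + 3 * (P90(Var) - P10(Var))``
   (linear-interpolation percentiles); remove every trial whose maximum
   retained-channel variance strictly exceeds the threshold; stop as soon
   as an iteration removes nothing.

The loop terminates because each pass either removes at least one trial
or exits, and applying it to its own output removes nothing (the final
threshold admitted every survivor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EpochedTrial

__all__ = ["VarianceScreen", "trial_variances", "channel_screen", "reject_high_variance"]

SMALL_VARIANCE = 0.5   # uV^2; "small variance" cutoff of the channel screen
SMALL_FRACTION = 0.10  # screen a channel if > this fraction of trials is small


@dataclass
class VarianceScreen:
    """Report of one artifact-rejection pass."""

    per_trial_variances: np.ndarray = None
    retained_channels: np.ndarray = None
    threshold_history: list = field(default_factory=list)
    removed_trial_ids: list = field(default_factory=list)


def trial_variances(trials: list[EpochedTrial]) -> np.ndarray:
    """N x C matrix of per-trial, per-channel variances (ddof=1)."""
    return np.stack([np.var(t.samples, axis=0, ddof=1) for t in trials])


def channel_screen(variances: np.ndarray,
                   small_variance: float = SMALL_VARIANCE,
                   small_fraction: float = SMALL_FRACTION) -> np.ndarray:
    """Indices of channels kept by the low-variance screen.

    Channel j is dropped iff strictly more than ``small_fraction`` of
    trials have variance < ``small_variance`` at j.
    """
    v = np.asarray(variances, dtype=float)
    frac_small = np.mean(v < small_variance, axis=0)
    return np.where(~(frac_small > small_fraction))[0]


def reject_high_variance(trials: list[EpochedTrial],
                         small_variance: float = SMALL_VARIANCE,
                         small_fraction: float = SMALL_FRACTION
                         ) -> tuple[list[EpochedTrial], VarianceScreen]:
    """Iteratively remove trials with excessive variance.

    Returns the surviving trials (original order preserved) and a report
    with the channel screen, the threshold of every iteration and the ids
    of removed trials.  Raises if fewer than two trials are given or if
    the rule would remove every trial.
    """
    if len(trials) < 2:
        raise ValueError("need at least two trials")
    variances = trial_variances(trials)
    kept_ch = channel_screen(variances, small_variance, small_fraction)
    if kept_ch.size == 0:
        raise ValueError("channel screen removed every channel")

    report = VarianceScreen(per_trial_variances=variances, retained_channels=kept_ch)
    alive = list(range(len(trials)))
    while True:
        pool = variances[np.ix_(alive, kept_ch)]
        var = pool.ravel()
        p90, p10 = np.percentile(var, [90, 10])
        threshold = p90 + 3.0 * (p90 - p10)
        report.threshold_history.append(float(threshold))
        doomed = [i for i in alive if variances[i, kept_ch].max() > threshold]
        if not doomed:
            break
        for i in doomed:
            report.removed_trial_ids.append(trials[i].trial_id or str(i))
        alive = [i for i in alive if i not in doomed]
        if not alive:
            raise ValueError("variance rule removed every trial")
    return [trials[i] for i in alive], report
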