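"""EOG blink-threshold calibration and "dissatisfied trial" gating.

During the EOG run the subject blinks on cue; the peak absolute amplitude
of each 2-s blink trace is its feature.  Features more than twice the
median or below half the median are pruned as outliers, and the mean of
the survivors becomes the blink threshold.  During calibration runs a
trial whose confirmation-phase EOG peak strictly exceeds that threshold
is marked dissatisfied (the subject blinked deliberately to discard it)
and removed from the training set — trials are dropped, never cleaned or
relabelled.

"Peak" means maximum absolute value: blinks are biphasic and the
deflection polarity depends on electrode wiring.  Outlier bounds are
strict, so boundary features survive.  Only blink-labelled trials of the
EOG run feed calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BlinkCalibration", "blink_feature", "calibrate_threshold", "is_dissatisfied"]


@dataclass(frozen=True)
class BlinkCalibration:
    raw_features: tuple[float, ...]
    retained_features: tuple[float, ...]
    threshold: float

    def to_dict(self) -> dict:
        return {"raw_features": list(self.raw_features),
                "retained_features": list(self.retained_features),
                "threshold": self.threshold}

    @classmethod
    def from_dict(cls, d: dict) -> "BlinkCalibration":
        return cls(tuple(d["raw_features"]), tuple(d["retained_features"]),
                   float(d["threshold"]))


def blink_feature(trace: np.ndarray) -> float:
    """Peak absolute amplitude (uV) of a 2-s EOG epoch."""
    t = np.asarray(trace, dtype=float)
    if t.size == 0:
        raise ValueError("empty EOG trace")
    return float(np.max(np.abs(t)))


def calibrate_threshold(features) -> BlinkCalibration:
    """Prune outlier blink features and average the survivors.

    A feature is pruned iff it is strictly greater than twice the median
    or strictly less than half the median of the *input* features.  The
    threshold is the arithmetic mean of the survivors.
    """
    feats = np.asarray(list(features), dtype=float)
    if feats.size == 0:
        raise ValueError("no blink features to calibrate from")
    med = float(np.median(feats))
    keep = (feats <= 2.0 * med) & (feats >= med / 2.0)
    retained = feats[keep]
    if retained.size == 0:
        raise ValueError("outlier pruning removed every blink feature")
    return BlinkCalibration(raw_features=tuple(feats.tolist()),
                            retained_features=tuple(retained.tolist()),
                            threshold=float(retained.mean()))


def is_dissatisfied(confirmation_eog: np.ndarray,
                    calibration: BlinkCalibration) -> bool:
    """True iff the confirmation-phase EOG peak strictly exceeds the
    calibrated blink threshold."""
    if calibration is None:
        raise ValueError("blink calibration required")
    return blink_feature(confirmation_eog) > calibration.threshold
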