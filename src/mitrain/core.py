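"""Shared vocabulary of the two-class motor-imagery (MI) paradigm.

Everything downstream — the synthetic session generator, the EOG blink
gate, trial feedback, artifact rejection and the CSP+LDA decoder — speaks
in terms of the fixed objects defined here: the 21-electrode sensorimotor
montage (plus one prefrontal EOG channel), the trial timing scheme of a
calibration run, and the trial containers.

Class coding follows the convention used throughout the toolkit:
``1`` is right-hand MI, ``2`` is left-hand MI.  Every sample matrix has
channels as columns, in montage order; modules resolve electrode indices
through :class:`Montage`, never by hard-coded position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "CLASS_RIGHT",
    "CLASS_LEFT",
    "Montage",
    "TimingScheme",
    "RawTrial",
    "EpochedTrial",
    "TrainingSet",
    "standard_montage",
    "class_name",
]

CLASS_RIGHT = 1
CLASS_LEFT = 2

_ALL_LABELS = (
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
)
_LEFT_GROUP = ("FC5", "FC3", "FC1", "C5", "C3", "C1", "CP5", "CP3", "CP1")
_RIGHT_GROUP = ("FC2", "FC4", "FC6", "C2", "C4", "C6", "CP2", "CP4", "CP6")
_MIDLINE = ("FCz", "Cz", "CPz")

# Planar scalp positions (head-centred, unit-free) from the standard 10-20
# 2-D projection: three anterior-posterior rows (FC / C / CP) and seven
# lateral positions (5, 3, 1, z, 2, 4, 6).  Used for topographic export only.
_ROW_Y = {"FC": 0.35, "C": 0.0, "CP": -0.35}
_COL_X = {"5": -0.72, "3": -0.45, "1": -0.17, "z": 0.0,
          "2": 0.17, "4": 0.45, "6": 0.72}


def _coord(label: str) -> tuple[float, float]:
    row, col = label[:-1], label[-1]
    return (_COL_X[col], _ROW_Y[row])


@dataclass(frozen=True)
class Montage:
    """The fixed sensorimotor electrode layout plus the EOG channel.

    The 21 EEG electrodes split into a left group ``J1`` and a right group
    ``J2`` of nine electrodes each, and three midline electrodes that never
    enter hemispheric scoring.  The prefrontal channel named by
    :attr:`eog_label` carries the electrooculogram used for blink gating;
    it is recorded separately and is not a column of the trial matrices.
    """

    all_labels: tuple[str, ...] = _ALL_LABELS
    left_group: tuple[str, ...] = _LEFT_GROUP
    right_group: tuple[str, ...] = _RIGHT_GROUP
    midline: tuple[str, ...] = _MIDLINE
    eog_label: str = "Fp2"

    def __post_init__(self) -> None:
        lateral = set(self.left_group) | set(self.right_group) | set(self.midline)
        if lateral != set(self.all_labels):
            raise ValueError("left/right/midline groups must partition all_labels")
        if set(self.left_group) & set(self.right_group):
            raise ValueError("left and right groups overlap")

    @property
    def n_channels(self) -> int:
        return len(self.all_labels)

    def index(self, label: str) -> int:
        """Column index of ``label`` in every trial matrix."""
        return self.all_labels.index(label)

    @property
    def left_indices(self) -> np.ndarray:
        return np.array([self.index(l) for l in self.left_group])

    @property
    def right_indices(self) -> np.ndarray:
        return np.array([self.index(l) for l in self.right_group])

    @property
    def midline_indices(self) -> np.ndarray:
        return np.array([self.index(l) for l in self.midline])

    def coordinates(self) -> dict[str, tuple[float, float]]:
        """Planar (x, y) scalp positions for topographic export."""
        return {label: _coord(label) for label in self.all_labels}


@dataclass(frozen=True)
class TimingScheme:
    """Timing constants of one calibration trial, in seconds from MI-cue onset.

    The preparation phase precedes the cue and is not recorded; the 4-s MI
    window is sampled at 256 Hz (1024 rows); a 2-s confirmation window
    follows, during which only the EOG channel matters.  Sample windows are
    half-open ``[start, end)``, so the (0.5, 2.5) training window covers
    rows 128..639 — exactly 512 samples — and the three feedback segments
    contain 256, 512 and 768 samples.
    """

    sampling_rate: int = 256
    preparation_s: float = 2.0
    mi_s: float = 4.0
    confirmation_s: float = 2.0
    training_window_s: tuple[float, float] = (0.5, 2.5)
    feedback_segments_s: tuple[tuple[float, float], ...] = (
        (0.5, 1.5), (0.5, 2.5), (0.5, 3.5),
    )
    eog_task_s: float = 2.0

    def __post_init__(self) -> None:
        for lo, hi in self.feedback_segments_s:
            if not (0.0 <= lo < hi <= self.mi_s):
                raise ValueError("feedback segment outside the MI window")

    @property
    def n_mi_samples(self) -> int:
        return int(round(self.mi_s * self.sampling_rate))

    @property
    def n_epoch_samples(self) -> int:
        lo, hi = self.training_window_s
        return int(np.floor(hi * self.sampling_rate)) - int(np.floor(lo * self.sampling_rate))

    @property
    def n_confirmation_samples(self) -> int:
        return int(round(self.confirmation_s * self.sampling_rate))

    def segment_rows(self) -> list[tuple[int, int]]:
        """Half-open row ranges of the three feedback segments."""
        fs = self.sampling_rate
        return [(int(np.floor(lo * fs)), int(np.floor(hi * fs)))
                for lo, hi in self.feedback_segments_s]


@dataclass
class RawTrial:
    """One unprocessed calibration or testing trial.

    ``mi_samples`` is the 4-s MI window (1024 samples x 21 channels, uV);
    ``confirmation_eog`` the 2-s EOG trace that follows it (512 samples).
    """

    mi_samples: np.ndarray
    confirmation_eog: np.ndarray
    label: int
    trial_id: str = ""
    run_id: str = ""

    def __post_init__(self) -> None:
        self.mi_samples = np.asarray(self.mi_samples, dtype=float)
        self.confirmation_eog = np.asarray(self.confirmation_eog, dtype=float)
        if self.mi_samples.ndim != 2:
            raise ValueError("mi_samples must be 2-D (samples x channels)")
        if self.label not in (CLASS_RIGHT, CLASS_LEFT):
            raise ValueError(f"invalid class label: {self.label!r}")


@dataclass
class EpochedTrial:
    """A preprocessed MI trial restricted to the training window (512 x 21)."""

    samples: np.ndarray
    label: int
    satisfied: bool = True
    trial_id: str = ""
    run_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (samples x channels)")
        if self.label not in (CLASS_RIGHT, CLASS_LEFT):
            raise ValueError(f"invalid class label: {self.label!r}")


@dataclass
class TrainingSet:
    """Epoched trials surviving gating/rejection, with per-run provenance.

    ``n_after_gating`` and ``n_final`` map run ids to trial counts after
    the blink gate and after variance-based artifact rejection.
    """

    trials: list = field(default_factory=list)
    n_after_gating: dict = field(default_factory=dict)
    n_final: dict = field(default_factory=dict)


def standard_montage() -> Montage:
    """The fixed 21-electrode sensorimotor montage with EOG at Fp2."""
    return Montage()


def class_name(label: int) -> str:
    """Human-readable name for a class label (1 → right-hand, 2 → left-hand)."""
    if label == CLASS_RIGHT:
        return "right-hand"
    if label == CLASS_LEFT:
        return "left-hand"
    raise ValueError(f"invalid class label: {label!r}")
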