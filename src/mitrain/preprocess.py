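"""Temporal filtering and epoch extraction.

Each 4-s MI window is band-pass filtered between 0.1 and 30 Hz with an
order-8 Butterworth filter and band-stop ("notch") filtered between 48 and
52 Hz, then the training epoch is cut from 0.5 to 2.5 s after cue onset.
The same chain is applied to calibration and testing trials.

Filter order convention: ``bandpass_order`` is the overall transfer-function
order of the band-pass (an order-8 band-pass has four pole pairs per edge,
i.e. scipy's ``butter(4, ..., btype="band")``).  Zero-phase (forward-backward)
application is the default for offline analysis; each pass applies the
designed order, and the squared magnitude response is what the attenuation
figures below refer to.  A causal mode is provided for code paths that
mirror the real-time loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["FilterSpec", "filter_trial", "extract_epoch"]


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass + band-stop filter chain parameters.

    ``phase_mode`` is ``"zero"`` (forward-backward, no group delay) or
    ``"causal"`` (single forward pass, as a real-time system would run).
    """

    bandpass_hz: tuple[float, float] = (0.1, 30.0)
    bandpass_order: int = 8
    notch_hz: tuple[float, float] = (48.0, 52.0)
    notch_order: int = 8
    phase_mode: str = "zero"
    sampling_rate: float = 256.0

    def __post_init__(self) -> None:
        lo, hi = self.bandpass_hz
        nyq = self.sampling_rate / 2.0
        if not (0.0 < lo < hi < nyq):
            raise ValueError("band edges must satisfy 0 < low < high < Nyquist")
        if self.phase_mode not in ("zero", "causal"):
            raise ValueError("phase_mode must be 'zero' or 'causal'")

    def sos(self) -> np.ndarray:
        """Second-order sections of the full band-pass + band-stop cascade."""
        bp = signal.butter(self.bandpass_order // 2, self.bandpass_hz,
                           btype="bandpass", fs=self.sampling_rate, output="sos")
        notch = signal.butter(self.notch_order // 2, self.notch_hz,
                              btype="bandstop", fs=self.sampling_rate, output="sos")
        return np.vstack([bp, notch])


def filter_trial(samples: np.ndarray, spec: FilterSpec | None = None) -> np.ndarray:
    """Apply the band-pass + notch cascade along the time axis (axis 0).

    Returns an array of the same shape.  Raises on non-finite input or on
    signals too short for stable (filtfilt-padded) filtering.
    """
    if spec is None:
        spec = FilterSpec()
    x = np.asarray(samples, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples")
    sos = spec.sos()
    min_len = 3 * (2 * sos.shape[0] + 1)
    if x.shape[0] <= min_len:
        raise ValueError(f"need more than {min_len} samples, got {x.shape[0]}")
    if spec.phase_mode == "zero":
        return signal.sosfiltfilt(sos, x, axis=0)
    return signal.sosfilt(sos, x, axis=0)


def extract_epoch(mi_samples: np.ndarray,
                  window_s: tuple[float, float] = (0.5, 2.5),
                  sampling_rate: float = 256.0) -> np.ndarray:
    """Cut the half-open window ``[start, end)`` out of a trial.

    Rows ``floor(start*fs) .. floor(end*fs)-1`` are returned, so the default
    (0.5, 2.5) window of a 4-s, 256-Hz trial yields rows 128..639 — a
    512 x n_channels epoch.
    """
    x = np.asarray(mi_samples)
    lo, hi = window_s
    if lo < 0 or lo >= hi:
        raise ValueError("window must satisfy 0 <= start < end")
    start = int(np.floor(lo * sampling_rate))
    stop = int(np.floor(hi * sampling_rate))
    if stop > x.shape[0]:
        raise ValueError(
            f"window ({lo}, {hi}) s exceeds the {x.shape[0] / sampling_rate:g}-s trial")
    return x[start:stop]
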