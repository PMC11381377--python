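"""Synthetic EEG/EOG session generator.

The generator produces sessions with the statistical structure the
training paradigm assumes, so every downstream stage can be exercised
without recorded data:

* an ongoing mu oscillation (default 10 Hz) on the lateral electrode
  groups whose envelope, from 0.5 s after cue onset, is multiplicatively
  reduced on the hemisphere contralateral to the imagined hand (ERD) and
  increased ipsilaterally (ERS);
* unmodulated mu on the midline electrodes;
* broadband background noise on every channel (white by default, 1/f
  "pink" optionally, to stress the filters);
* occasional artifact trials: a large, slow movement/electrode-type
  deflection (within the analysis band, so filtering does not remove it)
  on one to three random channels, scaled to a configurable multiple of
  the typical clean channel variance;
* EOG confirmation traces with or without a large biphasic blink
  deflection, and a dedicated EOG calibration run of labelled blink /
  no-blink trials.

ERD is modelled as a multiplicative envelope change of the ongoing
rhythm, not an additive component: for a right-hand trial (class 1) the
left-group envelope is scaled by ``1 - effect_size`` and the right-group
envelope by ``1 + effect_size`` (mirrored for class 2).  Because the
baseline used downstream is the mean envelope over the full 4-s window,
the unmodulated first 0.5 s guarantees that contralateral deviations come
out negative and ipsilateral ones positive, which is exactly the sign
structure the hemispheric scoring expects.

One integer seed drives a splittable per-trial stream
(`numpy.random.SeedSequence.spawn`), so any single trial is reproducible
without regenerating the whole session.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import CLASS_LEFT, CLASS_RIGHT, Montage, RawTrial, TimingScheme, standard_montage

__all__ = [
    "SimConfig",
    "EOGTrial",
    "SimulatedSession",
    "simulate_mi_trial",
    "simulate_eog_trace",
    "simulate_session",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults define the study conditions.

    ``effect_size`` is the fractional envelope change: the contralateral mu
    envelope is multiplied by ``1 - effect_size`` and the ipsilateral one
    by ``1 + effect_size`` during the MI window.  Amplitudes are in uV.
    """

    effect_size: float = 0.4
    mu_freq_hz: float = 10.0
    noise_sd: float = 3.0
    mu_amp: float = 10.0
    blink_amp: float = 300.0
    p_artifact: float = 0.05
    p_blink: float = 0.1
    trials_per_run: int = 20
    n_cal_runs: int = 6
    n_test_runs: int = 4
    seed: int = 0
    artifact_var_factor: float = 20.0
    noise_color: str = "white"
    erd_onset_s: float = 0.5
    deliberate_blink_scale: float = 1.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.effect_size < 1.0):
            raise ValueError("effect_size must lie in [0, 1)")
        for name in ("noise_sd", "mu_amp", "blink_amp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("p_artifact", "p_blink"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_color not in ("white", "pink"):
            raise ValueError("noise_color must be 'white' or 'pink'")


@dataclass
class EOGTrial:
    """One 2-s trace of the EOG calibration run, with its blink label."""

    trace: np.ndarray
    blink: bool
    trial_id: str = ""


@dataclass
class SimulatedSession:
    """A full simulated session: EOG run, calibration runs, testing runs.

    ``ground_truth`` is a DataFrame with one row per MI trial (columns:
    kind, run, trial_id, label, blink, artifact).
    """

    eog_run: list
    calibration_runs: list
    testing_runs: list
    ground_truth: pd.DataFrame
    config: SimConfig = field(default_factory=SimConfig)


def _noise(rng: np.random.Generator, shape: tuple, sd: float, color: str) -> np.ndarray:
    white = rng.normal(0.0, 1.0, shape)
    if color == "white":
        return sd * white
    # 1/f amplitude shaping along axis 0, renormalised to unit variance.
    n = shape[0]
    spec = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.where(freqs > 0, 1.0 / np.sqrt(np.maximum(freqs, freqs[1])), 0.0)
    shaped = np.fft.irfft(spec * scale.reshape(-1, *([1] * (white.ndim - 1))), n=n, axis=0)
    shaped /= shaped.std(axis=0, keepdims=True)
    return sd * shaped


def simulate_mi_trial(label: int, config: SimConfig, rng: np.random.Generator,
                      montage: Montage | None = None,
                      timing: TimingScheme | None = None,
                      artifact: bool = False,
                      blink: bool = False,
                      trial_id: str = "", run_id: str = "") -> RawTrial:
    """Generate one raw MI trial (4-s EEG window + 2-s confirmation EOG).

    The contralateral lateral group carries ERD (envelope x(1-effect)),
    the ipsilateral group ERS (x(1+effect)); modulation starts at
    ``erd_onset_s`` after cue onset.  ``artifact`` adds broadband noise
    scaled so the total background variance is about
    ``artifact_var_factor`` times the clean level; ``blink`` inserts a
    blink deflection into the confirmation trace.
    """
    if label not in (CLASS_RIGHT, CLASS_LEFT):
        raise ValueError(f"invalid class label: {label!r}")
    montage = montage or standard_montage()
    timing = timing or TimingScheme()
    fs = timing.sampling_rate
    n = timing.n_mi_samples
    t = np.arange(n) / fs

    onset = t >= config.erd_onset_s

    # class 1 (right hand): contralateral = left group.
    contra_idx = montage.left_indices if label == CLASS_RIGHT else montage.right_indices
    ipsi_idx = montage.right_indices if label == CLASS_RIGHT else montage.left_indices

    envelope = np.ones((n, montage.n_channels))
    envelope[np.ix_(onset, contra_idx)] = 1.0 - config.effect_size
    envelope[np.ix_(onset, ipsi_idx)] = 1.0 + config.effect_size

    phases = rng.uniform(0, 2 * np.pi, montage.n_channels)
    mu = config.mu_amp * envelope * np.sin(
        2 * np.pi * config.mu_freq_hz * t[:, None] + phases[None, :])

    x = mu + _noise(rng, (n, montage.n_channels), config.noise_sd, config.noise_color)
    if artifact:
        # Movement/electrode artifact: a large, slow (in-band) deflection on a
        # small random subset of channels, scaled so the affected channel's
        # variance is about artifact_var_factor x the typical clean level.
        from scipy import signal as _signal

        n_aff = int(rng.integers(1, 4))
        chans = rng.choice(montage.n_channels, size=n_aff, replace=False)
        target_sd = np.sqrt(config.artifact_var_factor
                            * (config.mu_amp ** 2 / 2.0 + config.noise_sd ** 2))
        sos = _signal.butter(2, 8.0, btype="lowpass", fs=fs, output="sos")
        slow = _signal.sosfilt(sos, rng.normal(0.0, 1.0, (n, n_aff)), axis=0)
        slow = slow / slow.std(axis=0, keepdims=True) * target_sd
        x[:, chans] += slow

    eog = simulate_eog_trace(blink, config, rng, timing=timing,
                             amplitude_scale=config.deliberate_blink_scale)
    return RawTrial(mi_samples=x, confirmation_eog=eog, label=label,
                    trial_id=trial_id, run_id=run_id)


def simulate_eog_trace(blink: bool, config: SimConfig, rng: np.random.Generator,
                       timing: TimingScheme | None = None,
                       amplitude_scale: float = 1.0) -> np.ndarray:
    """One 2-s EOG trace; a blink is a biphasic deflection with peak
    amplitude at least ``blink_amp`` (drawn in [1.2, 1.6] x blink_amp,
    times ``amplitude_scale``).

    Deliberate trial-discarding blinks during the confirmation phase are
    generated with ``amplitude_scale`` > 1 (see
    ``SimConfig.deliberate_blink_scale``): a subject rejecting a trial
    blinks harder than one following the casual cue of the EOG run, which
    is what makes the mean of the EOG-run features a usable threshold.
    """
    timing = timing or TimingScheme()
    n = int(round(timing.eog_task_s * timing.sampling_rate))
    trace = _noise(rng, (n,), config.noise_sd, config.noise_color)
    if blink:
        fs = timing.sampling_rate
        t = np.arange(n) / fs
        center = rng.uniform(0.5, timing.eog_task_s - 0.5)
        width = 0.08  # s; typical blink half-width
        shape = (t - center) * np.exp(-((t - center) ** 2) / (2 * width ** 2))
        shape = shape / np.max(np.abs(shape))
        peak = config.blink_amp * amplitude_scale * rng.uniform(1.2, 1.6)
        trace = trace + peak * shape
    return trace


def _balanced_labels(n: int, rng: np.random.Generator) -> np.ndarray:
    labels = np.array([CLASS_RIGHT, CLASS_LEFT] * (n // 2))
    rng.shuffle(labels)
    return labels


def simulate_session(config: SimConfig) -> SimulatedSession:
    """Assemble a full session per the experimental layout: one EOG run of
    20 labelled trials, ``n_cal_runs`` calibration runs of
    ``trials_per_run`` class-balanced trials, and ``n_test_runs`` testing
    runs of 10 class-balanced trials (five per MI type)."""
    root = np.random.SeedSequence(config.seed)
    eog_ss, cal_ss, test_ss, layout_ss = root.spawn(4)
    layout_rng = np.random.default_rng(layout_ss)

    # EOG run: half blink / half no-blink, shuffled.
    eog_flags = np.array([True] * 10 + [False] * 10)
    layout_rng.shuffle(eog_flags)
    eog_run = []
    for i, (flag, ss) in enumerate(zip(eog_flags, eog_ss.spawn(20))):
        rng = np.random.default_rng(ss)
        eog_run.append(EOGTrial(trace=simulate_eog_trace(bool(flag), config, rng),
                                blink=bool(flag), trial_id=f"eog-t{i:02d}"))

    records = []

    def _make_runs(kind: str, n_runs: int, trials_per: int, ss: np.random.SeedSequence):
        runs = []
        run_seeds = ss.spawn(n_runs)
        for r in range(n_runs):
            run_id = f"{kind}{r + 1}"
            trial_seeds = run_seeds[r].spawn(trials_per)
            labels = _balanced_labels(trials_per, layout_rng)
            run = []
            for i in range(trials_per):
                rng = np.random.default_rng(trial_seeds[i])
                blink = kind == "cal" and layout_rng.uniform() < config.p_blink
                artifact = layout_rng.uniform() < config.p_artifact
                trial_id = f"{run_id}-t{i:02d}"
                run.append(simulate_mi_trial(
                    int(labels[i]), config, rng, artifact=artifact, blink=blink,
                    trial_id=trial_id, run_id=run_id))
                records.append(dict(kind=kind, run=run_id, trial_id=trial_id,
                                    label=int(labels[i]), blink=blink,
                                    artifact=artifact))
            runs.append(run)
        return runs

    calibration_runs = _make_runs("cal", config.n_cal_runs, config.trials_per_run, cal_ss)
    testing_runs = _make_runs("test", config.n_test_runs, 10, test_ss)

    return SimulatedSession(eog_run=eog_run, calibration_runs=calibration_runs,
                            testing_runs=testing_runs,
                            ground_truth=pd.DataFrame.from_records(records),
                            config=config)
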