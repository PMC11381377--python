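"""Session readers/writers and manifests.

The canonical on-disk format is plain delimited text matrices plus a JSON
manifest: portable, diff-able, and lossless (floats are written with 17
significant digits, which round-trips IEEE doubles exactly).  EDF
recordings can be imported (requires mne); channels are mapped onto the
montage by name, so permuted channel order in the file is harmless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import Montage, RawTrial, standard_montage
from .simulate import EOGTrial, SimConfig, SimulatedSession

__all__ = ["write_session", "read_session", "write_run", "read_run", "read_edf_run"]

_FMT = "%.17g"


def _save(path: Path, arr: np.ndarray) -> None:
    np.savetxt(path, np.atleast_2d(arr), fmt=_FMT, delimiter="\t")


def _load(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"manifest references missing file: {path}")
    return np.loadtxt(path, delimiter="\t")


def write_run(run: list[RawTrial], out_dir: Path, kind: str = "calibration",
              montage: Montage | None = None) -> Path:
    """Write one run of raw trials; returns the manifest path."""
    montage = montage or standard_montage()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, t in enumerate(run):
        stem = t.trial_id or f"t{i:02d}"
        mi_file = f"{stem}_mi.tsv"
        eog_file = f"{stem}_eog.tsv"
        _save(out_dir / mi_file, t.mi_samples)
        _save(out_dir / eog_file, t.confirmation_eog)
        entries.append({"trial_id": stem, "run_id": t.run_id, "label": t.label,
                        "mi_file": mi_file, "eog_file": eog_file})
    manifest = {"kind": kind, "sampling_rate": 256,
                "montage": list(montage.all_labels),
                "eog_label": montage.eog_label, "trials": entries}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_run(manifest_path: Path) -> list[RawTrial]:
    """Read a run back from its manifest (lossless round-trip)."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    trials = []
    for e in manifest["trials"]:
        mi = _load(base / e["mi_file"])
        eog = _load(base / e["eog_file"]).ravel()
        trials.append(RawTrial(mi_samples=mi, confirmation_eog=eog,
                               label=int(e["label"]), trial_id=e["trial_id"],
                               run_id=e.get("run_id", "")))
    return trials


def write_session(session: SimulatedSession, out_dir: Path) -> Path:
    """Write a whole simulated session (EOG + calibration + testing runs)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    montage = standard_montage()

    eog_dir = out_dir / "eog"
    eog_dir.mkdir(exist_ok=True)
    eog_entries = []
    for t in session.eog_run:
        fname = f"{t.trial_id}.tsv"
        _save(eog_dir / fname, t.trace)
        eog_entries.append({"trial_id": t.trial_id, "blink": bool(t.blink),
                            "file": f"eog/{fname}"})

    run_entries = []
    for kind, runs in (("calibration", session.calibration_runs),
                       ("testing", session.testing_runs)):
        for run in runs:
            run_id = run[0].run_id
            write_run(run, out_dir / run_id, kind=kind, montage=montage)
            run_entries.append({"kind": kind, "run_id": run_id,
                                "manifest": f"{run_id}/manifest.json"})

    session.ground_truth.to_csv(out_dir / "ground_truth.csv", index=False)
    top = {"session_kind": "trial-feedback", "sampling_rate": 256,
           "montage": list(montage.all_labels), "eog_label": montage.eog_label,
           "config": vars(session.config) | {}, "eog_run": eog_entries,
           "runs": run_entries, "ground_truth": "ground_truth.csv"}
    path = out_dir / "session.json"
    path.write_text(json.dumps(top, indent=1, default=str))
    return path


def read_session(session_path: Path) -> SimulatedSession:
    import pandas as pd

    session_path = Path(session_path)
    top = json.loads(session_path.read_text())
    base = session_path.parent
    eog_run = []
    for e in top["eog_run"]:
        eog_run.append(EOGTrial(trace=_load(base / e["file"]).ravel(),
                                blink=bool(e["blink"]), trial_id=e["trial_id"]))
    cal_runs, test_runs = [], []
    for e in top["runs"]:
        run = read_run(base / e["manifest"])
        (cal_runs if e["kind"] == "calibration" else test_runs).append(run)
    gt = pd.read_csv(base / top["ground_truth"])
    known = SimConfig.__dataclass_fields__
    cfg = SimConfig(**{k: _coerce(known[k], v)
                       for k, v in top.get("config", {}).items() if k in known})
    return SimulatedSession(eog_run=eog_run, calibration_runs=cal_runs,
                            testing_runs=test_runs, ground_truth=gt, config=cfg)


def _coerce(field, value):
    for typ in (int, float):
        if field.type in (typ.__name__, typ):
            return typ(value)
    return value


def read_edf_run(path: Path, montage: Montage | None = None):
    """Import an EDF recording as (samples, channel_labels) with columns
    reordered to montage order; the EOG channel, if present, is returned
    separately.  Requires mne."""
    import mne

    montage = montage or standard_montage()
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data(units="uV").T  # samples x channels
    names = [n.strip() for n in raw.ch_names]
    missing = [l for l in montage.all_labels if l not in names]
    if missing:
        raise ValueError(f"EDF is missing montage channels: {missing}")
    order = [names.index(l) for l in montage.all_labels]
    eeg = data[:, order]
    eog = data[:, names.index(montage.eog_label)] \
        if montage.eog_label in names else None
    return eeg, eog
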