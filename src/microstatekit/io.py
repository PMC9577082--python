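"""Readers and writers for recordings, cohorts and analysis products.

Real recordings are read from EDF or BrainVision (.vhdr/.eeg/.vmrk)
via MNE and converted to microvolt arrays; channel names are normalized
to upper-case 10-20 labels on the way in.  Synthetic cohorts are stored
in a simple HDF5 layout::

    /                 attrs: sfreq, ch_names, microstatekit_version
    /subjects/<id>    dataset "data" (channels x samples, float32, uV)
                      attrs: group

Prototypes are serialized as JSON (channel names + map values) and CSV;
label sequences as per-subject CSV (frame, epoch, label, fit).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .microstates import LabelSequence, MicrostatePrototypes
from .preprocessing import EEGRecording

__all__ = [
    "normalize_channel_name",
    "read_recording",
    "write_cohort_h5",
    "read_cohort_h5",
    "write_prototypes_json",
    "read_prototypes_json",
    "write_prototypes_csv",
    "write_labels_csv",
    "read_labels_csv",
]


def normalize_channel_name(name: str) -> str:
    """Upper-case 10-20 label with surrounding whitespace stripped."""
    return name.strip().upper()


def read_recording(path) -> EEGRecording:
    """Read an EDF or BrainVision recording into microvolts."""
    import mne

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif suffix == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported recording format: {path.name!r}")
    picks = mne.pick_types(raw.info, eeg=True, eog=False, misc=False)
    data = raw.get_data(picks=picks) * 1e6  # volts -> microvolts
    names = [normalize_channel_name(raw.ch_names[i]) for i in picks]
    return EEGRecording(data=data, sfreq=float(raw.info["sfreq"]),
                        ch_names=names, reference="as-recorded")


def write_cohort_h5(path, recordings: dict, groups: dict | None = None) -> None:
    from . import __version__

    with h5py.File(path, "w") as f:
        first = next(iter(recordings.values()))
        f.attrs["sfreq"] = first.sfreq
        f.attrs["ch_names"] = [str(c) for c in first.ch_names]
        f.attrs["microstatekit_version"] = __version__
        subj = f.create_group("subjects")
        for sid, rec in recordings.items():
            g = subj.create_group(sid)
            g.create_dataset("data", data=rec.data.astype(np.float32),
                             compression="gzip", compression_opts=4)
            if groups and sid in groups:
                g.attrs["group"] = groups[sid]


def read_cohort_h5(path) -> dict:
    """Returns subject_id -> :class:`EEGRecording` (float64, uV)."""
    out = {}
    with h5py.File(path, "r") as f:
        sfreq = float(f.attrs["sfreq"])
        ch_names = [str(c) for c in f.attrs["ch_names"]]
        for sid in sorted(f["subjects"]):
            data = np.asarray(f["subjects"][sid]["data"], dtype=np.float64)
            out[sid] = EEGRecording(data=data, sfreq=sfreq, ch_names=ch_names,
                                    reference="average")
    return out


def write_prototypes_json(path, p: MicrostatePrototypes, ch_names) -> None:
    payload = {
        "labels": list(p.labels),
        "ch_names": list(ch_names),
        "maps": np.asarray(p.maps).tolist(),
        "gev": p.gev,
        "n_restarts": p.n_restarts,
        "n_iterations_used": p.n_iterations_used,
        "seed": p.seed,
        "empty_cluster_events": p.empty_cluster_events,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_prototypes_json(path) -> tuple:
    d = json.loads(Path(path).read_text())
    p = MicrostatePrototypes(maps=np.asarray(d["maps"], float), labels=d["labels"],
                             gev=float(d["gev"]), n_restarts=d.get("n_restarts", 0),
                             n_iterations_used=d.get("n_iterations_used", 0),
                             seed=d.get("seed"))
    return p, d["ch_names"]


def write_prototypes_csv(path, p: MicrostatePrototypes, ch_names) -> None:
    df = pd.DataFrame(np.asarray(p.maps).T, index=list(ch_names), columns=list(p.labels))
    df.index.name = "channel"
    df.to_csv(path)


def write_labels_csv(path, ls: LabelSequence) -> None:
    n_ep, n_t = ls.labels.shape
    ep = np.repeat(np.arange(n_ep), n_t)
    frame = np.tile(np.arange(n_t), n_ep)
    lab = [ls.class_labels[i] for i in ls.labels.ravel()]
    pd.DataFrame({"epoch": ep, "frame": frame, "label": lab,
                  "fit": ls.fit.ravel()}).to_csv(path, index=False)


def read_labels_csv(path, sfreq: float, class_labels) -> LabelSequence:
    df = pd.read_csv(path)
    n_ep = int(df["epoch"].max()) + 1
    n_t = int(df["frame"].max()) + 1
    lut = {lab: i for i, lab in enumerate(class_labels)}
    labels = np.asarray([lut[v] for v in df["label"]],
                        dtype=np.int32).reshape(n_ep, n_t)
    fit = df["fit"].to_numpy().reshape(n_ep, n_t)
    return LabelSequence(labels=labels, fit=fit, sfreq=sfreq,
                         class_labels=list(class_labels))
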