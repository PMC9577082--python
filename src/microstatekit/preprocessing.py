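"""Deterministic preprocessing of continuous resting-state EEG.

The stage order is fixed: average reference -> 1-20 Hz band-pass ->
downsample to 250 Hz -> 2 s epochs -> 80 uV amplitude rejection ->
minimum-epoch inclusion gate.  Every stage is a pure function of its
input; there is no randomness anywhere in this module.

An optional time-window crop (e.g. minutes 2-7 of a longer recording)
can be applied before all stages.  Artifact correction by ICA is a
documented no-op hook (``ica_correct``): the synthetic cohorts this
package ships with contain no ocular or muscle artifacts, and real-data
users can plug a corrector callable into the same slot.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Callable, Optional

import numpy as np
from scipy import signal as sps

__all__ = [
    "EEGRecording",
    "EpochedEEG",
    "PreprocessingParams",
    "SubjectExcluded",
    "average_reference",
    "bandpass",
    "resample",
    "crop",
    "epoch",
    "reject_amplitude",
    "require_min_epochs",
    "preprocess_recording",
]


class SubjectExcluded(Exception):
    """A subject failed an inclusion gate (e.g. fewer than 100 clean epochs)."""

    def __init__(self, subject_id: str, reason: str):
        self.subject_id = subject_id
        self.reason = reason
        super().__init__(f"subject {subject_id!r} excluded: {reason}")


@dataclass
class EEGRecording:
    """Continuous multichannel EEG in microvolts.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Scalp potentials in uV.
    sfreq : float
        Sampling rate in Hz.
    ch_names : list of str
        Channel names, same order as the rows of ``data``.
    reference : str
        Free-text reference descriptor ("average" after re-referencing).
    """

    data: np.ndarray
    sfreq: float
    ch_names: list
    reference: str = "unknown"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] < 2:
            raise ValueError("a recording needs at least 2 channels")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("ch_names length does not match channel count")
        if not self.sfreq > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq


@dataclass
class EpochedEEG:
    """EEG cut into fixed-length, non-overlapping epochs.

    ``kept_indices`` are indices into the original epochization and stay
    strictly increasing through rejection; ``rejection_log`` records one
    entry per removed epoch (index, worst channel, worst value).
    """

    data: np.ndarray  # (n_epochs, n_channels, n_samples)
    sfreq: float
    ch_names: list
    epoch_length_s: float
    kept_indices: list = field(default_factory=list)
    rejection_log: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("epoched data must be 3-D (epochs x channels x samples)")
        n_per = self.epoch_length_s * self.sfreq
        if abs(n_per - round(n_per)) > 1e-9 or round(n_per) != self.data.shape[2]:
            raise ValueError("samples per epoch must equal epoch_length_s * sfreq exactly")
        if not self.kept_indices:
            self.kept_indices = list(range(self.data.shape[0]))
        if np.any(np.diff(self.kept_indices) <= 0):
            raise ValueError("kept-epoch indices must be strictly increasing")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples_per_epoch(self) -> int:
        return self.data.shape[2]


@dataclass
class PreprocessingParams:
    """All knobs of the fixed preprocessing chain, with study defaults."""

    low_hz: float = 1.0
    high_hz: float = 20.0
    filter_order: int = 4
    resample_hz: float = 250.0
    epoch_length_s: float = 2.0
    reject_threshold_uv: float = 80.0
    min_epochs: int = 100
    window_start_s: Optional[float] = None
    window_end_s: Optional[float] = None


def average_reference(rec: EEGRecording) -> EEGRecording:
    """Re-reference to the mean of all electrodes (zero channel-mean per sample)."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=data, reference="average")


def bandpass(rec: EEGRecording, low_hz: float = 1.0, high_hz: float = 20.0,
             order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass (forward-backward, SOS realization)."""
    if high_hz <= low_hz:
        raise ValueError("high cut-off must exceed low cut-off")
    if high_hz >= rec.sfreq / 2:
        raise ValueError("high cut-off must be below the Nyquist frequency")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass",
                     fs=rec.sfreq, output="sos")
    data = sps.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=data)


def resample(rec: EEGRecording, target_hz: float = 250.0) -> EEGRecording:
    """Anti-aliased polyphase downsampling; identity when already at target."""
    if target_hz > rec.sfreq:
        raise ValueError("upsampling is out of contract (target above current rate)")
    if target_hz == rec.sfreq:
        return replace(rec, data=rec.data.copy())
    frac = Fraction(target_hz / rec.sfreq).limit_denominator(10_000)
    data = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return replace(rec, data=data, sfreq=float(target_hz))


def crop(rec: EEGRecording, start_s: Optional[float], end_s: Optional[float]) -> EEGRecording:
    """Select a time window [start_s, end_s) before any other stage."""
    i0 = 0 if start_s is None else int(round(start_s * rec.sfreq))
    i1 = rec.n_samples if end_s is None else int(round(end_s * rec.sfreq))
    i0, i1 = max(i0, 0), min(i1, rec.n_samples)
    if i1 <= i0:
        raise ValueError("empty time window")
    return replace(rec, data=rec.data[:, i0:i1].copy())


def epoch(rec: EEGRecording, length_s: float = 2.0) -> EpochedEEG:
    """Cut into consecutive non-overlapping epochs; trailing partial discarded."""
    n_per = length_s * rec.sfreq
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError("epoch length must be an integer number of samples")
    n_per = int(round(n_per))
    n_ep = rec.n_samples // n_per
    if n_ep < 1:
        raise ValueError("recording shorter than one epoch")
    data = rec.data[:, : n_ep * n_per].reshape(rec.n_channels, n_ep, n_per)
    data = np.ascontiguousarray(np.moveaxis(data, 1, 0))
    return EpochedEEG(data=data, sfreq=rec.sfreq, ch_names=list(rec.ch_names),
                      epoch_length_s=float(length_s))


def reject_amplitude(ep: EpochedEEG, threshold_uv: float = 80.0) -> EpochedEEG:
    """Drop epochs whose absolute amplitude strictly exceeds the threshold.

    The bound is strict ("exceeding"): an epoch whose extreme value equals
    the threshold exactly is kept.  The log records, for each removed
    epoch, its original index and the offending channel/value.
    """
    absmax = np.abs(ep.data).max(axis=2)  # (n_epochs, n_channels)
    bad = absmax.max(axis=1) > threshold_uv
    log = list(ep.rejection_log)
    for i in np.flatnonzero(bad):
        ch = int(absmax[i].argmax())
        log.append({
            "epoch": int(ep.kept_indices[i]),
            "channel": ep.ch_names[ch],
            "max_abs_uv": float(absmax[i, ch]),
            "threshold_uv": float(threshold_uv),
        })
    keep = ~bad
    kept = [idx for idx, k in zip(ep.kept_indices, keep) if k]
    return EpochedEEG(data=ep.data[keep], sfreq=ep.sfreq, ch_names=ep.ch_names,
                      epoch_length_s=ep.epoch_length_s, kept_indices=kept,
                      rejection_log=log)


def require_min_epochs(ep: EpochedEEG, minimum: int = 100,
                       subject_id: str = "?") -> EpochedEEG:
    """Pass through unchanged, or raise :class:`SubjectExcluded`."""
    if ep.n_epochs < minimum:
        raise SubjectExcluded(subject_id,
                              f"only {ep.n_epochs} clean epochs (minimum {minimum})")
    return ep


def preprocess_recording(rec: EEGRecording, params: PreprocessingParams,
                         subject_id: str = "?",
                         ica_correct: Optional[Callable[[EEGRecording], EEGRecording]] = None,
                         ) -> tuple[EpochedEEG, list]:
    """Run the full fixed-order chain; returns the epochs and a stage log.

    ``ica_correct`` is the slot where step 4 of the original chain (ICA
    artifact correction) would act; it defaults to a no-op because the
    synthetic cohorts contain no artifacts to correct.
    """
    log = []

    def _log(stage, **info):
        log.append({"stage": stage, **info})

    if params.window_start_s is not None or params.window_end_s is not None:
        rec = crop(rec, params.window_start_s, params.window_end_s)
        _log("crop", start_s=params.window_start_s, end_s=params.window_end_s,
             samples=rec.n_samples)
    rec = average_reference(rec)
    _log("average_reference", channels=rec.n_channels)
    rec = bandpass(rec, params.low_hz, params.high_hz, params.filter_order)
    _log("bandpass", low_hz=params.low_hz, high_hz=params.high_hz,
         order=params.filter_order)
    rec = resample(rec, params.resample_hz)
    _log("resample", sfreq=rec.sfreq, samples=rec.n_samples)
    if ica_correct is not None:
        rec = ica_correct(rec)
        _log("ica_correct", applied=True)
    else:
        _log("ica_correct", applied=False, note="no-op stage")
    ep = epoch(rec, params.epoch_length_s)
    _log("epoch", epoch_length_s=params.epoch_length_s, epochs=ep.n_epochs)
    ep = reject_amplitude(ep, params.reject_threshold_uv)
    _log("reject_amplitude", threshold_uv=params.reject_threshold_uv,
         epochs_in=len(ep.rejection_log) + ep.n_epochs, epochs_out=ep.n_epochs)
    ep = require_min_epochs(ep, params.min_epochs, subject_id)
    _log("require_min_epochs", minimum=params.min_epochs, epochs=ep.n_epochs)
    return ep, log
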