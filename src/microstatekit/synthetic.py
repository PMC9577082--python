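"""Ground-truth synthetic two-group microstate EEG cohorts.

The generator emulates an eyes-closed resting-state study of 25 young
smokers and 25 non-smoking controls: 64-channel recordings in which the
scalp field at every instant is one of four canonical microstate
topographies (A-D), amplitude-modulated by a rectified alpha-band
envelope with random polarity flips, plus sensor noise.  The state
sequence is semi-Markov: the next class is drawn among the other
classes, and the run length comes from a discretized gamma distribution
whose mean is that subject's class mean duration.

Planted structure mirrors the effect directions reported for nicotine
dependence: smokers visit class C less often (reduced entry weight ->
longer inter-visit gaps), carry a longer class-D mean duration, and
within smokers an FTND-like score couples negatively to the class-D
duration.  Every per-subject truth (label sequence, parameters,
covariates) is recorded so that downstream stages have a recoverable
ground truth.

All randomness flows from one master seed; subject ``i`` draws from an
independent substream keyed by ``(seed, i)``, so any subject's recording
can be regenerated in isolation, bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps

from .features import subject_parameters, parameters_row
from .microstates import LabelSequence, spatial_correlation
from .preprocessing import EEGRecording

__all__ = [
    "Montage",
    "TemplateSet",
    "GenerativeSpec",
    "GroundTruth",
    "default_montage",
    "make_canonical_templates",
    "simulate_label_sequence",
    "render_eeg",
    "simulate_cohort",
]

CLASS_LABELS = ("A", "B", "C", "D")

#: 64-channel 10-20/10-10 layout (BrainAmp-style cap).
DEFAULT_64 = [
    "Fp1", "Fz", "F3", "F7", "FT9", "FC5", "FC1", "C3", "T7", "TP9",
    "CP5", "CP1", "Pz", "P3", "P7", "O1", "Oz", "O2", "P4", "P8",
    "TP10", "CP6", "CP2", "Cz", "C4", "T8", "FT10", "FC6", "FC2", "F4",
    "F8", "Fp2", "AF7", "AF3", "AFz", "F1", "F5", "FT7", "FC3", "C1",
    "C5", "TP7", "CP3", "P1", "P5", "PO7", "PO3", "POz", "PO4", "PO8",
    "P6", "P2", "CPz", "CP4", "TP8", "C6", "C2", "FC4", "FT8", "F6",
    "AF8", "AF4", "F2", "Iz",
]


@dataclass
class Montage:
    """Ordered channel names with 2-D (and optionally 3-D) sensor positions.

    2-D positions are an azimuthal-equidistant projection of the scalp
    (+y anterior, +x right), scaled so the outermost electrode sits at
    radius 1.
    """

    ch_names: list
    pos2d: np.ndarray
    pos3d: Optional[np.ndarray] = None

    @property
    def n_channels(self) -> int:
        return len(self.ch_names)


def default_montage(ch_names: Optional[list] = None) -> Montage:
    """Standard 10-20/10-10 montage for the given channels (default: 64).

    Positions come from the standard idealized head model; unknown
    channel names raise a montage error.
    """
    import mne

    names = list(ch_names) if ch_names is not None else list(DEFAULT_64)
    try:
        std = mne.channels.make_standard_montage("colin27_1005")
    except ValueError:  # older idealized-head name
        std = mne.channels.make_standard_montage("standard_1005")
    pos_by_name = {k.upper(): v for k, v in std.get_positions()["ch_pos"].items()}
    pos3d = np.empty((len(names), 3))
    for i, nm in enumerate(names):
        key = nm.strip().upper()
        if key not in pos_by_name:
            raise ValueError(f"unknown channel name {nm!r} for the 10-20 montage")
        pos3d[i] = pos_by_name[key]
    # azimuthal-equidistant projection about the vertex
    centered = pos3d - pos3d.mean(axis=0)
    r = np.linalg.norm(centered, axis=1)
    with np.errstate(invalid="ignore"):
        theta = np.arccos(np.clip(centered[:, 2] / r, -1, 1))
    phi = np.arctan2(centered[:, 1], centered[:, 0])
    rho = theta
    xy = np.column_stack((rho * np.cos(phi), rho * np.sin(phi)))
    xy /= np.abs(xy).max()
    # +y anterior: standard montage has +y toward the nasion already
    return Montage(ch_names=names, pos2d=xy, pos3d=pos3d)


@dataclass
class TemplateSet:
    """K generating topographies (zero-mean, unit-norm) over a montage."""

    maps: np.ndarray            # (k, n_channels)
    labels: list
    montage: Montage

    def __post_init__(self):
        k = self.maps.shape[0]
        means = np.abs(self.maps.mean(axis=1))
        norms = np.linalg.norm(self.maps, axis=1)
        if np.any(means > 1e-9) or np.any(np.abs(norms - 1) > 1e-9):
            raise ValueError("template maps must be zero-mean and unit-norm")
        for i in range(k):
            for j in range(i + 1, k):
                if abs(spatial_correlation(self.maps[i], self.maps[j])) >= 0.7:
                    raise ValueError(
                        f"templates {self.labels[i]}/{self.labels[j]} are not "
                        "distinguishable (|spatial correlation| >= 0.7)")


def _gauss(xy: np.ndarray, center, sigma: float) -> np.ndarray:
    d2 = np.sum((xy - np.asarray(center)) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * sigma ** 2))


def make_canonical_templates(montage: Montage) -> TemplateSet:
    """The four archetype maps A-D as smooth dipolar fields on the scalp.

    A: left-posterior / right-frontal diagonal gradient;
    B: right-posterior / left-frontal diagonal gradient;
    C: anterior-posterior dipole (occipital positive pole);
    D: fronto-central maximum.

    Deterministic for a fixed montage; each map is zero-mean, unit-norm,
    and every pair is spatially distinguishable (|corr| < 0.7).
    """
    if montage.n_channels < 16:
        raise ValueError("montage must have at least 16 positioned channels")
    xy = montage.pos2d
    ca, sa = np.cos(np.deg2rad(35.0)), np.sin(np.deg2rad(35.0))
    fields = [
        _gauss(xy, (0.8 * ca, 0.8 * sa), 0.55) - _gauss(xy, (-0.8 * ca, -0.8 * sa), 0.55),
        _gauss(xy, (-0.8 * ca, 0.8 * sa), 0.55) - _gauss(xy, (0.8 * ca, -0.8 * sa), 0.55),
        _gauss(xy, (0.0, -0.85), 0.60) - _gauss(xy, (0.0, 0.85), 0.60),
        _gauss(xy, (0.0, 0.15), 0.38),
    ]
    maps = np.stack(fields)
    maps -= maps.mean(axis=1, keepdims=True)
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    return TemplateSet(maps=maps, labels=list(CLASS_LABELS), montage=montage)


@dataclass
class GenerativeSpec:
    """All parameters of the synthetic cohort, YAML-serializable.

    Durations are per class per group in ms; the smoker class-D mean is
    additionally shifted per subject by ``covariate_coupling`` ms for
    every FTND point away from the FTND midpoint, so the group mean and
    the within-group correlation are controlled independently.
    ``class_entry_weights`` implements selective occurrence effects: a
    class with weight w < 1 is entered less often from every other class
    (longer gaps between its visits), lowering its occurrence without
    touching its duration.
    """

    n_per_group: int = 25
    mean_duration_ms: dict = field(default_factory=lambda: {
        "control": {"A": 90.0, "B": 90.0, "C": 100.0, "D": 85.0},
        "smoker": {"A": 90.0, "B": 90.0, "C": 100.0, "D": 100.0},
    })
    class_entry_weights: dict = field(default_factory=lambda: {
        "control": {"A": 1.0, "B": 1.0, "C": 1.0, "D": 1.0},
        "smoker": {"A": 1.0, "B": 1.0, "C": 0.7, "D": 1.0},
    })
    duration_shape: float = 4.0
    subject_duration_sd: float = 0.10      # lognormal between-subject jitter (CV)
    snr: float = 4.0
    carrier_band_hz: tuple = (8.0, 12.0)
    sampling_rate_hz: float = 250.0
    record_seconds: float = 300.0
    amplitude_uv: float = 15.0
    noise_spatial_corr: float = 0.0        # uniform channel correlation, off by default
    covariate_coupling: float = -4.0       # ms of class-D duration per FTND point
    ftnd_range: tuple = (3, 10)
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        for grp in self.mean_duration_ms.values():
            if any(d <= 0 for d in grp.values()):
                raise ValueError("all mean durations must be positive")
        if self.record_seconds <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("record length and sampling rate must be positive")
        if not 0 <= self.noise_spatial_corr < 1:
            raise ValueError("noise_spatial_corr must lie in [0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["carrier_band_hz"] = list(self.carrier_band_hz)
        d["ftnd_range"] = list(self.ftnd_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeSpec":
        d = dict(d)
        if "carrier_band_hz" in d:
            d["carrier_band_hz"] = tuple(d["carrier_band_hz"])
        if "ftnd_range" in d:
            d["ftnd_range"] = tuple(d["ftnd_range"])
        return cls(**d)


def simulate_label_sequence(n_samples: int, sfreq: float, mean_durations_ms,
                            duration_shape: float, rng: np.random.Generator,
                            entry_weights=None) -> np.ndarray:
    """Semi-Markov microstate label sequence.

    The next class is drawn among the classes other than the current
    one, with probabilities proportional to ``entry_weights`` (uniform
    by default); each run length is a discretized gamma draw
    (``shape = duration_shape``, mean = that class's mean duration in
    samples), with a minimum of one sample.  Empirical mean run length
    converges to the generative mean as the sequence grows.
    """
    means = np.asarray(mean_durations_ms, dtype=float)
    k = means.size
    if n_samples <= 0:
        raise ValueError("requested a zero-length label sequence")
    if np.any(means <= 0):
        raise ValueError("mean durations must be positive")
    mean_samples = means / 1000.0 * sfreq
    labels = np.empty(n_samples, dtype=np.int16)
    if k == 1:
        labels[:] = 0
        return labels
    w = np.ones(k) if entry_weights is None else np.asarray(entry_weights, float)
    # per current class: cumulative entry probabilities over the other classes
    others = [np.array([j for j in range(k) if j != c]) for c in range(k)]
    cumw = [np.cumsum(w[o]) / np.sum(w[o]) for o in others]
    scale = mean_samples / duration_shape

    cur = int(np.searchsorted(np.cumsum(w) / w.sum(), rng.random()))
    pos = 0
    batch = max(16, int(n_samples / mean_samples.min() * 1.25))
    while pos < n_samples:
        gammas = rng.standard_gamma(duration_shape, size=batch)
        unis = rng.random(size=batch)
        for g, u in zip(gammas, unis):
            run = max(1, int(round(g * scale[cur])))
            end = min(pos + run, n_samples)
            labels[pos:end] = cur
            pos = end
            if pos >= n_samples:
                break
            cur = int(others[cur][np.searchsorted(cumw[cur], u)])
    return labels


def render_eeg(labels: np.ndarray, templates: TemplateSet, spec: GenerativeSpec,
               rng: np.random.Generator) -> EEGRecording:
    """Forward-model a recording from a label sequence.

    ``x_t = s * a_t * map_{L_t} + noise`` where ``a_t`` is a band-limited
    (carrier band, alpha by default) Gaussian carrier with unit RMS whose
    rectification ``|a_t|`` is the momentary field-strength envelope, and
    ``s`` an independent random sign per segment.  The carrier's own sign
    alternation plus the per-segment flips make polarity entirely
    uninformative, and GFP local maxima coincide with the envelope
    maxima (twice per carrier cycle, as in real alpha-dominated EEG).
    Keeping the amplitude signed keeps the signal inside the carrier
    band, so the analysis band-pass leaves the topography intact.  Noise
    is Gaussian, spatially white by default, scaled so state-signal RMS /
    noise RMS equals ``snr``.  The output is average-referenced by
    construction.
    """
    spec.validate()
    n = labels.size
    c = templates.montage.n_channels
    sf = spec.sampling_rate_hz
    lo, hi = spec.carrier_band_hz
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=sf, output="sos")
    a = sps.sosfilt(sos, rng.standard_normal(n))
    a /= np.sqrt(np.mean(a ** 2))
    # one random sign per segment
    edges = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], edges))
    signs = rng.choice([-1.0, 1.0], size=starts.size)
    sign_t = np.repeat(signs, np.diff(np.concatenate((starts, [n]))))
    amp = spec.amplitude_uv
    data = (templates.maps[labels].T * (amp * a * sign_t))
    if np.isfinite(spec.snr):
        sigma = amp / (np.sqrt(c) * spec.snr)
        noise = rng.normal(0.0, sigma, size=(c, n))
        rho = spec.noise_spatial_corr
        if rho > 0:
            shared = rng.normal(0.0, sigma, size=n)
            noise = np.sqrt(1 - rho) * noise + np.sqrt(rho) * shared
        noise -= noise.mean(axis=0, keepdims=True)   # keep the average reference
        data = data + noise
    return EEGRecording(data=data, sfreq=sf, ch_names=list(templates.montage.ch_names),
                        reference="average")


@dataclass
class GroundTruth:
    """Everything the generator knows: the recoverable truth."""

    labels: dict                      # subject_id -> int array (true frame labels)
    parameters: pd.DataFrame          # true temporal parameters per subject
    generative_durations: pd.DataFrame  # per-subject generative class means (ms)
    templates: TemplateSet
    spec: GenerativeSpec


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def _true_parameter_row(labels: np.ndarray, sfreq: float) -> dict:
    ls = LabelSequence(labels=labels.reshape(1, -1).astype(np.int32),
                       fit=np.ones((1, labels.size)), sfreq=sfreq,
                       class_labels=list(CLASS_LABELS))
    return parameters_row(subject_parameters(ls))


def simulate_cohort(spec: GenerativeSpec, render: bool = True):
    """Generate the full two-group cohort.

    Returns ``(recordings, clinical, truth)``: recordings is a dict
    subject_id -> :class:`EEGRecording` (or None when ``render=False``,
    which produces only label sequences and truth tables — useful for
    statistics-level replicate studies), clinical is the per-subject
    table (group, age, education, FTND, CPD, pack_years), and truth
    carries the label sequences, the true parameter table and the
    generating templates.

    Smokers get an integer FTND score uniform on the inclusion range
    [3, 10]; within smokers the class-D generative mean duration moves by
    ``covariate_coupling`` ms per FTND point (centred on the range
    midpoint).  Re-running with the same spec is bitwise reproducible.
    """
    spec.validate()
    montage = default_montage()
    templates = make_canonical_templates(montage)
    n_samp = int(round(spec.record_seconds * spec.sampling_rate_hz))
    ftnd_lo, ftnd_hi = spec.ftnd_range
    ftnd_mid = (ftnd_lo + ftnd_hi) / 2.0

    demo_rng = _subject_rng(spec.seed, 10_000)  # cohort-level demographics stream
    recordings = {} if render else None
    labels_by_subject = {}
    clin_rows, truth_rows, gen_rows = [], [], []
    idx = 0
    for group, prefix in (("smoker", "S"), ("control", "N")):
        base = np.array([spec.mean_duration_ms[group][c] for c in CLASS_LABELS])
        weights = np.array([spec.class_entry_weights[group][c] for c in CLASS_LABELS])
        for i in range(spec.n_per_group):
            sid = f"{prefix}{i + 1:02d}"
            rng = _subject_rng(spec.seed, idx)
            if group == "smoker":
                ftnd = int(rng.integers(ftnd_lo, ftnd_hi + 1))
                cpd = float(np.clip(np.round(rng.normal(14.25, 4.59)), 10, None))
                smoke_years = float(np.clip(rng.normal(4.21, 2.21), 0.25, None))
                pack_years = smoke_years * cpd / 20.0
                age = float(np.clip(np.round(rng.normal(20.40, 1.26)), 18, 23))
                edu = float(np.clip(np.round(rng.normal(14.04, 0.61)), 12, 16))
            else:
                ftnd = np.nan
                cpd = np.nan
                pack_years = np.nan
                age = float(np.clip(np.round(rng.normal(20.16, 1.14)), 18, 23))
                edu = float(np.clip(np.round(rng.normal(14.24, 0.66)), 12, 16))
            jitter = np.exp(rng.normal(0.0, spec.subject_duration_sd, size=4))
            means = base * jitter
            if group == "smoker":
                means[3] = max(40.0, means[3] + spec.covariate_coupling * (ftnd - ftnd_mid))
            lab = simulate_label_sequence(n_samp, spec.sampling_rate_hz, means,
                                          spec.duration_shape, rng,
                                          entry_weights=weights)
            labels_by_subject[sid] = lab
            if render:
                recordings[sid] = render_eeg(lab, templates, spec, rng)
            clin_rows.append({"subject_id": sid, "group": group, "age": age,
                              "education": edu, "FTND": ftnd, "CPD": cpd,
                              "pack_years": pack_years})
            truth_rows.append({"subject_id": sid, "group": group,
                               **_true_parameter_row(lab, spec.sampling_rate_hz)})
            gen_rows.append({"subject_id": sid, "group": group,
                             **{f"gen_duration_{c}": m for c, m in zip(CLASS_LABELS, means)}})
            idx += 1
    clinical = pd.DataFrame(clin_rows)
    truth = GroundTruth(labels=labels_by_subject,
                        parameters=pd.DataFrame(truth_rows),
                        generative_durations=pd.DataFrame(gen_rows),
                        templates=templates, spec=spec)
    return recordings, clinical, truth
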