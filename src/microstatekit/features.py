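"""Temporal microstate parameters from a smoothed label sequence.

Four statistics per subject and class: mean segment duration (ms),
occurrence rate (segments per second), time coverage (fraction), and the
conditional transition-probability matrix between consecutive segments.
Segments touching epoch edges are included in all statistics, so the
identity ``occurrence_k * duration_k / 1000 == coverage_k`` holds
exactly whenever the class occurs at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .microstates import LabelSequence, _runs

__all__ = [
    "Segment",
    "SubjectParameters",
    "segments_from_labels",
    "compute_duration",
    "compute_occurrence",
    "compute_coverage",
    "transition_matrix",
    "subject_parameters",
    "parameters_row",
    "cohort_parameter_table",
    "transition_column",
]


@dataclass(frozen=True)
class Segment:
    """One maximal run of a single class within one epoch.

    Frame interval is half-open: ``stop - start`` frames long.
    """

    label: int
    start: int
    stop: int
    epoch: int
    duration_ms: float


def segments_from_labels(ls: LabelSequence) -> list:
    """Maximal same-label runs per epoch, in temporal order."""
    out = []
    for e in range(ls.n_epochs):
        for a, b, lab in _runs(ls.labels[e]):
            out.append(Segment(label=lab, start=a, stop=b, epoch=e,
                               duration_ms=(b - a) / ls.sfreq * 1000.0))
    return out


def compute_duration(segments, label: int) -> float:
    """Mean duration (ms) over all segments of the class; NaN when absent."""
    d = [s.duration_ms for s in segments if s.label == label]
    return float(np.mean(d)) if d else float("nan")


def compute_occurrence(segments, label: int, total_seconds: float) -> float:
    """Segments of the class per analysed second (0 when absent)."""
    return sum(1 for s in segments if s.label == label) / total_seconds


def compute_coverage(segments, label: int) -> float:
    """Fraction of all frames spent in the class."""
    total = sum(s.stop - s.start for s in segments)
    mine = sum(s.stop - s.start for s in segments if s.label == label)
    return mine / total


def transition_matrix(segments, n_classes: int):
    """Conditional transition probabilities between consecutive segments.

    Transitions are counted within epochs only (never across epoch
    boundaries) and each row is normalized by that class's outgoing
    count.  The diagonal is structurally zero.  Rows with no outgoing
    transitions are left all-zero and flagged.

    Returns
    -------
    P : ndarray (k, k)
    flagged : ndarray of bool, shape (k,)
        True where the row had no outgoing transitions.
    """
    counts = np.zeros((n_classes, n_classes), dtype=float)
    for prev, nxt in zip(segments[:-1], segments[1:]):
        if prev.epoch == nxt.epoch:
            counts[prev.label, nxt.label] += 1
    row = counts.sum(axis=1)
    flagged = row == 0
    P = np.zeros_like(counts)
    nz = ~flagged
    P[nz] = counts[nz] / row[nz, None]
    return P, flagged


@dataclass
class SubjectParameters:
    """Per-subject microstate parameters over all analysed epochs."""

    class_labels: list
    duration_ms: dict
    occurrence_per_s: dict
    coverage: dict
    transition: np.ndarray
    transition_flagged: np.ndarray
    total_seconds: float


def subject_parameters(ls: LabelSequence) -> SubjectParameters:
    """All four parameter families from one smoothed label sequence."""
    segs = segments_from_labels(ls)
    total_frames = ls.labels.size
    total_seconds = total_frames / ls.sfreq
    k = ls.n_classes
    duration = {lab: compute_duration(segs, i) for i, lab in enumerate(ls.class_labels)}
    occurrence = {lab: compute_occurrence(segs, i, total_seconds)
                  for i, lab in enumerate(ls.class_labels)}
    coverage = {lab: compute_coverage(segs, i) for i, lab in enumerate(ls.class_labels)}
    P, flagged = transition_matrix(segs, k)
    return SubjectParameters(class_labels=list(ls.class_labels),
                             duration_ms=duration, occurrence_per_s=occurrence,
                             coverage=coverage, transition=P,
                             transition_flagged=flagged,
                             total_seconds=total_seconds)


def transition_column(a: str, b: str) -> str:
    return f"t_{a}_{b}"


def parameters_row(sp: SubjectParameters) -> dict:
    """Flatten parameters into one tidy table row."""
    row = {}
    for lab in sp.class_labels:
        row[f"duration_{lab}"] = sp.duration_ms[lab]
    for lab in sp.class_labels:
        row[f"occurrence_{lab}"] = sp.occurrence_per_s[lab]
    for lab in sp.class_labels:
        row[f"coverage_{lab}"] = sp.coverage[lab]
    for i, a in enumerate(sp.class_labels):
        for j, b in enumerate(sp.class_labels):
            if i != j:
                row[transition_column(a, b)] = sp.transition[i, j]
    row["total_seconds"] = sp.total_seconds
    return row


def cohort_parameter_table(params_by_subject: dict, clinical: pd.DataFrame) -> pd.DataFrame:
    """One row per subject: parameters joined with the clinical table.

    ``params_by_subject`` maps subject_id -> :class:`SubjectParameters`.
    Every subject must have a clinical row; a missing row is a hard error
    naming the subject.
    """
    clin = clinical.set_index("subject_id")
    rows = []
    for sid, sp in params_by_subject.items():
        if sid not in clin.index:
            raise KeyError(f"no clinical row for subject {sid!r}")
        row = {"subject_id": sid, "group": clin.loc[sid, "group"]}
        row.update(parameters_row(sp))
        rows.append(row)
    return pd.DataFrame(rows)
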