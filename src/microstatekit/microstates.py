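"""Polarity-invariant microstate segmentation.

The analysis treats the multichannel EEG as a sequence of quasi-stable
scalp topographies.  Candidate topographies are taken at peaks of the
global field power (GFP), pooled across subjects, and clustered with the
modified K-means algorithm, which identifies a map with its polarity
inversion: samples are assigned by squared projection onto the cluster
map, and each cluster map is updated to the principal eigenvector of its
members' outer-product sum.  Prototypes are then ordered against the
canonical A-D archetype topographies, fitted back to every EEG frame by
absolute spatial correlation, and runs shorter than a minimum duration
are dissolved into their most similar neighbouring class using global
map dissimilarity (GMD).

Conventions used throughout (the source literature is split on both):

* spatial correlation = Pearson correlation across channels of the two
  zero-meaned maps; polarity is ignored by taking the absolute value;
* GFP = *population* standard deviation across channels (divide by the
  channel count, not count - 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .preprocessing import EpochedEEG

__all__ = [
    "GfpSeries",
    "MicrostatePrototypes",
    "LabelSequence",
    "spatial_correlation",
    "compute_gfp",
    "detect_gfp_peaks",
    "select_peaks",
    "extract_peak_maps",
    "modified_kmeans",
    "compute_gev",
    "order_canonically",
    "backfit",
    "gmd",
    "smooth_segments",
]

_ZERO_GFP = 1e-12


# ---------------------------------------------------------------------------
# map algebra

def _demean(x: np.ndarray) -> np.ndarray:
    """Remove the across-channel mean (last axis)."""
    return x - x.mean(axis=-1, keepdims=True)


def spatial_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Signed Pearson correlation across channels of two topographies."""
    xd, yd = _demean(np.asarray(x, float)), _demean(np.asarray(y, float))
    nx, ny = np.linalg.norm(xd), np.linalg.norm(yd)
    if nx < _ZERO_GFP or ny < _ZERO_GFP:
        return 0.0
    return float(xd @ yd / (nx * ny))


def _abs_corr_matrix(X: np.ndarray, A: np.ndarray) -> np.ndarray:
    """|spatial correlation| between every row of X (n, c) and of A (k, c)."""
    Xd, Ad = _demean(X), _demean(A)
    xn = np.linalg.norm(Xd, axis=1)
    an = np.linalg.norm(Ad, axis=1)
    num = np.abs(Xd @ Ad.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = num / np.outer(xn, an)
    C[xn < _ZERO_GFP, :] = 0.0
    return np.clip(C, 0.0, 1.0)


def gmd(x: np.ndarray, y: np.ndarray) -> float:
    """Polarity-invariant global map dissimilarity of two topographies.

    Both maps are zero-meaned and scaled to unit GFP, then the root mean
    square channel-wise difference is taken, minimized over the sign of
    one map: ``GMD = sqrt(2 * (1 - |spatial correlation|))``.  Identical
    or sign-flipped maps give 0; spatially orthogonal maps give sqrt(2).
    """
    r = abs(spatial_correlation(x, y))
    return float(np.sqrt(max(2.0 * (1.0 - r), 0.0)))


# ---------------------------------------------------------------------------
# GFP and peak selection

@dataclass
class GfpSeries:
    """GFP per sample, organised as epochs x samples, plus detected peaks.

    ``peaks`` is an (n, 2) integer array of (epoch, sample) pairs, kept in
    temporal order; ``log`` accumulates the peak-selection bookkeeping
    (counts found / after outlier exclusion / after subsampling).
    """

    values: np.ndarray
    sfreq: float
    peaks: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    log: dict = field(default_factory=dict)


def compute_gfp(ep: EpochedEEG) -> GfpSeries:
    """Global field power: population SD of the potential across channels."""
    values = ep.data.std(axis=1, ddof=0)
    return GfpSeries(values=values, sfreq=ep.sfreq)


def _greedy_peaks(v: np.ndarray, min_gap: int) -> np.ndarray:
    """Strict local maxima kept greedily by descending height.

    Ties are broken toward the earlier index.  Any two kept peaks are at
    least ``min_gap`` samples apart.
    """
    cand = np.flatnonzero((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])) + 1
    if cand.size == 0:
        return cand
    order = cand[np.lexsort((cand, -v[cand]))]
    blocked = np.zeros(v.size, dtype=bool)
    kept = []
    for i in order:
        if not blocked[i]:
            kept.append(i)
            blocked[max(0, i - min_gap + 1): i + min_gap] = True
    return np.sort(np.asarray(kept, dtype=int))


def detect_gfp_peaks(g: GfpSeries, min_distance_ms: float = 10.0) -> GfpSeries:
    """Locate GFP peaks within each epoch (peaks never straddle epochs).

    A peak is strictly greater than both neighbours; peaks are retained
    greedily in descending height subject to the minimum-distance
    constraint (10 ms by default).
    """
    min_gap = max(1, int(np.ceil(min_distance_ms * g.sfreq / 1000.0)))
    rows = []
    for e in range(g.values.shape[0]):
        for i in _greedy_peaks(g.values[e], min_gap):
            rows.append((e, int(i)))
    peaks = np.asarray(rows, dtype=int).reshape(-1, 2)
    log = dict(g.log)
    log["n_peaks_found"] = int(peaks.shape[0])
    return replace(g, peaks=peaks, log=log)


def select_peaks(g: GfpSeries, sd_multiplier: float = 2.0, n_sample: int = 1000,
                 rng: Optional[np.random.Generator] = None) -> GfpSeries:
    """Drop outlier peaks, then subsample to at most ``n_sample`` peaks.

    Peaks whose GFP exceeds mean + ``sd_multiplier`` * SD of this
    subject's peak heights are eliminated (one-sided: the aim is removing
    abnormally strong fields).  The survivors are subsampled uniformly
    without replacement; with a fixed generator the selection is
    deterministic.
    """
    if g.peaks.shape[0] == 0:
        raise ValueError("no GFP peaks to select from")
    heights = g.values[g.peaks[:, 0], g.peaks[:, 1]]
    thr = heights.mean() + sd_multiplier * heights.std(ddof=0)
    keep = heights <= thr
    remaining = g.peaks[keep]
    if remaining.shape[0] == 0:
        raise ValueError("no GFP peaks remain after outlier exclusion")
    n_take = min(n_sample, remaining.shape[0])
    if n_take < remaining.shape[0]:
        if rng is None:
            rng = np.random.default_rng()
        idx = np.sort(rng.choice(remaining.shape[0], size=n_take, replace=False))
        remaining = remaining[idx]
    log = dict(g.log)
    log.update(n_peaks_after_sd=int(keep.sum()), n_peaks_sampled=int(n_take),
               sd_multiplier=float(sd_multiplier))
    return replace(g, peaks=remaining, log=log)


def extract_peak_maps(ep: EpochedEEG, g: GfpSeries) -> np.ndarray:
    """Topographies at the selected GFP peaks, shape (n_peaks, n_channels)."""
    return ep.data[g.peaks[:, 0], :, g.peaks[:, 1]].copy()


# ---------------------------------------------------------------------------
# modified K-means

@dataclass
class MicrostatePrototypes:
    """K cluster topographies (zero-mean, unit-norm) with fit metadata."""

    maps: np.ndarray                 # (k, n_channels)
    labels: list                     # class names, canonical A-D after ordering
    gev: float
    n_restarts: int = 0
    n_iterations_used: int = 0
    seed: Optional[int] = None
    gev_history: list = field(default_factory=list)  # winning restart, per iteration
    empty_cluster_events: int = 0

    @property
    def k(self) -> int:
        return self.maps.shape[0]


def _principal_map(Xk: np.ndarray, a0: np.ndarray) -> np.ndarray:
    """Principal eigenvector of Xk^T Xk by power iteration, warm-started.

    The matrix is PSD, so each power step cannot decrease the Rayleigh
    quotient sum_t (x_t . a)^2 — the ascent property of the K-means
    update is preserved even before full convergence.
    """
    a = a0
    for _ in range(500):
        b = Xk.T @ (Xk @ a)
        nb = np.linalg.norm(b)
        if nb == 0.0:          # degenerate cluster (all-zero maps)
            return a0
        b /= nb
        if 1.0 - abs(b @ a) < 1e-14:
            return b
        a = b
    return a


def modified_kmeans(maps_pool: np.ndarray, k: int = 4, n_restarts: int = 50,
                    max_iter: int = 1000, tol: float = 1e-6,
                    seed: Optional[int] = None) -> MicrostatePrototypes:
    """Polarity-invariant topographic clustering of a pool of maps.

    Parameters
    ----------
    maps_pool : ndarray, shape (n_maps, n_channels)
        Concatenated GFP-peak topographies of all subjects.
    k : int
        Number of microstate classes (4 for the canonical analysis).
    n_restarts, max_iter, tol :
        Random restarts, iteration cap per restart, and relative
        explained-variance change below which a restart stops.
    seed : int, optional
        Controls initialization of all restarts; restart ``r`` draws from
        an independent substream derived from (seed, r).

    Notes
    -----
    Each restart initializes the k maps from k distinct pool maps, then
    alternates (i) assigning every map t to ``argmax_k (x_t . a_k)^2``
    and (ii) replacing ``a_k`` by the principal eigenvector of
    ``sum_{t in k} x_t x_t^T``.  Both steps increase the global explained
    variance, so GEV ascends monotonically within a restart (asserted).
    An emptied cluster is re-seeded from the pool map currently worst
    fitted by the prototypes.  The restart with the highest GEV wins.
    """
    X = _demean(np.asarray(maps_pool, dtype=np.float64))
    n, c = X.shape
    if n < k:
        raise ValueError(f"pool of {n} maps cannot support k={k} clusters")
    denom = float(np.einsum("ij,ij->", X, X))
    if denom <= 0:
        raise ValueError("pool has zero total variance")

    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(r,)))
        idx = rng.choice(n, size=k, replace=False)
        A = X[idx].copy()
        norms = np.linalg.norm(A, axis=1)
        if np.any(norms < _ZERO_GFP):  # pathological zero maps in the pool
            idx = rng.permutation(np.flatnonzero(np.linalg.norm(X, axis=1) >= _ZERO_GFP))[:k]
            A = X[idx].copy()
            norms = np.linalg.norm(A, axis=1)
        A /= norms[:, None]

        prev_gev = -np.inf
        history = []
        n_iter = 0
        empties = 0
        labels = np.zeros(n, dtype=int)
        for n_iter in range(1, max_iter + 1):
            proj = X @ A.T
            labels = np.argmax(proj ** 2, axis=1)
            # re-seed empty clusters from the worst-fitted pool map
            for kk in range(k):
                if not np.any(labels == kk):
                    fit = np.max(proj ** 2, axis=1) / np.einsum("ij,ij->i", X, X)
                    worst = int(np.argmin(fit))
                    A[kk] = X[worst] / np.linalg.norm(X[worst])
                    proj[:, kk] = X @ A[kk]
                    labels = np.argmax(proj ** 2, axis=1)
                    empties += 1
            gev = float(np.sum(proj[np.arange(n), labels] ** 2) / denom)
            if gev < prev_gev - 1e-10:
                raise AssertionError("GEV decreased across modified K-means iterations")
            history.append(gev)
            if np.isfinite(prev_gev) and (gev - prev_gev) < tol * max(prev_gev, 1e-30):
                break
            prev_gev = gev
            for kk in range(k):
                members = labels == kk
                A[kk] = _principal_map(X[members], A[kk])
        gev = history[-1]
        if best is None or gev > best["gev"]:
            best = {"gev": gev, "A": A.copy(), "history": history,
                    "n_iter": n_iter, "empties": empties}

    A = _demean(best["A"])
    A /= np.linalg.norm(A, axis=1)[:, None]
    return MicrostatePrototypes(
        maps=A, labels=[str(i + 1) for i in range(k)], gev=best["gev"],
        n_restarts=n_restarts, n_iterations_used=best["n_iter"], seed=seed,
        gev_history=best["history"], empty_cluster_events=best["empties"])


def compute_gev(maps: np.ndarray, gfp: np.ndarray, labels: np.ndarray,
                prototypes: np.ndarray) -> float:
    """Global explained variance of labelled maps under the prototypes.

    ``GEV = sum_t (GFP_t * |corr(x_t, a_{L_t})|)^2 / sum_t GFP_t^2`` with
    corr the absolute spatial correlation.  Equals 1 for noiseless
    single-template data and 0 when every map is assigned to a spatially
    orthogonal prototype.
    """
    maps = np.asarray(maps, float)
    gfp = np.asarray(gfp, float)
    labels = np.asarray(labels, int)
    C = _abs_corr_matrix(maps, np.asarray(prototypes, float))
    r = C[np.arange(maps.shape[0]), labels]
    denom = float(np.sum(gfp ** 2))
    if denom == 0.0:
        return 0.0
    return float(np.sum((gfp * r) ** 2) / denom)


# ---------------------------------------------------------------------------
# canonical ordering

def order_canonically(p: MicrostatePrototypes, templates) -> MicrostatePrototypes:
    """Relabel prototypes A-D by optimal assignment to canonical templates.

    All ``k!`` one-to-one assignments are scored by total absolute
    spatial correlation and the exact maximum is taken (ties broken by
    lexicographic permutation order).  Prototype polarity is aligned to
    the template for display purposes only; polarity carries no
    information anywhere in the analysis.
    """
    T = np.asarray(templates.maps, float)
    if T.shape[0] != p.k:
        raise ValueError("template count does not match prototype count")
    C = _abs_corr_matrix(p.maps, T)  # (k prototypes, k templates)
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(p.k)):
        score = sum(C[perm[j], j] for j in range(p.k))
        if score > best_score + 1e-15:
            best_score, best_perm = score, perm
    maps = p.maps[list(best_perm)].copy()
    for j in range(p.k):  # cosmetic sign alignment with the template
        if spatial_correlation(maps[j], T[j]) < 0:
            maps[j] = -maps[j]
    return replace(p, maps=maps, labels=list(templates.labels))


# ---------------------------------------------------------------------------
# backfitting

@dataclass
class LabelSequence:
    """Per-frame microstate labels with fit quality, epochs x samples."""

    labels: np.ndarray        # (n_epochs, n_samples) int
    fit: np.ndarray           # (n_epochs, n_samples) |spatial correlation|
    sfreq: float
    class_labels: list

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    @property
    def n_epochs(self) -> int:
        return self.labels.shape[0]


def _fill_nearest(labels: np.ndarray, bad: np.ndarray) -> np.ndarray:
    """Replace ``bad`` entries with the nearest good label (ties -> left)."""
    good = np.flatnonzero(~bad)
    if good.size == 0:
        return labels
    out = labels.copy()
    for i in np.flatnonzero(bad):
        j = np.searchsorted(good, i)
        cand = []
        if j > 0:
            cand.append(good[j - 1])
        if j < good.size:
            cand.append(good[j])
        src = min(cand, key=lambda g: (abs(g - i), g))
        out[i] = labels[src]
    return out


def backfit(ep: EpochedEEG, p: MicrostatePrototypes) -> LabelSequence:
    """Label every frame with its best prototype by absolute spatial correlation.

    Frames with essentially zero GFP carry no topographic information;
    they inherit the label of the nearest labelled frame within the same
    epoch (fit recorded as 0).
    """
    if ep.n_channels != p.maps.shape[1]:
        raise ValueError("epochs and prototypes have different channel counts")
    n_ep, _, n_t = ep.data.shape
    labels = np.zeros((n_ep, n_t), dtype=np.int32)
    fit = np.zeros((n_ep, n_t), dtype=np.float64)
    for e in range(n_ep):
        Xt = ep.data[e].T  # (n_t, c)
        C = _abs_corr_matrix(Xt, p.maps)
        lab = np.argmax(C, axis=1).astype(np.int32)
        fv = C[np.arange(n_t), lab]
        bad = np.linalg.norm(_demean(Xt), axis=1) < _ZERO_GFP
        if np.any(bad) and not np.all(bad):
            lab = _fill_nearest(lab, bad)
            fv = fv.copy()
            fv[bad] = 0.0
        labels[e], fit[e] = lab, fv
    return LabelSequence(labels=labels, fit=fit, sfreq=ep.sfreq,
                         class_labels=list(p.labels))


# ---------------------------------------------------------------------------
# minimum-duration smoothing

def _runs(lab: np.ndarray) -> list:
    """Maximal runs of identical labels as (start, stop, label) half-open."""
    edges = np.flatnonzero(np.diff(lab)) + 1
    starts = np.concatenate(([0], edges))
    stops = np.concatenate((edges, [lab.size]))
    return [(int(a), int(b), int(lab[a])) for a, b in zip(starts, stops)]


def smooth_segments(ep: EpochedEEG, ls: LabelSequence, p: MicrostatePrototypes,
                    min_duration_ms: float = 30.0,
                    max_passes: int = 1000) -> LabelSequence:
    """Dissolve segments shorter than ``min_duration_ms`` via GMD.

    Within each epoch (segments never cross epoch boundaries), the
    shortest offending segment is processed first: each of its frames is
    relabelled to its *next most likely* class — the class with the
    smallest polarity-invariant global map dissimilarity among the
    classes not yet rejected for that frame.  Rejections are cumulative
    per frame (a dissolved class cannot return to the same frame), which
    is what makes the walk down each frame's similarity ranking
    terminate.  A frame that exhausts every class is merged into the
    neighbouring segment with the smaller mean GMD.  Segments are then
    recomputed and the procedure repeats until no segment is shorter
    than the minimum.  Non-convergence within ``max_passes`` passes over
    one epoch raises a diagnostic error.
    """
    min_frames = int(np.ceil(min_duration_ms * ls.sfreq / 1000.0))
    labels = ls.labels.copy()
    fit = ls.fit.copy()
    k = p.k
    for e in range(ls.n_epochs):
        lab = labels[e]
        Xt = ep.data[e].T
        C = _abs_corr_matrix(Xt, p.maps)          # GMD ranking = |corr| ranking
        GMD = np.sqrt(np.maximum(2.0 * (1.0 - C), 0.0))
        excluded = np.zeros((lab.size, k), dtype=bool)
        for _pass in range(max_passes):
            runs = _runs(lab)
            if len(runs) <= 1:
                break
            off = [r for r in runs if (r[1] - r[0]) < min_frames]
            if not off:
                break
            start, stop, cls = min(off, key=lambda r: (r[1] - r[0], r[0]))
            excluded[start:stop, cls] = True
            seg_excl = excluded[start:stop]
            exhausted = seg_excl.all(axis=1)
            if np.any(exhausted):
                # no admissible class left: merge into the closer neighbour
                run_idx = runs.index((start, stop, cls))
                cand = []
                if run_idx > 0:
                    cand.append(runs[run_idx - 1][2])
                if run_idx < len(runs) - 1:
                    cand.append(runs[run_idx + 1][2])
                target = min(cand, key=lambda j: GMD[start:stop, j].mean())
                lab[start:stop] = target
            else:
                seg_gmd = np.where(seg_excl, np.inf, GMD[start:stop])
                lab[start:stop] = np.argmin(seg_gmd, axis=1)
            fit[e, start:stop] = C[np.arange(start, stop), lab[start:stop]]
        else:
            raise RuntimeError(
                f"smoothing did not converge in {max_passes} passes "
                f"(epoch {e}: {sum((r[1]-r[0]) < min_frames for r in _runs(lab))} "
                f"segments still below {min_duration_ms} ms)")
        labels[e] = lab
    return LabelSequence(labels=labels, fit=fit, sfreq=ls.sfreq,
                         class_labels=list(ls.class_labels))
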