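"""Unit and oracle tests for GFP, clustering, backfitting and smoothing."""

import itertools

import numpy as np
import pytest

from microstatekit.microstates import (GfpSeries, LabelSequence,
                                       MicrostatePrototypes, backfit,
                                       compute_gev, compute_gfp,
                                       detect_gfp_peaks, extract_peak_maps,
                                       gmd, modified_kmeans, order_canonically,
                                       select_peaks, smooth_segments,
                                       spatial_correlation)
from microstatekit.preprocessing import EpochedEEG


def make_epochs(data, sfreq=250.0):
    data = np.asarray(data, float)
    names = [f"ch{i}" for i in range(data.shape[1])]
    return EpochedEEG(data=data, sfreq=sfreq, ch_names=names,
                      epoch_length_s=data.shape[2] / sfreq)


def random_maps(rng, n, c=8):
    X = rng.normal(size=(n, c))
    X -= X.mean(axis=1, keepdims=True)
    return X


class TestGfp:
    @pytest.mark.parametrize("frame,expected", [
        ([1.0, -1.0], 1.0),
        ([2.0, 0.0, -2.0, 0.0], np.sqrt(2.0)),
        ([5.0, 5.0, 5.0], 0.0),
    ])
    def test_closed_forms(self, frame, expected):
        ep = make_epochs(np.asarray(frame)[None, :, None])
        assert compute_gfp(ep).values[0, 0] == pytest.approx(expected)

    def test_population_sd_convention(self, rng):
        ep = make_epochs(rng.normal(size=(2, 16, 50)))
        g = compute_gfp(ep)
        np.testing.assert_allclose(g.values, ep.data.std(axis=1, ddof=0))


class TestPeakDetection:
    def test_rectified_alpha_peak_rate(self):
        """|sin| at 10 Hz has 20 maxima per second."""
        t = np.arange(500) / 250.0  # one 2 s epoch
        v = np.abs(np.sin(2 * np.pi * 10 * t))
        g = GfpSeries(values=v[None, :], sfreq=250.0)
        g = detect_gfp_peaks(g, min_distance_ms=10.0)
        assert g.peaks.shape[0] == 40

    def test_monotone_series_has_no_peaks(self):
        g = GfpSeries(values=np.linspace(0, 1, 100)[None, :], sfreq=250.0)
        assert detect_gfp_peaks(g).peaks.shape[0] == 0

    def test_spacing_rule_with_equal_heights(self):
        """Two equal maxima 8 ms (2 samples) apart: earlier one wins."""
        v = np.zeros(20)
        v[[5, 7]] = 1.0
        g = detect_gfp_peaks(GfpSeries(values=v[None, :], sfreq=250.0),
                             min_distance_ms=10.0)
        assert g.peaks.tolist() == [[0, 5]]

    def test_peaks_do_not_straddle_epochs(self):
        v = np.zeros((2, 20))
        v[0, -1] = 1.0  # rising to the edge: not a strict local maximum
        v[1, 5] = 1.0
        g = detect_gfp_peaks(GfpSeries(values=v, sfreq=250.0))
        assert g.peaks.tolist() == [[1, 5]]


class TestPeakSelection:
    def _series(self, heights):
        v = np.zeros((1, 4 * len(heights) + 4))
        for i, h in enumerate(heights):
            v[0, 2 + 4 * i] = h
        g = GfpSeries(values=v, sfreq=1000.0)
        return detect_gfp_peaks(g, min_distance_ms=2.0)

    def test_outlier_removed(self, rng):
        heights = [1.0] * 200 + [50.0]
        g = select_peaks(self._series(heights), rng=rng)
        kept = g.values[g.peaks[:, 0], g.peaks[:, 1]]
        assert kept.max() < 50.0
        assert g.log["n_peaks_after_sd"] == 200

    def test_min_rule_keeps_everything(self, rng):
        g = select_peaks(self._series([1.0 + 0.001 * i for i in range(30)]),
                         n_sample=1000, rng=rng)
        assert g.peaks.shape[0] == 30

    def test_subsampling_deterministic(self):
        g0 = self._series([1.0 + 0.01 * (i % 7) for i in range(60)])
        picks = [select_peaks(g0, n_sample=20,
                              rng=np.random.default_rng(5)).peaks.tolist()
                 for _ in range(2)]
        assert picks[0] == picks[1]
        assert len(picks[0]) == 20

    def test_no_peaks_is_an_error(self, rng):
        g = GfpSeries(values=np.zeros((1, 10)), sfreq=250.0)
        with pytest.raises(ValueError):
            select_peaks(g, rng=rng)


class TestModifiedKmeans:
    def test_orthogonal_pool_recovered_exactly(self, rng):
        """Four orthogonal maps with sign flips: |corr| = 1 and GEV = 1."""
        base = np.zeros((4, 8))
        base[0, :2] = [1, -1]
        base[1, 2:4] = [1, -1]
        base[2, 4:6] = [1, -1]
        base[3, 6:8] = [1, -1]
        signs = rng.choice([-1.0, 1.0], size=400)
        pool = base[np.repeat(np.arange(4), 100)] * signs[:, None]
        p = modified_kmeans(pool, k=4, n_restarts=5, seed=0)
        C = np.abs(p.maps @ (base / np.linalg.norm(base, axis=1, keepdims=True)).T)
        # every generator matched by exactly one prototype
        assert np.allclose(np.sort(C.max(axis=0)), 1.0, atol=1e-9)
        assert p.gev == pytest.approx(1.0, abs=1e-12)

    def test_k1_equals_principal_eigenvector(self, rng):
        """k=1 prototype is the principal eigenvector of the outer-product sum."""
        X = random_maps(rng, 50)
        p = modified_kmeans(X, k=1, n_restarts=3, seed=1)
        w, V = np.linalg.eigh(X.T @ X)  # independent oracle
        oracle = V[:, np.argmax(w)]
        assert abs(spatial_correlation(p.maps[0], oracle)) == pytest.approx(1.0, abs=1e-8)

    def test_tiny_pool_matches_exhaustive_enumeration(self, rng):
        """6 maps, k=2: assignment equals the best of all 2^6 labelings."""
        X = random_maps(rng, 6, c=5)
        p = modified_kmeans(X, k=2, n_restarts=20, seed=2)
        denom = np.sum(X ** 2)

        def ev(labels):
            total = 0.0
            for kk in (0, 1):
                Xk = X[np.asarray(labels) == kk]
                if len(Xk) == 0:
                    continue
                w, V = np.linalg.eigh(Xk.T @ Xk)
                total += w.max()
            return total / denom

        best = max((ev(lab), lab) for lab in
                   itertools.product((0, 1), repeat=6))
        proj = X @ p.maps.T
        ours = np.argmax(proj ** 2, axis=1)
        ours_ev = ev(ours)
        assert ours_ev == pytest.approx(best[0], abs=1e-9)
        assert tuple(ours) in (best[1], tuple(1 - np.asarray(best[1])))

    def test_gev_monotone_within_winning_restart(self, rng):
        X = random_maps(rng, 300, c=16)
        p = modified_kmeans(X, k=4, n_restarts=5, seed=3)
        diffs = np.diff(p.gev_history)
        assert np.all(diffs >= -1e-10)

    def test_pool_smaller_than_k_rejected(self, rng):
        with pytest.raises(ValueError):
            modified_kmeans(random_maps(rng, 3), k=4)


class TestGev:
    def test_single_template_data_explains_everything(self, rng):
        a = random_maps(rng, 1, 8)[0]
        a /= np.linalg.norm(a)
        amps = rng.uniform(0.5, 2.0, size=40)
        maps = np.outer(amps, a)
        gfp = maps.std(axis=1, ddof=0)
        assert compute_gev(maps, gfp, np.zeros(40, int), a[None]) == pytest.approx(1.0)

    def test_orthogonal_assignment_explains_nothing(self):
        maps = np.tile([1.0, -1.0, 0.0, 0.0], (10, 1))
        proto = np.asarray([[0.0, 0.0, 1.0, -1.0]]) / np.sqrt(2)
        gfp = maps.std(axis=1, ddof=0)
        assert compute_gev(maps, gfp, np.zeros(10, int), proto) == pytest.approx(0.0)

    def test_random_labels_never_beat_optimal(self, rng):
        maps = random_maps(rng, 100, 8)
        protos = random_maps(rng, 4, 8)
        protos /= np.linalg.norm(protos, axis=1, keepdims=True)
        gfp = maps.std(axis=1, ddof=0)
        from microstatekit.microstates import _abs_corr_matrix
        opt = np.argmax(_abs_corr_matrix(maps, protos), axis=1)
        for _ in range(10):
            rand = rng.integers(0, 4, size=100)
            assert (compute_gev(maps, gfp, rand, protos)
                    <= compute_gev(maps, gfp, opt, protos) + 1e-12)


class TestCanonicalOrdering:
    def _protos(self, maps):
        return MicrostatePrototypes(maps=maps, labels=[str(i + 1) for i in
                                                       range(maps.shape[0])], gev=0.9)

    def test_identity_when_already_canonical(self, templates):
        p = order_canonically(self._protos(templates.maps.copy()), templates)
        np.testing.assert_allclose(p.maps, templates.maps, atol=1e-12)
        assert p.labels == ["A", "B", "C", "D"]

    def test_sign_flips_ignored(self, templates):
        flipped = templates.maps * np.asarray([-1, 1, -1, 1])[:, None]
        p = order_canonically(self._protos(flipped), templates)
        for j in range(4):
            assert abs(spatial_correlation(p.maps[j], templates.maps[j])) == \
                pytest.approx(1.0, abs=1e-12)

    def test_shuffle_inverted(self, templates, rng):
        perm = rng.permutation(4)
        p = order_canonically(self._protos(templates.maps[perm].copy()), templates)
        np.testing.assert_allclose(np.abs(p.maps @ templates.maps.T),
                                   np.abs(templates.maps @ templates.maps.T),
                                   atol=1e-9)
        for j in range(4):
            assert abs(spatial_correlation(p.maps[j], templates.maps[j])) == \
                pytest.approx(1.0, abs=1e-12)

    def test_matches_linear_sum_assignment_oracle(self, templates, rng):
        """Brute force over 24 permutations equals the Hungarian solution."""
        from scipy.optimize import linear_sum_assignment
        from microstatekit.microstates import _abs_corr_matrix
        noisy = templates.maps + 0.2 * random_maps(rng, 4, templates.maps.shape[1])
        noisy -= noisy.mean(axis=1, keepdims=True)
        noisy /= np.linalg.norm(noisy, axis=1, keepdims=True)
        p = order_canonically(self._protos(noisy[rng.permutation(4)].copy()),
                              templates)
        C = _abs_corr_matrix(p.maps, templates.maps)
        rows, cols = linear_sum_assignment(-C)
        assert np.array_equal(cols, np.arange(4))  # oracle agrees: identity


class TestBackfit:
    def test_exact_prototypes_fit_perfectly(self, templates):
        p = MicrostatePrototypes(maps=templates.maps, labels=list("ABCD"), gev=1.0)
        frames = templates.maps[[0, 3, 1, 2, 2, 0]].T[None] * 7.5
        ls = backfit(make_epochs(frames), p)
        assert ls.labels[0].tolist() == [0, 3, 1, 2, 2, 0]
        np.testing.assert_allclose(ls.fit, 1.0, atol=1e-12)

    def test_polarity_invariance(self, templates):
        p = MicrostatePrototypes(maps=templates.maps, labels=list("ABCD"), gev=1.0)
        frames = templates.maps[[2, 1, 0, 3]].T[None]
        a = backfit(make_epochs(frames), p)
        b = backfit(make_epochs(-frames), p)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_zero_gfp_frames_inherit_nearest_label(self, templates):
        p = MicrostatePrototypes(maps=templates.maps, labels=list("ABCD"), gev=1.0)
        frames = np.zeros((1, templates.maps.shape[1], 5))
        frames[0, :, 0] = templates.maps[2]
        frames[0, :, 4] = templates.maps[1]
        ls = backfit(make_epochs(frames), p)
        assert ls.labels[0].tolist() == [2, 2, 2, 1, 1]  # tie at centre -> left
        assert ls.fit[0, 1] == 0.0


class TestGmdAndSmoothing:
    def test_gmd_closed_forms(self, templates):
        a, b = templates.maps[0], templates.maps[1]
        assert gmd(a, a) == pytest.approx(0.0, abs=1e-9)
        assert gmd(a, -a) == pytest.approx(0.0, abs=1e-9)
        orth_a = np.asarray([1.0, -1.0, 0.0, 0.0])
        orth_b = np.asarray([0.0, 0.0, 1.0, -1.0])
        assert gmd(orth_a, orth_b) == pytest.approx(np.sqrt(2.0))

    def test_short_segment_absorbed(self, templates):
        """A(100 ms) B(8 ms) A(100 ms) becomes one 208 ms A segment."""
        p = MicrostatePrototypes(maps=templates.maps, labels=list("ABCD"), gev=1.0)
        nA, nB = 25, 2
        frames = np.concatenate([
            np.tile(templates.maps[0], (nA, 1)),
            # B-period frames: labelled B, but A is the next most similar class
            np.tile(0.6 * templates.maps[0] - 0.8 * templates.maps[1], (nB, 1)),
            np.tile(templates.maps[0], (nA, 1)),
        ]).T[None]
        ls = backfit(make_epochs(frames), p)
        assert ls.labels[0, nA] == 1  # the bridge really is labelled B first
        sm = smooth_segments(make_epochs(frames), ls, p, 30.0)
        assert np.all(sm.labels == 0)

    def test_all_long_segments_fixed_point(self, templates):
        p = MicrostatePrototypes(maps=templates.maps, labels=list("ABCD"), gev=1.0)
        frames = np.concatenate([np.tile(templates.maps[i], (10, 1))
                                 for i in range(4)]).T[None]
        ep = make_epochs(frames)
        ls = backfit(ep, p)
        sm = smooth_segments(ep, ls, p, 30.0)
        np.testing.assert_array_equal(sm.labels, ls.labels)

    def test_no_short_segments_survive(self, small_study):
        min_frames = int(np.ceil(30.0 * 250.0 / 1000.0))
        from microstatekit.features import segments_from_labels
        for ls in small_study.label_sequences.values():
            assert min(s.stop - s.start for s in segments_from_labels(ls)) >= min_frames

    def test_frame_count_conserved(self, small_study):
        for sid, ls in small_study.label_sequences.items():
            assert ls.labels.size == ls.fit.size
            assert ls.labels.shape[1] == 500


class TestEndToEndInvariances:
    def _mini_epochs(self, templates, rng, flip=1.0, perm=None):
        spec_maps = templates.maps if perm is None else templates.maps[:, perm]
        n_t = 250
        lab = np.repeat(np.arange(4), n_t // 4 + 1)[:n_t]
        carrier = np.sin(2 * np.pi * 10 * np.arange(n_t) / 250.0) + 1.2
        frames = spec_maps[lab].T * carrier
        frames = frames + 0.05 * rng.normal(size=frames.shape)
        frames -= frames.mean(axis=0, keepdims=True)
        return make_epochs(flip * frames[None])

    def test_polarity_invariance_end_to_end(self, templates):
        rng = np.random.default_rng(7)
        ep_pos = self._mini_epochs(templates, rng)
        rng = np.random.default_rng(7)
        ep_neg = self._mini_epochs(templates, rng, flip=-1.0)
        out = []
        for ep in (ep_pos, ep_neg):
            g = select_peaks(detect_gfp_peaks(compute_gfp(ep)),
                             rng=np.random.default_rng(0))
            p = modified_kmeans(extract_peak_maps(ep, g), k=4, n_restarts=10, seed=4)
            p = order_canonically(p, templates)
            ls = smooth_segments(ep, backfit(ep, p), p, 30.0)
            out.append((np.abs(p.maps), ls.labels))
        np.testing.assert_allclose(out[0][0], out[1][0], atol=1e-9)
        np.testing.assert_array_equal(out[0][1], out[1][1])

    def test_channel_permutation_equivariance(self, templates):
        c = templates.maps.shape[1]
        perm = np.random.default_rng(9).permutation(c)
        rng = np.random.default_rng(7)
        ep = self._mini_epochs(templates, rng)
        rng = np.random.default_rng(7)
        ep_perm = make_epochs(self._mini_epochs(templates, rng).data[:, perm, :])

        def run(e, maps):
            from types import SimpleNamespace
            g = select_peaks(detect_gfp_peaks(compute_gfp(e)),
                             rng=np.random.default_rng(0))
            p = modified_kmeans(extract_peak_maps(e, g), k=4, n_restarts=10, seed=4)
            # cluster numbering is arbitrary: fix identities canonically
            p = order_canonically(p, SimpleNamespace(maps=maps,
                                                     labels=list("ABCD")))
            ls = backfit(e, p)
            return p.gev, ls.labels

        gev_a, lab_a = run(ep, templates.maps)
        gev_b, lab_b = run(ep_perm, templates.maps[:, perm])
        assert gev_a == pytest.approx(gev_b, rel=1e-9)
        np.testing.assert_array_equal(lab_a, lab_b)
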