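"""dF/F pipeline and the spatial statistics computed on response images."""

import numpy as np
import pytest
import scipy.cluster.hierarchy as sch

from arborcable.imaging import (
    DistanceMatrix,
    ResponseImage,
    TrialVolumeSeries,
    average_trials,
    correlation_matrix,
    dff,
    distance_regression,
    gaussian_kernel,
    linkage_distances,
    normalize_distances,
    paired_comparison,
    pca_responses,
    peak_response,
    pixel_cv,
    smooth,
    zproject,
)


def image_set(arrays, labels=None):
    labels = labels or [f"o{i}" for i in range(len(arrays))]
    return {
        lab: ResponseImage(dff=np.asarray(a, float), odor_label=lab)
        for lab, a in zip(labels, arrays)
    }


class TestFrameOps:
    def test_zproject_identity_for_single_plane(self):
        data = np.random.default_rng(0).uniform(1, 2, size=(5, 1, 4, 4))
        trial = TrialVolumeSeries(data=data, volume_rate=2.0, baseline_s=1.0)
        assert np.array_equal(zproject(trial), data[:, 0])

    def test_zproject_means_planes(self):
        data = np.stack([np.ones((2, 4, 4)), 3 * np.ones((2, 4, 4))], axis=1)
        trial = TrialVolumeSeries(data=data, volume_rate=1.0, baseline_s=1.0)
        assert np.allclose(zproject(trial), 2.0)

    def test_dff_sign_conventions(self):
        frames = np.full((10, 2, 2), 100.0)
        frames[6] = 150.0
        frames[7] = 70.0
        out = dff(frames, baseline_volumes=5)
        assert np.allclose(out[:5], 0.0)
        assert np.allclose(out[6], 0.5)
        assert np.allclose(out[7], -0.3)

    def test_dff_masks_nonpositive_baseline(self, caplog):
        frames = np.ones((4, 2, 2))
        frames[:, 0, 0] = 0.0
        out = dff(frames, baseline_volumes=2)
        assert np.isnan(out[:, 0, 0]).all()
        assert np.isfinite(out[:, 1, 1]).all()

    def test_smooth_preserves_constant_and_mass(self):
        const = np.full((8, 8), 3.7)
        assert np.allclose(smooth(const), const)
        impulse = np.zeros((16, 16))
        impulse[8, 8] = 1.0
        out = smooth(impulse)
        assert out.sum() == pytest.approx(1.0)

    def test_smooth_matches_brute_force_convolution(self):
        rng = np.random.default_rng(1)
        img = rng.normal(size=(8, 8))
        kernel = gaussian_kernel(4, 1.0)
        # direct reflect-padded convolution oracle
        pad = 4
        padded = np.pad(img, pad, mode="symmetric")  # edge-reflecting boundary
        expected = np.empty_like(img)
        ky, kx = kernel.shape
        # even-size kernels are centered at index size // 2
        cy, cx = ky // 2, kx // 2
        for y in range(8):
            for x in range(8):
                acc = 0.0
                for i in range(ky):
                    for j in range(kx):
                        acc += (
                            kernel[i, j]
                            * padded[pad + y + cy - i, pad + x + cx - j]
                        )
                expected[y, x] = acc
        assert np.allclose(smooth(img), expected, atol=1e-12)


class TestPeakResponse:
    def make_series(self, peak_at, amplitude=1.0, T=30):
        series = np.zeros((T, 8, 8))
        series[peak_at] = amplitude
        return series

    def test_window_centered_on_peak(self):
        series = self.make_series(peak_at=18)
        roi = np.ones((8, 8), bool)
        img = peak_response(series, roi, volume_rate=6.5)
        assert img.peak_window == (17, 19)
        assert np.allclose(img.dff, 1.0 / 3.0)

    def test_inhibitory_peak_found_by_absolute_deflection(self):
        series = self.make_series(peak_at=18, amplitude=-1.0)
        roi = np.ones((8, 8), bool)
        img = peak_response(series, roi, volume_rate=6.5)
        assert img.peak_window == (17, 19)

    def test_flat_series_near_zero_image(self):
        series = np.zeros((30, 8, 8))
        roi = np.ones((8, 8), bool)
        img = peak_response(series, roi, volume_rate=6.5)
        assert np.allclose(img.dff, 0.0)

    def test_fixed_window_reused(self):
        series = self.make_series(peak_at=20)
        roi = np.ones((8, 8), bool)
        img = peak_response(series, roi, peak_window=(14, 16))
        assert img.peak_window == (14, 16)
        assert np.allclose(img.dff, 0.0)

    def test_edge_peak_clips_with_warning(self):
        series = self.make_series(peak_at=29, T=30)
        roi = np.ones((8, 8), bool)
        with pytest.warns(UserWarning, match="edge"):
            img = peak_response(series, roi, volume_rate=6.5)
        assert img.peak_window == (28, 29)


class TestAveraging:
    def test_identical_and_cancelling_trials(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(6, 6))
        same = average_trials([ResponseImage(a), ResponseImage(a.copy())])
        assert np.allclose(same.dff, a)
        zero = average_trials([ResponseImage(a), ResponseImage(-a)])
        assert np.allclose(zero.dff, 0.0)
        assert same.n_trials == 2

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            average_trials(
                [ResponseImage(np.zeros((4, 4))), ResponseImage(np.zeros((5, 5)))]
            )

    def test_extraction_commutes_with_averaging(self):
        # fixed peak window: mean of per-trial responses == response of the
        # mean series (all stages linear)
        rng = np.random.default_rng(2)
        trials = [rng.normal(size=(20, 8, 8)) for _ in range(3)]
        roi = np.ones((8, 8), bool)
        window = (10, 12)
        per_trial = [
            peak_response(smooth(t), roi, peak_window=window) for t in trials
        ]
        avg_then = peak_response(
            smooth(np.mean(trials, axis=0)), roi, peak_window=window
        )
        then_avg = average_trials(per_trial)
        assert np.allclose(then_avg.dff, avg_then.dff, atol=1e-9)


class TestPCA:
    def test_two_planted_orthogonal_modes_recovered(self):
        rng = np.random.default_rng(0)
        shape = (16, 16)
        m1 = np.zeros(shape); m1[:8] = 1.0
        m2 = np.zeros(shape); m2[:, :8] = 1.0
        m2 -= m2.mean(); m1 -= m1.mean()  # orthogonalish
        gains = rng.uniform(0.5, 1.5, size=(12, 2))
        images = [g1 * m1 + g2 * m2 for g1, g2 in gains]
        mask = np.ones(shape, bool)
        res = pca_responses(image_set(images), mask)
        # first two score images span the planted plane
        basis = np.column_stack([m1[mask], m2[mask]])
        q, _ = np.linalg.qr(basis)
        for k in range(2):
            v = res.component_images[k][mask]
            v = v / np.linalg.norm(v)
            proj = q @ (q.T @ v)
            angle = np.degrees(np.arccos(np.clip(np.linalg.norm(proj), -1, 1)))
            assert angle < 1.0
        assert res.variance_explained[:2].sum() > 0.999

    def test_variance_fractions_properties(self):
        rng = np.random.default_rng(3)
        images = [rng.normal(size=(10, 10)) for _ in range(5)]
        res = pca_responses(image_set(images), np.ones((10, 10), bool))
        v = res.variance_explained
        assert np.all(np.diff(v) <= 1e-12)
        assert v.sum() == pytest.approx(1.0)

    def test_score_images_orthogonal(self):
        rng = np.random.default_rng(4)
        images = [rng.normal(size=(12, 12)) for _ in range(6)]
        mask = np.ones((12, 12), bool)
        res = pca_responses(image_set(images), mask)
        for i in range(3):
            for j in range(i + 1, 3):
                dot = np.dot(res.component_images[i][mask],
                             res.component_images[j][mask])
                norm = np.linalg.norm(res.component_images[i][mask]) * \
                    np.linalg.norm(res.component_images[j][mask])
                assert abs(dot) / norm < 1e-9

    def test_identical_images_carry_no_odor_structure(self):
        # with per-odor (column) centering, identical images leave a rank-1
        # matrix: a single component with uniform odor loadings and nothing
        # beyond it
        img = np.random.default_rng(5).normal(size=(8, 8))
        res = pca_responses(image_set([img, img.copy(), img.copy()]),
                            np.ones((8, 8), bool))
        assert np.allclose(res.variance_explained[1:], 0.0, atol=1e-12)


class TestPixelCV:
    def test_identical_images_zero_cv(self):
        img = np.full((6, 6), 0.5)
        assert pixel_cv(image_set([img, img.copy()])) == pytest.approx(0.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        imgs = [0.5 + 0.2 * rng.uniform(size=(8, 8)) for _ in range(5)]
        cv1 = pixel_cv(image_set(imgs))
        cv2 = pixel_cv(image_set([2 * i for i in imgs]))
        assert cv1 == pytest.approx(cv2, rel=1e-12)

    def test_odor_specific_patterns_have_higher_cv(self):
        # shared mode scaled by gains vs odor-specific orthogonal patterns
        rng = np.random.default_rng(1)
        mode = 0.2 + rng.uniform(size=(12, 12))
        gains = rng.uniform(0.8, 1.2, size=6)
        shared = [g * mode for g in gains]
        specific = []
        for k in range(6):
            m = np.full((12, 12), 0.05)
            m[(2 * k) % 12 : (2 * k) % 12 + 2] = 1.0
            specific.append(m * np.mean(gains))
        assert pixel_cv(image_set(specific)) > pixel_cv(image_set(shared))

    def test_all_excluded_raises(self):
        imgs = [np.zeros((4, 4)), np.zeros((4, 4))]
        with pytest.raises(ValueError):
            pixel_cv(image_set(imgs))


class TestCorrelationAndLinkage:
    def test_self_and_negation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(6, 6))
        C = correlation_matrix(image_set([a, a.copy(), -a]),
                               np.ones((6, 6), bool))
        assert C.D[0, 1] == pytest.approx(1.0)
        assert C.D[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(C.D), 1.0)

    def test_matches_brute_force_pearson(self):
        rng = np.random.default_rng(1)
        imgs = [rng.normal(size=(5, 5)) for _ in range(4)]
        mask = np.ones((5, 5), bool)
        C = correlation_matrix(image_set(imgs), mask)
        for i in range(4):
            for j in range(4):
                x, y = imgs[i].ravel(), imgs[j].ravel()
                xc, yc = x - x.mean(), y - y.mean()
                r = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
                assert C.D[i, j] == pytest.approx(r, abs=1e-12)

    def test_twelve_odors_give_66_pairs(self):
        rng = np.random.default_rng(2)
        imgs = [rng.normal(size=(6, 6)) for _ in range(12)]
        C = correlation_matrix(image_set(imgs), np.ones((6, 6), bool))
        D, tree = linkage_distances(C)
        assert len(D.condensed()) == 66
        assert tree.merges.shape == (11, 4)

    def test_identical_rows_merge_first(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(6, 6))
        imgs = [a, a.copy()] + [rng.normal(size=(6, 6)) for _ in range(3)]
        C = correlation_matrix(image_set(imgs), np.ones((6, 6), bool))
        D, tree = linkage_distances(C)
        assert D.D[0, 1] == pytest.approx(0.0, abs=1e-9)
        assert set(tree.merges[0, :2].astype(int)) == {0, 1}

    def test_planted_groups_merge_within_first(self):
        rng = np.random.default_rng(4)
        g1 = rng.normal(size=(8, 8))
        g2 = rng.normal(size=(8, 8))
        imgs = [g1 + 0.05 * rng.normal(size=(8, 8)) for _ in range(3)] + [
            g2 + 0.05 * rng.normal(size=(8, 8)) for _ in range(3)
        ]
        C = correlation_matrix(image_set(imgs), np.ones((8, 8), bool))
        _, tree = linkage_distances(C)
        labels = sch.fcluster(tree.merges, 2, "maxclust")
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]


class TestDistances:
    def test_normalize_and_average(self):
        d1 = DistanceMatrix(["a", "b"], np.array([[0.0, 2.0], [2.0, 0.0]]))
        d2 = DistanceMatrix(["a", "b"], np.array([[0.0, 8.0], [8.0, 0.0]]))
        normed, mean = normalize_distances([d1, d2])
        assert normed[0].D.max() == 1.0 and normed[1].D.max() == 1.0
        assert mean.D[0, 1] == pytest.approx(1.0)
        # scaling a preparation leaves its normalized distances unchanged
        d3 = DistanceMatrix(["a", "b"], 7 * d1.D)
        assert np.allclose(normalize_distances([d3])[0][0].D, normed[0].D)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_distances([DistanceMatrix(["a", "b"], np.zeros((2, 2)))])


class TestRegression:
    def test_perfect_fit(self):
        a = np.linspace(0, 1, 66)
        r2, p, slope, intercept = distance_regression(a, a)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)

    def test_slope_recovery(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(size=66)
        b = 2 * a + 1e-9 * rng.normal(size=66)
        r2, p, slope, intercept = distance_regression(a, b)
        assert slope == pytest.approx(2.0, abs=1e-6)
        assert p < 1e-20

    def test_independent_vectors_usually_null(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(20):
            a, b = rng.uniform(size=66), rng.uniform(size=66)
            r2, p, *_ = distance_regression(a, b)
            hits += p < 0.05
        assert hits <= 4  # ~5% false positive rate

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError):
            distance_regression(np.ones(10), np.linspace(0, 1, 10))


class TestPairedComparison:
    def test_identical_vectors(self):
        v = np.arange(5.0)
        t, p = paired_comparison(v, v.copy())
        assert t == 0.0 and p == 1.0

    def test_constant_shift_highly_significant(self):
        rng = np.random.default_rng(0)
        before = rng.uniform(size=8)
        after = before + 1.0 + 1e-6 * rng.normal(size=8)
        t, p = paired_comparison(before, after)
        assert p < 1e-10 and t > 0

    def test_matches_textbook_formula(self):
        before = np.array([10.0, 12.0, 9.0, 11.0, 13.0])
        after = np.array([12.0, 13.0, 11.0, 12.0, 15.0])
        d = after - before
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        t, p = paired_comparison(before, after)
        assert t == pytest.approx(t_manual, rel=1e-12)
        assert 0 < p < 1
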