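import numpy as np
import pytest
from scipy import stats as sps

from quapos.tem import (
    CoherencyMap,
    GlobalCoherency,
    GrayImage2D,
    OrientationField,
    analyze_image,
    coherency,
    compute_gradient,
    dominant_angle_deg,
    global_coherency,
    gradient_to_orientation,
    local_coherency_map,
    q_tensor,
    replicate_alignment,
    roi_distributions,
    summarize_roi,
)
from quapos.synth import MembranePatternSpec, make_membrane_image

from conftest import make_grating


def field_of(img: np.ndarray) -> OrientationField:
    return gradient_to_orientation(compute_gradient(GrayImage2D(img)))


class TestQTensor:
    def test_single_pixel(self):
        q = q_tensor(np.array([0.0]), np.array([1.0]))
        assert q.qxx == pytest.approx(0.5)
        assert q.qxy == pytest.approx(0.0)
        assert q.weight_sum == pytest.approx(1.0)

    def test_perpendicular_cancellation(self):
        q = q_tensor(np.array([0.0, np.pi / 2]), np.array([1.0, 1.0]))
        assert q.qxx == pytest.approx(0.0, abs=1e-15)
        assert q.qxy == pytest.approx(0.0, abs=1e-15)

    def test_weighted_pair(self):
        # oracle: direct evaluation of the summand formula
        q = q_tensor(np.array([0.0, np.pi / 4]), np.array([1.0, 2.0]))
        assert q.qxx == pytest.approx(0.5)
        assert q.qxy == pytest.approx(1.0)

    def test_zero_weight_ignores_nan_theta(self):
        q = q_tensor(np.array([0.3, np.nan]), np.array([2.0, 0.0]))
        assert q.weight_sum == pytest.approx(2.0)
        assert coherency(q) == pytest.approx(1.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            q_tensor(np.array([]), np.array([]))


class TestCoherency:
    def test_identical_directors(self):
        q = q_tensor(np.full(5, 1.0), np.array([0.5, 1, 2, 3, 0.1]))
        assert coherency(q) == pytest.approx(1.0)

    def test_perpendicular_zero(self):
        q = q_tensor(np.array([0.0, np.pi / 2]), np.array([1.0, 1.0]))
        assert coherency(q) == pytest.approx(0.0, abs=1e-15)

    def test_three_angles_third(self):
        # oracle: |e^{i0} + e^{i pi} + e^{i pi/2}| / 3 = 1/3
        q = q_tensor(np.radians([0.0, 90.0, 45.0]), np.ones(3))
        assert coherency(q) == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_zero_weight_sum(self):
        q = q_tensor(np.array([np.nan]), np.array([0.0]))
        assert coherency(q) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_complex_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0, np.pi, 50)
        m = rng.uniform(0, 3, 50)
        q = q_tensor(theta, m)
        expect = np.abs(np.sum(m * np.exp(2j * theta))) / m.sum()
        assert coherency(q) == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_eigenvalue_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        theta = rng.uniform(0, np.pi, 30)
        m = rng.uniform(0, 2, 30)
        q = q_tensor(theta, m)
        Q = np.array([[q.qxx, q.qxy], [q.qxy, -q.qxx]])
        expect = 2 * np.linalg.eigvalsh(Q)[-1] / q.weight_sum
        assert coherency(q) == pytest.approx(expect, abs=1e-12)

    def test_unity_iff_identical(self):
        rng = np.random.default_rng(8)
        # forward: identical directors with positive weights -> 1
        q = q_tensor(np.full(10, 0.42), rng.uniform(0.1, 2, 10))
        assert coherency(q) == pytest.approx(1.0, abs=1e-12)
        # converse: non-identical directors -> strictly below 1
        q2 = q_tensor(np.array([0.4, 0.4, 0.5]), np.ones(3))
        assert coherency(q2) < 1.0 - 1e-4


class TestDominantAngle:
    def test_zero(self):
        assert dominant_angle_deg(q_tensor(np.zeros(3), np.ones(3))) == pytest.approx(0.0)

    def test_range_fold_170(self):
        q = q_tensor(np.radians(np.full(4, 170.0)), np.ones(4))
        assert dominant_angle_deg(q) == pytest.approx(170.0)

    def test_three_members_grid_oracle(self):
        # oracle: argmax of sum cos(2(theta - phi)) over a fine phi grid
        angles = np.radians([10.0, 20.0, 30.0])
        q = q_tensor(angles, np.ones(3))
        grid = np.linspace(0, np.pi, 200001)
        score = np.cos(2 * (angles[:, None] - grid[None, :])).sum(axis=0)
        expect = np.degrees(grid[np.argmax(score)])
        assert dominant_angle_deg(q) == pytest.approx(expect, abs=1e-3)
        assert dominant_angle_deg(q) == pytest.approx(20.0, abs=1e-9)

    def test_zero_tensor_nan(self):
        q = q_tensor(np.array([0.0, np.pi / 2]), np.ones(2))
        assert np.isnan(dominant_angle_deg(q))

    @pytest.mark.parametrize("shift", [10.0, 45.0, 90.0, 133.7])
    def test_rotation_equivariance(self, shift):
        rng = np.random.default_rng(12)
        theta = rng.uniform(0, np.pi, 40)
        m = rng.uniform(0.1, 2, 40)
        q1 = q_tensor(theta, m)
        q2 = q_tensor(theta + np.radians(shift), m)
        assert coherency(q1) == pytest.approx(coherency(q2), abs=1e-12)
        diff = (dominant_angle_deg(q2) - dominant_angle_deg(q1)) % 180.0
        assert diff == pytest.approx(shift, abs=1e-9) or diff == pytest.approx(
            shift - 180.0, abs=1e-9
        )


class TestLocalCoherencyMap:
    def test_uniform_grating_high_local(self):
        f = field_of(make_grating(96, 40.0, 12.0))
        cmap = local_coherency_map(f, np.ones(f.shape, bool))
        assert cmap.n_valid > 0
        assert cmap.valid_coherencies().min() > 0.95

    def test_white_noise_low_mean_local(self):
        # oracle: random-walk scaling of |sum e^{2i theta}| over 625-pixel boxes
        rng = np.random.default_rng(0)
        means = []
        for _ in range(100):
            f = field_of(rng.standard_normal((60, 60)))
            cmap = local_coherency_map(f, np.ones((60, 60), bool))
            means.append(cmap.valid_coherencies().mean())
        assert np.mean(means) < 0.3

    def test_too_small_roi_empty_map(self):
        f = field_of(make_grating(40, 0.0, 10.0))
        roi = np.zeros(f.shape, bool)
        roi[5:25, 5:25] = True  # 20x20: erosion by 14 leaves nothing
        cmap = local_coherency_map(f, roi)
        assert cmap.is_empty
        assert cmap.n_valid == 0

    def test_validity_is_erosion_by_box_radius_plus_two(self):
        f = field_of(make_grating(80, 0.0, 10.0))
        roi = np.zeros(f.shape, bool)
        roi[10:70, 10:70] = True
        cmap = local_coherency_map(f, roi, box_radius=12)
        expect = np.zeros(f.shape, bool)
        expect[24:56, 24:56] = True
        assert np.array_equal(cmap.valid_mask, expect)


class TestGlobalCoherency:
    def test_uniform_grating(self):
        f = field_of(make_grating(96, 75.0, 12.0))
        g = global_coherency(f, np.ones(f.shape, bool))
        assert g.coherency >= 0.95
        assert abs((g.angle_deg - 75.0 + 90) % 180 - 90) < 1.0

    def test_half_and_half_cancels(self):
        img = np.concatenate(
            [make_grating(96, 0.0, 12.0)[:, :48], make_grating(96, 90.0, 12.0)[:, 48:]],
            axis=1,
        )
        f = field_of(img)
        g = global_coherency(f, np.ones(f.shape, bool))
        assert g.coherency < 0.1

    def test_empty_eroded_roi_raises(self):
        f = field_of(make_grating(20, 0.0, 10.0))
        roi = np.zeros(f.shape, bool)
        roi[5:8, 5:8] = True  # 3x3 < 5x5 support
        with pytest.raises(ValueError, match="erosion"):
            global_coherency(f, roi)


class TestSummarizeRoi:
    def _map(self, values):
        vals = np.asarray(values, float)
        valid = np.ones(vals.shape, bool)
        return CoherencyMap(vals, np.zeros_like(vals), valid)

    def test_equal_values_ratio_one(self):
        s = summarize_roi("r", self._map([[0.5, 0.5]]), GlobalCoherency(0.5, 10.0, 99))
        assert s.mean_local_coherency == pytest.approx(0.5)
        assert s.ratio_global_to_local == pytest.approx(1.0)

    def test_arithmetic(self):
        s = summarize_roi("r", self._map([[0.2, 0.4, 0.6]]), GlobalCoherency(0.3, 0.0, 5))
        assert s.mean_local_coherency == pytest.approx(0.4)
        assert s.ratio_global_to_local == pytest.approx(0.75)

    def test_empty_map_keeps_global(self):
        empty = CoherencyMap(
            np.full((4, 4), np.nan), np.full((4, 4), np.nan), np.zeros((4, 4), bool)
        )
        s = summarize_roi("r", empty, GlobalCoherency(0.7, 42.0, 10))
        assert np.isnan(s.mean_local_coherency)
        assert np.isnan(s.ratio_global_to_local)
        assert s.global_coherency == pytest.approx(0.7)

    def test_patchwork_mean_local_exceeds_global(self):
        spec = MembranePatternSpec(
            size=120,
            wavelength=12,
            patch_grid=(2, 2),
            patch_directors_deg=(0.0, 45.0, 90.0, 135.0),
            seed=3,
        )
        img, _ = make_membrane_image(spec)
        f = field_of(img.pixels)
        roi = np.ones(f.shape, bool)
        s = summarize_roi("p", local_coherency_map(f, roi), global_coherency(f, roi))
        assert s.mean_local_coherency > s.global_coherency


class TestReplicateAlignment:
    def test_identical_angles(self):
        rep = replicate_alignment([37.0, 37.0, 37.0])
        assert rep.alignment == pytest.approx(1.0)
        assert rep.dominant_angle_deg == pytest.approx(37.0)

    def test_perpendicular_pair(self):
        assert replicate_alignment([0.0, 90.0]).alignment == pytest.approx(0.0, abs=1e-15)

    def test_two_against_one(self):
        # oracle: |2 e^{i0} + e^{i pi}| / 3 = 1/3
        rep = replicate_alignment([0.0, 0.0, 90.0])
        assert rep.alignment == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_periodicity(self):
        assert replicate_alignment([1.0, 181.0]).alignment == pytest.approx(1.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            replicate_alignment([])


class TestRoiDistributions:
    def _map_from(self, coh, ang):
        coh = np.atleast_2d(np.asarray(coh, float))
        ang = np.atleast_2d(np.asarray(ang, float))
        return CoherencyMap(coh, ang, np.ones(coh.shape, bool))

    def test_single_value_one_bin(self):
        cmap = self._map_from([0.52, 0.52, 0.52], [10.0, 10.0, 10.0])
        d = roi_distributions(cmap, GlobalCoherency(0.5, 10.0, 3))
        assert np.count_nonzero(d.coherency_density) == 1
        assert np.count_nonzero(d.angle_counts) == 1

    def test_uniform_directors_flat_histogram(self):
        rng = np.random.default_rng(5)
        n = 10_000
        cmap = self._map_from(rng.uniform(0, 1, n), rng.uniform(0, 180, n))
        d = roi_distributions(cmap, GlobalCoherency(0.1, 0.0, n), angle_bins=18)
        chi2 = sps.chisquare(d.angle_counts)
        assert chi2.pvalue > 0.01

    def test_grating_concentrated(self):
        f = field_of(make_grating(96, 63.0, 12.0))
        roi = np.ones(f.shape, bool)
        cmap = local_coherency_map(f, roi)
        d = roi_distributions(cmap, global_coherency(f, roi))
        assert d.angle_counts.max() / d.angle_counts.sum() > 0.95

    def test_empty_raises(self):
        empty = CoherencyMap(
            np.full((2, 2), np.nan), np.full((2, 2), np.nan), np.zeros((2, 2), bool)
        )
        with pytest.raises(ValueError):
            roi_distributions(empty, GlobalCoherency(0.0, 0.0, 0))


class TestDisorderMonotonicity:
    def test_coherency_decreases_with_jitter(self):
        sigmas = [0.0, 10.0, 20.0, 40.0]
        glob, loc = [], []
        for sigma in sigmas:
            gs, ls = [], []
            for seed in range(20):
                spec = MembranePatternSpec(
                    size=96, director_deg=30.0, wavelength=12, jitter_deg=sigma, seed=seed
                )
                img, _ = make_membrane_image(spec)
                f = field_of(img.pixels)
                roi = np.ones(f.shape, bool)
                gs.append(global_coherency(f, roi).coherency)
                ls.append(local_coherency_map(f, roi).valid_coherencies().mean())
            glob.append(np.mean(gs))
            loc.append(np.mean(ls))
        assert np.all(np.diff(glob) < 0)
        assert np.all(np.diff(loc) < 0)


class TestAnalyzeImage:
    def test_full_pipeline_on_grating(self):
        img = GrayImage2D(make_grating(96, 20.0, 12.0))
        masks = {"a": np.ones(img.shape, bool)}
        summaries, maps = analyze_image(img, masks)
        assert len(summaries) == 1
        s = summaries[0]
        assert s.roi_id == "a"
        assert s.global_coherency > 0.95
        assert s.ratio_global_to_local == pytest.approx(1.0, abs=0.05)
        assert maps["a"].n_valid == s.n_valid_local

    def test_downsampling_factors(self):
        img = GrayImage2D(make_grating(192, 20.0, 24.0))
        masks = {"a": np.ones(img.shape, bool)}
        summaries, _ = analyze_image(img, masks, downsample_gray_factor=2)
        assert summaries[0].global_coherency > 0.9
        assert abs((summaries[0].global_angle_deg - 20.0 + 90) % 180 - 90) < 2.0
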