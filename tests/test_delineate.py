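import warnings

import numpy as np
import pytest

import petdelin as p
from petdelin.core import BinaryMask, BoundingBox, GridSpec, VoxelVolume
from petdelin.delineate import CalibrationSample, METHOD_REGISTRY, optimal_threshold
from petdelin.phantoms import CylinderBody, PhantomSpec, SphereLesion
from petdelin.simulate import gaussian_blur


UNIT = GridSpec((12, 12, 12), (1.0, 1.0, 1.0))
FULL = BoundingBox((0, 0, 0), (12, 12, 12))


def cube(values):
    arr = np.zeros((12, 12, 12))
    flat = np.asarray(values, dtype=float).ravel()
    arr.ravel()[: flat.size] = flat
    return VoxelVolume(arr, UNIT)


class TestVoiStats:
    def test_uniform_voi(self):
        vol = VoxelVolume(np.full((12, 12, 12), 3.0), UNIT)
        s = p.voi_stats(vol, FULL)
        assert s.suv_max == 3.0 and s.m_suv70 == 3.0

    def test_msuv70_cut(self):
        # values {10, 8, 6, 1}: cut at 7 keeps {10, 8}, mean 9
        vol = cube([10, 8, 6, 1])
        s = p.voi_stats(vol, BoundingBox((0, 0, 0), (1, 1, 4)))
        assert s.suv_max == 10.0
        assert s.m_suv70 == pytest.approx(9.0)

    def test_msuv70_never_exceeds_max(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            vol = VoxelVolume(rng.random((12, 12, 12)) * 10, UNIT)
            s = p.voi_stats(vol, FULL)
            assert s.m_suv70 <= s.suv_max


class TestApplyThreshold:
    def test_zero_threshold_keeps_whole_voi(self):
        vol = VoxelVolume(np.random.default_rng(0).random((12, 12, 12)), UNIT)
        voi = BoundingBox((2, 2, 2), (6, 7, 8))
        mask = p.apply_threshold(vol, voi, 0.0)
        assert mask.voxel_count == voi.n_voxels

    def test_above_max_threshold_empty(self):
        vol = cube([3, 4, 5, 10])
        assert p.apply_threshold(vol, FULL, 10.5).voxel_count == 0

    def test_inclusive_comparison(self):
        vol = cube([3, 4, 5, 10])
        mask = p.apply_threshold(vol, BoundingBox((0, 0, 0), (1, 1, 4)), 4.0)
        assert mask.voxel_count == 3  # {4, 5, 10}: boundary voxel kept

    def test_threshold_monotonicity_property(self):
        rng = np.random.default_rng(2)
        vol = VoxelVolume(rng.random((12, 12, 12)) * 8, UNIT)
        for _ in range(20):
            t1, t2 = sorted(rng.random(2) * 8)
            m1 = p.apply_threshold(vol, FULL, t1)
            m2 = p.apply_threshold(vol, FULL, t2)
            assert not (m2.values & ~m1.values).any()  # mask(T2) subset of mask(T1)


class TestFixedAndAdaptive:
    def test_fixed_threshold_value(self):
        vol = cube([10, 2, 3])
        mask, rule = p.delineate_fixed(vol, FULL, 0.4)
        assert rule.threshold_value == pytest.approx(4.0)

    def test_uniform_voi_fully_delineated(self):
        vol = VoxelVolume(np.full((12, 12, 12), 6.0), UNIT)
        for frac in (0.4, 0.5, 1.0):
            mask, _ = p.delineate_fixed(vol, FULL, frac)
            assert mask.voxel_count == FULL.n_voxels

    def test_t50_subset_of_t40(self):
        vol = VoxelVolume(np.random.default_rng(3).random((12, 12, 12)) * 9, UNIT)
        m40, _ = p.delineate_fixed(vol, FULL, 0.4)
        m50, _ = p.delineate_fixed(vol, FULL, 0.5)
        assert not (m50.values & ~m40.values).any()

    def test_adaptive_threshold_formula(self):
        vol = cube([10, 1])
        bg = p.BackgroundStats(2.0, (0, 0, 0))
        _, r40 = p.delineate_adaptive(vol, FULL, bg, 0.4)
        _, r50 = p.delineate_adaptive(vol, FULL, bg, 0.5)
        assert r40.threshold_value == pytest.approx(0.4 * (10 - 2) + 2)  # 5.2
        assert r50.threshold_value == pytest.approx(6.0)

    def test_zero_background_reduces_to_fixed(self):
        vol = VoxelVolume(np.random.default_rng(4).random((12, 12, 12)) * 7, UNIT)
        bg = p.BackgroundStats(0.0, (0, 0, 0))
        ma, ra = p.delineate_adaptive(vol, FULL, bg, 0.4)
        mf, rf = p.delineate_fixed(vol, FULL, 0.4)
        assert ra.threshold_value == rf.threshold_value
        assert (ma.values == mf.values).all()

    def test_adaptive_above_fixed_with_positive_background(self):
        vol = VoxelVolume(np.random.default_rng(5).random((12, 12, 12)) * 9 + 1, UNIT)
        bg = p.BackgroundStats(1.5, (0, 0, 0))
        ma, ra = p.delineate_adaptive(vol, FULL, bg, 0.4)
        mf, rf = p.delineate_fixed(vol, FULL, 0.4)
        assert ra.threshold_value > rf.threshold_value
        assert not (ma.values & ~mf.values).any()

    def test_no_contrast_warns_and_returns_empty(self):
        vol = VoxelVolume(np.full((12, 12, 12), 2.0), UNIT)
        bg = p.BackgroundStats(5.0, (0, 0, 0))
        with pytest.warns(UserWarning, match="does not exceed background"):
            mask, _ = p.delineate_adaptive(vol, FULL, bg, 0.4)
        assert mask.voxel_count == 0


class TestBackgroundRoi:
    def test_uniform_image(self):
        vol = VoxelVolume(np.full((30, 30, 30), 5.2), GridSpec((30, 30, 30), (4, 4, 2)))
        bg = p.measure_background(vol, (15, 15, 15))
        assert bg.bg_mean == pytest.approx(5.2)

    def test_roi_voxel_count_matches_brute_force(self):
        vol = VoxelVolume(np.ones((30, 30, 30)), GridSpec((30, 30, 30), (4, 4, 2)))
        center, d = (15, 14, 16), 20
        # independent scan
        expected = sum(
            (i - center[0]) ** 2 + (j - center[1]) ** 2 + (k - center[2]) ** 2 <= (d / 2) ** 2
            for i in range(30) for j in range(30) for k in range(30))
        # spike the centre voxel: ROI mean = 1 + 1/N reveals the ROI voxel count N
        vol2 = VoxelVolume(np.ones((30, 30, 30)), vol.grid)
        vol2.values[center[0], center[1], center[2]] = 2.0
        bg = p.measure_background(vol2, center, d)
        count = round(1.0 / (bg.bg_mean - 1.0))
        assert count == expected

    def test_clipped_roi_is_an_error(self):
        vol = VoxelVolume(np.ones((30, 30, 30)), GridSpec((30, 30, 30), (4, 4, 2)))
        with pytest.raises(ValueError, match="clipped"):
            p.measure_background(vol, (5, 15, 15))

    def test_noiseless_phantom_background(self):
        spec = p.build_nema_iq_spec(8, p.standard_grid(200, nz=75))
        act, _ = p.voxelize(spec)
        # on-axis, ~45 mm above the sphere plane: inside the body, clear of spheres
        bg = p.measure_background(act, (100, 100, 59))
        assert bg.bg_mean == pytest.approx(5.2)


def _manufactured_samples(a, b, n_samples, seed):
    """Samples whose volume-matched optimal threshold is exactly a*mSUV70 + b*BG.

    Image values are dense enough that every grid threshold changes the
    thresholded volume, so the search has a unique optimum; BG is chosen so the
    target threshold falls exactly on one of the 200 search-grid points.
    """
    rng = np.random.default_rng(seed)
    grid = GridSpec((8, 8, 8), (1.0, 1.0, 1.0))
    voi = BoundingBox((0, 0, 0), (8, 8, 8))
    samples = []
    while len(samples) < n_samples:
        h = float(rng.uniform(8, 20))
        vals = np.linspace(rng.uniform(0.3, 1.0), h, 512)
        img = VoxelVolume(rng.permutation(vals).reshape(8, 8, 8), grid)
        m70 = p.voi_stats(img, voi).m_suv70
        k = int(rng.integers(60, 180))
        c = k / 199.0
        bg_val = (c * h - a * m70) / (b - (1 - c))  # solve t_grid[k] == a*m70 + b*bg
        if not (0.05 < bg_val < 0.6 * h):
            continue
        t_star = a * m70 + b * bg_val
        gt = BinaryMask(img.values >= t_star, grid)
        if gt.voxel_count in (0, 512):
            continue
        samples.append(CalibrationSample(img, voi, p.BackgroundStats(bg_val, (0, 0, 0)), gt))
    return samples


class TestCtCalibration:
    def test_recovers_manufactured_coefficients(self):
        samples = _manufactured_samples(0.5, 0.5, 12, seed=0)
        calib = p.calibrate_ct(samples)
        assert calib.a == pytest.approx(0.5, abs=1e-6)
        assert calib.b == pytest.approx(0.5, abs=1e-6)
        assert calib.fit_rmse < 1e-9

    def test_recovers_other_coefficients(self):
        samples = _manufactured_samples(0.62, 0.31, 12, seed=1)
        calib = p.calibrate_ct(samples)
        assert calib.a == pytest.approx(0.62, abs=1e-3)
        assert calib.b == pytest.approx(0.31, abs=1e-3)

    def test_zero_background_design_is_degenerate(self):
        rng = np.random.default_rng(2)
        grid = GridSpec((8, 8, 8), (1.0, 1.0, 1.0))
        voi = BoundingBox((0, 0, 0), (8, 8, 8))
        samples = []
        for _ in range(4):
            img = VoxelVolume(rng.random((8, 8, 8)) * 10, grid)
            gt = BinaryMask(img.values >= 5.0, grid)
            samples.append(CalibrationSample(img, voi, p.BackgroundStats(0.0, (0, 0, 0)), gt))
        with pytest.raises(ValueError, match="rank deficient"):
            p.calibrate_ct(samples)
        calib = p.calibrate_ct(samples, allow_a_only=True)
        assert calib.b == 0.0 and calib.a > 0

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            p.calibrate_ct(_manufactured_samples(0.5, 0.5, 1, seed=3))

    def test_optimal_threshold_between_bg_and_max_on_blurred_sphere(self):
        grid = GridSpec((40, 40, 30), (4.0, 4.0, 4.0))
        spec = PhantomSpec(CylinderBody(150, 110), 5.2,
                           [SphereLesion((0, 0, 0), 28.0, 8.0)], grid)
        act, masks = p.voxelize(spec)
        img = gaussian_blur(act, 7.0)
        voi = BoundingBox.from_mask(masks[0], margin=4)
        bg = p.measure_background(img, (20, 20, 25), diameter_voxels=8)
        t = optimal_threshold(img, voi, bg, masks[0])
        s = p.voi_stats(img, voi)
        assert bg.bg_mean < t < s.suv_max
        # the matched threshold reproduces the GT volume closely
        vol = p.apply_threshold(img, voi, t).voxel_count
        assert abs(vol - masks[0].voxel_count) <= 3


class TestDelineateCt:
    def test_threshold_formula(self):
        vol = cube([10, 8, 2])
        calib = p.CtCalibration(0.5, 0.5, 0.0, 12)
        bg = p.BackgroundStats(2.0, (0, 0, 0))
        voi = BoundingBox((0, 0, 0), (1, 1, 3))
        _, rule = p.delineate_ct(vol, voi, bg, calib)
        # mSUV70 = mean{10, 8} = 9 -> T = 0.5*9 + 0.5*2 = 5.5
        assert rule.threshold_value == pytest.approx(5.5)

    def test_b_zero_behaves_as_msuv70_fraction(self):
        vol = VoxelVolume(np.full((12, 12, 12), 4.0), UNIT)
        calib = p.CtCalibration(0.4, 0.0, 0.0, 12)
        bg = p.BackgroundStats(1.0, (0, 0, 0))
        mask, rule = p.delineate_ct(vol, FULL, bg, calib)
        assert rule.threshold_value == pytest.approx(0.4 * 4.0)
        assert mask.voxel_count == FULL.n_voxels

    def test_threshold_above_max_warns_empty(self):
        vol = VoxelVolume(np.full((12, 12, 12), 1.0), UNIT)
        calib = p.CtCalibration(2.0, 2.0, 0.0, 12)
        bg = p.BackgroundStats(3.0, (0, 0, 0))
        with pytest.warns(UserWarning, match="exceeds SUVmax"):
            mask, _ = p.delineate_ct(vol, FULL, bg, calib)
        assert mask.voxel_count == 0

    def test_calibration_json_round_trip(self, tmp_path):
        calib = p.CtCalibration(0.51, 0.43, 0.02, 24)
        path = tmp_path / "ct.json"
        calib.save(path)
        assert p.CtCalibration.load(path) == calib


class TestRegistry:
    def test_flab_is_registered_but_unavailable(self):
        assert "FLAB" in METHOD_REGISTRY
        assert not METHOD_REGISTRY["FLAB"]["available"]
        assert "FLAB" not in p.available_methods()
        with pytest.raises(NotImplementedError, match="FLAB"):
            p.flab_stub()

    def test_unknown_method_key(self):
        vol = VoxelVolume(np.ones((12, 12, 12)), UNIT)
        with pytest.raises(KeyError):
            p.delineate("T60", vol, FULL)

    def test_dispatch_matches_direct_calls(self):
        vol = VoxelVolume(np.random.default_rng(6).random((12, 12, 12)) * 9, UNIT)
        bg = p.BackgroundStats(1.0, (0, 0, 0))
        m1, _ = p.delineate("AT40", vol, FULL, bg=bg)
        m2, _ = p.delineate_adaptive(vol, FULL, bg, 0.4)
        assert (m1.values == m2.values).all()
        with pytest.raises(ValueError, match="background"):
            p.delineate("AT40", vol, FULL)
        with pytest.raises(ValueError, match="CtCalibration"):
            p.delineate("CT", vol, FULL, bg=bg)
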