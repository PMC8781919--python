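import numpy as np
import pytest

from cbreco import (
    BHCParams,
    NormalizationConfig,
    OutlierConfig,
    ProjectionStack,
    apply_scm,
    bhc_correct,
    build_scm_dlr,
    calibrate_bhc,
    find_outlier_mask,
    normalize,
    repair_defects,
    to_attenuation,
)


def _stack(data, stage="raw"):
    return ProjectionStack(np.asarray(data, dtype=float), stage)


def _uniform_raw(n_proj=4, n=8, raw=150.0, dark=50.0, flat=250.0):
    raw_stack = _stack(np.full((n_proj, n, n), raw))
    cfg = NormalizationConfig("flat_mean", dark=np.full((n, n), dark),
                              flat=np.full((n, n), flat))
    return raw_stack, cfg


class TestNormalize:
    def test_flat_mean_arithmetic(self):
        raw, cfg = _uniform_raw()
        out = normalize(raw, cfg)
        # (150-50)/(250-50) * mean(flat-dark) / mean(flat-dark) = 0.5
        assert np.allclose(out.data, 0.5)
        assert out.stage == "normalized"

    def test_full_transmission_maps_to_one(self):
        n = 8
        raw = _stack(np.full((3, n, n), 250.0))
        cfg = NormalizationConfig("flat_mean", dark=np.zeros((n, n)),
                                  flat=np.full((n, n), 250.0))
        assert np.allclose(normalize(raw, cfg).data, 1.0)

    def test_roi_background_maps_to_one(self):
        n = 8
        data = np.full((3, n, n), 400.0)
        data[:, 4:, :] = 100.0  # "object" below the ROI
        raw = _stack(data)
        cfg = NormalizationConfig("roi_fluence", dark=np.zeros((n, n)),
                                  flat=np.full((n, n), 200.0), roi=(0, 0, n, 2))
        out = normalize(raw, cfg)
        assert np.allclose(out.data[:, :2, :], 1.0)

    def test_per_projection_fluence_upscaling(self):
        n = 4
        raw = _stack(np.full((2, n, n), 150.0))
        fl = [300.0, 150.0]
        cfg = NormalizationConfig("none", dark=np.full((n, n), 50.0),
                                  flat=np.full((n, n), 250.0),
                                  per_projection_fluence=fl)
        out = normalize(raw, cfg)
        # (150-50)/200 * (fl - mean(dark))
        assert np.allclose(out.data[0], 0.5 * 250.0)
        assert np.allclose(out.data[1], 0.5 * 100.0)

    def test_homogeneity_in_counts(self):
        # scaling (raw - dark) and (flat - dark) jointly leaves output unchanged
        rng = np.random.default_rng(0)
        n = 8
        base = rng.uniform(0.2, 1.0, size=(3, n, n))
        flat = rng.uniform(180.0, 220.0, size=(n, n))
        dark = np.full((n, n), 40.0)
        for mode, roi in [("flat_mean", None), ("roi_fluence", (0, 0, 3, 3))]:
            raw1 = _stack(dark + base * (flat - dark))
            raw2 = _stack(dark + 7.5 * base * (flat - dark))
            cfg1 = NormalizationConfig(mode, dark=dark, flat=flat, roi=roi)
            cfg2 = NormalizationConfig(mode, dark=dark, flat=dark + 7.5 * (flat - dark), roi=roi)
            assert np.allclose(normalize(raw1, cfg1).data,
                               normalize(raw2, cfg2).data)

    def test_unusable_flat_rejected(self):
        raw, _ = _uniform_raw()
        cfg_bad = NormalizationConfig("flat_mean", dark=np.full((8, 8), 250.0),
                                      flat=np.full((8, 8), 50.0))
        with pytest.raises(ValueError, match="flat"):
            normalize(raw, cfg_bad)

    def test_roi_outside_detector_rejected(self):
        with pytest.raises(ValueError, match="ROI"):
            NormalizationConfig("roi_fluence", dark=np.zeros((8, 8)),
                                flat=np.ones((8, 8)), roi=(6, 6, 4, 4))
        with pytest.raises(ValueError, match="area"):
            NormalizationConfig("roi_fluence", dark=np.zeros((8, 8)),
                                flat=np.ones((8, 8)), roi=(0, 0, 0, 2))


class TestToAttenuation:
    @pytest.mark.parametrize("value,expected", [
        (1.0, 0.0),
        (np.exp(-2.0), 2.0),
        (0.0, -np.log(1e-6)),
    ])
    def test_log_with_clamp(self, value, expected):
        stack = _stack(np.full((2, 4, 4), value), "normalized")
        assert np.allclose(to_attenuation(stack).data, expected)

    def test_no_object_scan_gives_zero_attenuation(self):
        n = 8
        flat = np.full((n, n), 220.0)
        raw = _stack(np.broadcast_to(flat, (3, n, n)))
        cfg = NormalizationConfig("flat_mean", dark=np.full((n, n), 20.0), flat=flat)
        att = to_attenuation(normalize(raw, cfg))
        assert np.allclose(att.data, 0.0, atol=1e-12)

    def test_requires_normalized_stage(self):
        with pytest.raises(ValueError, match="normalized"):
            to_attenuation(_stack(np.ones((2, 4, 4)), "raw"))


class TestBeamHardening:
    def test_identity_when_b_zero(self):
        stack = _stack(np.linspace(0, 2, 32).reshape(2, 4, 4), "attenuation")
        out = bhc_correct(stack, BHCParams(a=1.0, b=0.0, c=2.0))
        assert np.allclose(out.data, stack.data)

    def test_cubic_example(self):
        stack = _stack(np.full((1, 2, 2), 2.0), "attenuation")
        out = bhc_correct(stack, BHCParams(a=1.0, b=1.0, c=3.0))
        assert np.allclose(out.data, 10.0)

    def test_zero_maps_to_zero(self):
        stack = _stack(np.zeros((1, 2, 2)), "attenuation")
        for params in [BHCParams(1, 1, 3), BHCParams(0.5, 2.0, 2.2)]:
            assert np.allclose(bhc_correct(stack, params).data, 0.0)

    def test_negative_exponent_rejected(self):
        with pytest.raises(ValueError):
            BHCParams(a=1.0, b=1.0, c=-1.0)

    def test_calibration_recovers_linearizing_polynomial(self):
        # invert a known mildly saturating curve
        p = np.linspace(0.0, 1.0, 100)
        measured = p - 0.15 * p**2.5
        params = calibrate_bhc(measured, p)
        corrected = params.a * measured + params.b * measured**params.c
        assert 2.0 <= params.c <= 3.0
        assert np.abs(corrected - p).max() < 0.01


def _oracle_outlier_mask(stack_data, sigma_mult, w, h):
    """Literal re-implementation with naive loops: mean image, median blur
    (symmetric edge padding), abs difference, z-score threshold."""
    mean_img = stack_data.mean(axis=0)
    pad_v, pad_u = h // 2, w // 2
    padded = np.pad(mean_img, ((pad_v, pad_v), (pad_u, pad_u)), mode="symmetric")
    blurred = np.empty_like(mean_img)
    for i in range(mean_img.shape[0]):
        for j in range(mean_img.shape[1]):
            blurred[i, j] = np.median(padded[i:i + h, j:j + w])
    diff = np.abs(mean_img - blurred)
    if diff.std() == 0:
        return np.zeros_like(diff, dtype=bool)
    z = (diff - diff.mean()) / diff.std()
    return z > sigma_mult


class TestOutlierMask:
    def test_single_stuck_pixel_flagged_exactly(self):
        data = np.full((3, 16, 16), 100.0)
        data[:, 7, 9] = 1100.0
        mask = find_outlier_mask(_stack(data), OutlierConfig(3.0, (5, 5)))
        assert mask[7, 9]
        assert mask.sum() == 1

    def test_matches_bruteforce_oracle(self, rng):
        data = rng.uniform(90.0, 110.0, size=(4, 16, 16))
        data[:, 3, 12] = 500.0
        data[:, 11, 2] = 0.0
        mask = find_outlier_mask(_stack(data), OutlierConfig(3.0, (5, 5)))
        oracle = _oracle_outlier_mask(data, 3.0, 5, 5)
        assert np.array_equal(mask, oracle)
        assert mask[3, 12] and mask[11, 2]

    def test_constant_stack_empty_mask(self):
        mask = find_outlier_mask(_stack(np.full((3, 8, 8), 5.0)))
        assert not mask.any()

    def test_defect_row_flagged(self, rng):
        data = rng.uniform(95.0, 105.0, size=(5, 16, 16))
        data[:, 6, :] = 900.0
        mask = find_outlier_mask(_stack(data), OutlierConfig(3.0, (3, 3)))
        oracle = _oracle_outlier_mask(data, 3.0, 3, 3)
        assert mask[6, :].all()
        assert np.array_equal(mask, oracle)

    def test_needs_two_projections(self):
        with pytest.raises(ValueError):
            find_outlier_mask(_stack(np.ones((1, 8, 8))))


class TestRepairDefects:
    def test_hot_pixel_in_constant_image(self):
        data = np.full((2, 8, 8), 5.0)
        data[:, 4, 4] = 999.0
        mask = np.zeros((8, 8), dtype=bool)
        mask[4, 4] = True
        out = repair_defects(_stack(data), mask)
        assert np.allclose(out.data, 5.0)

    def test_empty_mask_is_identity(self, rng):
        data = rng.standard_normal((3, 8, 8))
        out = repair_defects(_stack(data), np.zeros((8, 8), dtype=bool))
        assert np.array_equal(out.data, data)

    def test_masked_line_in_gradient_matches_median_oracle(self):
        # horizontal gradient; masked vertical line must take row medians of
        # the valid neighbours
        n = 11
        img = np.tile(np.arange(n, dtype=float), (n, 1))
        data = img[None]
        mask = np.zeros((n, n), dtype=bool)
        mask[:, 5] = True
        out = repair_defects(_stack(data), mask, window=3)
        # valid neighbours in each 3x3 window are columns 4 and 6 -> median 5
        assert np.allclose(out.data[0][:, 5], 5.0)
        assert np.array_equal(out.data[0][:, :5], img[:, :5])

    def test_idempotent_for_fixed_mask(self, rng):
        data = rng.uniform(0, 10, size=(2, 12, 12))
        mask = rng.uniform(size=(12, 12)) < 0.1
        once = repair_defects(_stack(data), mask)
        twice = repair_defects(once, mask)
        assert np.allclose(once.data, twice.data)

    def test_fully_masked_window_grows(self):
        data = np.full((1, 9, 9), 7.0)
        data[:, 3:6, 3:6] = -1.0
        mask = np.zeros((9, 9), dtype=bool)
        mask[3:6, 3:6] = True
        out = repair_defects(_stack(data), mask, window=3)
        assert np.allclose(out.data, 7.0)


class TestSensitivityMatrix:
    def test_uniform_gain_gives_unit_scm(self, rng):
        # spatially uniform frames (all adjacent-pixel ratios exactly 1),
        # with per-projection intensity jitter
        levels = rng.uniform(0.9, 1.1, size=60)
        data = np.ones((60, 16, 32)) * levels[:, None, None]
        scm = build_scm_dlr(ProjectionStack(data, "normalized"))
        assert np.allclose(scm, 1.0, atol=1e-6)
        assert scm.mean() == pytest.approx(1.0, abs=1e-6)

    def test_apply_unit_scm_is_identity(self, rng):
        data = rng.uniform(0.5, 1.0, size=(3, 8, 8))
        stack = ProjectionStack(data, "normalized")
        out = apply_scm(stack, np.ones((8, 8)))
        assert np.array_equal(out.data, data)

    def test_gain_divide_round_trip(self, rng):
        data = rng.uniform(0.5, 1.0, size=(3, 8, 8))
        gain = rng.uniform(0.9, 1.1, size=(8, 8))
        corrupted = ProjectionStack(data * gain, "normalized")
        assert np.allclose(apply_scm(corrupted, gain).data, data)

    def test_requires_normalized_stage(self):
        with pytest.raises(ValueError):
            build_scm_dlr(_stack(np.ones((60, 8, 8)), "attenuation"))
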