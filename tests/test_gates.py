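"""Gates chain: TAC extraction, depth/dose corrections, uptake, regression."""

import math

import numpy as np
import pytest

from splitgfr import (
    DynamicRenogram,
    InjectionRecord,
    PatientBiometrics,
    RoiSet,
    ToolConfig,
)
from splitgfr.gates import (
    DepthCorrection,
    extract_tac,
    frame_window_weights,
    gates_gfr_from_uptake,
    gates_pipeline,
    kidney_depth,
    net_injected_counts,
    renal_uptake_fractions,
)
from splitgfr.plasma import body_surface_area, normalize_to_bsa


# ---------------------------------------------------------------- TACs


def _two_frame_stack():
    frames = np.array([[[1, 2], [3, 4]], [[5, 6], [7, 8]]], dtype=np.int64)
    return DynamicRenogram(
        frames=frames,
        frame_start_s=np.array([0.0, 2.0]),
        frame_duration_s=np.array([2.0, 2.0]),
    )


def test_extract_tac_hand_sums():
    reno = _two_frame_stack()
    col0 = np.array([[True, False], [True, False]])
    tac = extract_tac(reno, col0)
    assert tac.counts.tolist() == [4.0, 12.0]
    assert tac.count_rates.tolist() == [2.0, 6.0]
    all_on = np.ones((2, 2), bool)
    assert extract_tac(reno, all_on).counts.tolist() == [10.0, 26.0]
    single = np.zeros((2, 2), bool)
    single[1, 1] = True
    assert extract_tac(reno, single).counts.tolist() == [4.0, 8.0]


def test_extract_tac_rejects_empty_or_mismatched_mask():
    reno = _two_frame_stack()
    with pytest.raises(ValueError):
        extract_tac(reno, np.zeros((2, 2), bool))
    with pytest.raises(ValueError):
        extract_tac(reno, np.zeros((3, 3), bool))


# ---------------------------------------------------------------- depth


def test_tonnesen_depths_hand_values(biometrics):
    dl, dr = kidney_depth(biometrics)
    assert dl == pytest.approx(6.1353, abs=1e-4)
    assert dr == pytest.approx(6.1765, abs=1e-4)


def test_depth_intercept_limit():
    dl, dr = kidney_depth(PatientBiometrics(height_cm=250.0, weight_kg=2.0))
    assert dl == pytest.approx(0.7, abs=0.11)  # W/H -> 0 limit approaches 0.7
    assert dr == pytest.approx(0.7, abs=0.11)


def test_depth_coefficients_configurable(biometrics):
    cfg = ToolConfig(depth_coeff_left=(0.0, 1.0), depth_coeff_right=(0.0, 1.0))
    assert kidney_depth(biometrics, cfg) == (1.0, 1.0)


def test_attenuation_factors_bounded():
    dc = DepthCorrection(depth_left_cm=6.0, depth_right_cm=7.0, mu_per_cm=0.153)
    assert 0.0 < dc.attenuation_factor_right < dc.attenuation_factor_left < 1.0


# ---------------------------------------------------------------- dose


def test_net_injected_counts_rate_arithmetic(injection):
    assert net_injected_counts(injection) == pytest.approx(9900.0)


def test_net_injected_counts_zero_residual():
    rec = InjectionRecord(600_000.0, 60.0, 0.0, 6.0)
    assert net_injected_counts(rec) == pytest.approx(10_000.0)


def test_net_injected_counts_decay_correction_half_half_life():
    # full syringe counted half a half-life before injection: rate decays by 2^-0.5
    rec = InjectionRecord(
        full_syringe_counts=10_000.0 * 60.0,
        full_count_duration_s=60.0,
        empty_syringe_counts=0.0,
        empty_count_duration_s=6.0,
        full_count_time_offset_s=3.0029 * 3600.0,
    )
    got = net_injected_counts(rec, decay_correct=True)
    assert got == pytest.approx(10_000.0 * 2 ** -0.5, rel=1e-6)
    assert got == pytest.approx(7071.07, abs=0.05)


def test_net_injected_counts_residual_exceeds_full():
    rec = InjectionRecord(100.0, 60.0, 6000.0, 6.0)
    with pytest.raises(ValueError, match="residual"):
        net_injected_counts(rec)


# ---------------------------------------------------------------- window


def test_window_weights_match_brute_force_enumeration(standard_schedule_renogram):
    """Brute-force interval overlap per frame equals the vectorised weights,
    and the 120-180 s window selects exactly one 60 s frame with weight 1."""
    reno = standard_schedule_renogram
    for window in [(120.0, 180.0), (115.0, 185.0), (0.0, 60.0), (59.0, 61.0)]:
        weights = frame_window_weights(reno, window)
        for i in range(reno.n_frames):
            lo = reno.frame_start_s[i]
            hi = lo + reno.frame_duration_s[i]
            overlap = max(0.0, min(hi, window[1]) - max(lo, window[0]))
            assert weights[i] == pytest.approx(overlap / reno.frame_duration_s[i])
    w = frame_window_weights(reno, (120.0, 180.0))
    assert w[31] == 1.0
    assert np.count_nonzero(w) == 1


def test_window_outside_acquisition_raises(standard_schedule_renogram):
    with pytest.raises(ValueError):
        frame_window_weights(standard_schedule_renogram, (1200.0, 1400.0))


# ---------------------------------------------------------------- uptake


def _uptake_fixture():
    """5000 counts under each kidney in the window frame, flat background
    whose per-pixel prediction gives 1000 counts under the kidney ROI."""
    frames = np.zeros((1, 10, 10))
    kidney_l = np.zeros((10, 10), bool)
    kidney_l[2:4, 1:6] = True  # 10 px
    kidney_r = np.zeros((10, 10), bool)
    kidney_r[6:8, 1:6] = True
    bg_l = np.zeros((10, 10), bool)
    bg_l[0, 0:5] = True  # 5 px
    bg_r = np.zeros((10, 10), bool)
    bg_r[9, 0:5] = True
    frames[0][kidney_l] = 500.0  # 5000 total
    frames[0][kidney_r] = 500.0
    frames[0][bg_l] = 100.0  # 100/px -> predicts 1000 under 10-px kidney
    frames[0][bg_r] = 100.0
    reno = DynamicRenogram(
        frames=frames, frame_start_s=np.array([0.0]), frame_duration_s=np.array([60.0])
    )
    rois = RoiSet(masks={
        "left_kidney": kidney_l, "right_kidney": kidney_r,
        "left_background": bg_l, "right_background": bg_r,
    })
    depth = DepthCorrection(
        depth_left_cm=math.log(2.0) / 0.153, depth_right_cm=math.log(2.0) / 0.153,
        mu_per_cm=0.153,
    )  # attenuation factor exactly 0.5
    return reno, rois, depth


def test_uptake_chain_hand_arithmetic():
    reno, rois, depth = _uptake_fixture()
    # dose_rate x window = 100000 counts equivalent
    res = renal_uptake_fractions(reno, rois, depth, dose_rate=100000.0 / 60.0,
                                 variant="conventional", window_s=(0.0, 60.0))
    assert res.uptake_left == pytest.approx((5000 - 1000) / 0.5 / 100000)
    assert res.background_left == pytest.approx(1000.0)
    blank = renal_uptake_fractions(reno, rois, depth, dose_rate=100000.0 / 60.0,
                                   variant="blank_background", window_s=(0.0, 60.0))
    assert blank.uptake_left == pytest.approx(5000 / 0.5 / 100000)
    assert blank.uptake_right == pytest.approx(0.10)


def test_uptake_clamps_negative_net_counts_with_warning():
    reno, rois, depth = _uptake_fixture()
    reno.frames[0][rois["left_background"]] = 600.0  # predicts 6000 > 5000
    with pytest.warns(UserWarning, match="clamping"):
        res = renal_uptake_fractions(reno, rois, depth, dose_rate=100000.0 / 60.0,
                                     variant="conventional", window_s=(0.0, 60.0))
    assert res.uptake_left == 0.0


def test_conventional_variant_requires_backgrounds():
    reno, rois, depth = _uptake_fixture()
    bare = RoiSet(masks={k: rois[k] for k in ("left_kidney", "right_kidney")})
    with pytest.raises(ValueError, match="background"):
        renal_uptake_fractions(reno, bare, depth, dose_rate=100.0,
                               variant="conventional", window_s=(0.0, 60.0))


def test_uptake_monotone_in_kidney_counts():
    """Adding counts under a kidney ROI never decreases its uptake."""
    reno, rois, depth = _uptake_fixture()
    base = renal_uptake_fractions(reno, rois, depth, 100.0, "blank_background", (0.0, 60.0))
    reno.frames[0][rois["left_kidney"]] += 50.0
    more = renal_uptake_fractions(reno, rois, depth, 100.0, "blank_background", (0.0, 60.0))
    assert more.uptake_left > base.uptake_left
    assert more.uptake_right == base.uptake_right


# ---------------------------------------------------------------- regression


def test_gates_regression_hand_value():
    assert gates_gfr_from_uptake(0.10) == pytest.approx(91.302, abs=1e-3)


def test_gates_regression_clamps_at_zero():
    assert gates_gfr_from_uptake(0.0) == 0.0


def test_gates_regression_rejects_out_of_range():
    with pytest.raises(ValueError):
        gates_gfr_from_uptake(1.5)


def test_proportional_split():
    """A total of 80 mL/min with corrected counts 3:1 splits (60, 20)."""
    total = gates_gfr_from_uptake(0.10)
    left = total * 0.75
    right = total - left
    assert left / right == pytest.approx(3.0)


# ---------------------------------------------------------------- pipeline


def test_pipeline_matches_hand_composed_stages(small_noisy_cohort, default_config):
    """The pipeline must equal the chain of its four stages run by hand."""
    s = small_noisy_cohort.subjects[0]
    cfg = default_config
    res = gates_pipeline(s.renogram, s.true_rois, s.biometrics, s.injection,
                         variant="conventional", config=cfg)

    dl, dr = kidney_depth(s.biometrics, cfg)
    depth = DepthCorrection(dl, dr, cfg.mu_per_cm)
    dose = net_injected_counts(s.injection)
    up = renal_uptake_fractions(s.renogram, s.true_rois, depth, dose,
                                "conventional", cfg.window_s)
    total = gates_gfr_from_uptake(up.uptake_left + up.uptake_right,
                                  cfg.gates_slope, cfg.gates_intercept)
    gl = total * up.uptake_left / (up.uptake_left + up.uptake_right)
    bsa = body_surface_area(s.biometrics, cfg.bsa_formula)
    assert res.gfr_left == pytest.approx(normalize_to_bsa(gl, bsa), rel=1e-12)
    assert res.gfr_total == pytest.approx(normalize_to_bsa(total, bsa), rel=1e-12)


def test_pipeline_deterministic(small_noisy_cohort):
    s = small_noisy_cohort.subjects[1]
    a = gates_pipeline(s.renogram, s.true_rois, s.biometrics, s.injection)
    b = gates_pipeline(s.renogram, s.true_rois, s.biometrics, s.injection)
    assert (a.gfr_left, a.gfr_right) == (b.gfr_left, b.gfr_right)


def test_variant_switch_differs_exactly_by_background_term(small_noisy_cohort, default_config):
    s = small_noisy_cohort.subjects[2]
    cfg = default_config
    dl, dr = kidney_depth(s.biometrics, cfg)
    depth = DepthCorrection(dl, dr, cfg.mu_per_cm)
    dose = net_injected_counts(s.injection)
    conv = renal_uptake_fractions(s.renogram, s.true_rois, depth, dose,
                                  "conventional", cfg.window_s)
    blank = renal_uptake_fractions(s.renogram, s.true_rois, depth, dose,
                                   "blank_background", cfg.window_s)
    dose_eq = dose * (cfg.window_s[1] - cfg.window_s[0])
    predicted_delta = conv.background_left / depth.attenuation_factor_left / dose_eq
    assert blank.uptake_left - conv.uptake_left == pytest.approx(predicted_delta, rel=1e-9)


def test_blank_background_dominates_conventional(small_noisy_cohort):
    """gGFR' >= gGFR: omitting background subtraction only adds counts."""
    for s in small_noisy_cohort.subjects:
        for rois in [s.true_rois] + s.rater_rois:
            conv = gates_pipeline(s.renogram, rois, s.biometrics, s.injection,
                                  variant="conventional")
            blank = gates_pipeline(s.renogram, rois, s.biometrics, s.injection,
                                   variant="blank_background")
            assert blank.gfr_total >= conv.gfr_total - 1e-9


def test_per_kidney_gfrs_sum_to_total(small_noisy_cohort):
    s = small_noisy_cohort.subjects[3]
    res = gates_pipeline(s.renogram, s.true_rois, s.biometrics, s.injection)
    assert res.gfr_left + res.gfr_right == pytest.approx(res.gfr_total, abs=1e-12)
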