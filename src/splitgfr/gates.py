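"""Gates-method split GFR from a dynamic renogram.

The camera-based (Gates) estimate maps the percentage of the injected
Tc-99m-DTPA dose accumulated by the kidneys 2–3 min post-injection to a
GFR through a published linear regression.  The chain is:

1. time-activity curves from the kidney (and optionally background) ROIs;
2. net injected dose rate from pre/post syringe counting;
3. per-kidney counts in the uptake window, background-subtracted
   (conventional variant, gGFR) or not (blank-background variant, gGFR');
4. depth/attenuation correction ``e^(−μ·depth)`` with depths from the
   Tønnesen weight/height estimate;
5. uptake fractions → total GFR via the Gates regression, split between
   kidneys in proportion to corrected counts, optionally BSA-normalised.

All literature constants live in :class:`~splitgfr.config.ToolConfig`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .config import ToolConfig
from .core import (
    DynamicRenogram,
    GatesResult,
    InjectionRecord,
    PatientBiometrics,
    RoiSet,
    TC99M_HALF_LIFE_H,
    validate_study,
)
from .plasma import body_surface_area, normalize_to_bsa

__all__ = [
    "TimeActivityCurve",
    "DepthCorrection",
    "UptakeResult",
    "extract_tac",
    "kidney_depth",
    "net_injected_counts",
    "frame_window_weights",
    "renal_uptake_fractions",
    "gates_gfr_from_uptake",
    "gates_pipeline",
]


@dataclass
class TimeActivityCurve:
    """Summed ROI counts per frame with frame mid-times and count rates."""

    times_s: np.ndarray  # frame mid-times
    counts: np.ndarray  # summed ROI counts per frame
    count_rates: np.ndarray  # counts / frame duration


@dataclass(frozen=True)
class DepthCorrection:
    """Kidney depths and the resulting attenuation factors e^(−μ·depth)."""

    depth_left_cm: float
    depth_right_cm: float
    mu_per_cm: float

    @property
    def attenuation_factor_left(self) -> float:
        return math.exp(-self.mu_per_cm * self.depth_left_cm)

    @property
    def attenuation_factor_right(self) -> float:
        return math.exp(-self.mu_per_cm * self.depth_right_cm)


@dataclass
class UptakeResult:
    """Renal uptake fractions plus the intermediate window quantities."""

    uptake_left: float
    uptake_right: float
    window_counts_left: float
    window_counts_right: float
    background_left: float  # background counts predicted under each kidney ROI
    background_right: float
    variant: str


def extract_tac(renogram: DynamicRenogram, mask: np.ndarray) -> TimeActivityCurve:
    """Per-frame summed counts under a binary mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != renogram.image_shape:
        raise ValueError("mask shape does not match frames")
    if not mask.any():
        raise ValueError("empty mask")
    counts = renogram.frames[:, mask].sum(axis=1).astype(float)
    return TimeActivityCurve(
        times_s=renogram.frame_mid_s,
        counts=counts,
        count_rates=counts / renogram.frame_duration_s,
    )


def kidney_depth(
    biometrics: PatientBiometrics, config: Optional[ToolConfig] = None
) -> Tuple[float, float]:
    """Tønnesen kidney-depth estimate (cm) from weight/height.

    ``depth = a·(W/H) + b`` per side, with the coefficients taken from the
    configuration (defaults: left a=13.2, right a=13.3, b=0.7).
    """
    config = config or ToolConfig()
    bad = biometrics.violations()
    if bad:
        raise ValueError("; ".join(bad))
    ratio = biometrics.weight_kg / biometrics.height_cm
    al, bl = config.depth_coeff_left
    ar, br = config.depth_coeff_right
    return al * ratio + bl, ar * ratio + br


def net_injected_counts(
    injection: InjectionRecord,
    decay_correct: bool = False,
    half_life_h: float = TC99M_HALF_LIFE_H,
) -> float:
    """Net injected dose rate (counts/s): full-syringe minus residual rate.

    With ``decay_correct`` the full-syringe rate (counted before injection)
    is decayed forward to injection time and the empty-syringe rate
    (counted after) is corrected back to it.
    """
    full_rate = injection.full_syringe_counts / injection.full_count_duration_s
    empty_rate = injection.empty_syringe_counts / injection.empty_count_duration_s
    if decay_correct:
        full_rate *= 2.0 ** (-injection.full_count_time_offset_s / 3600.0 / half_life_h)
        empty_rate *= 2.0 ** (injection.empty_count_time_offset_s / 3600.0 / half_life_h)
    net = full_rate - empty_rate
    if net <= 0:
        raise ValueError("residual exceeds full syringe (non-positive net rate)")
    return net


def frame_window_weights(
    renogram: DynamicRenogram, window_s: Tuple[float, float]
) -> np.ndarray:
    """Fractional overlap of each frame with the window ``[start, end)``.

    Weight = overlapping seconds / frame duration, so weighting per-frame
    counts by these values approximates the counts acquired inside the
    window (frames fully inside get weight 1, partial frames the overlap
    fraction)."""
    w0, w1 = window_s
    if not w0 < w1:
        raise ValueError("window start must precede window end")
    if w0 < renogram.frame_start_s[0] or w1 > renogram.frame_end_s[-1]:
        raise ValueError("window outside the acquisition span")
    overlap = np.minimum(renogram.frame_end_s, w1) - np.maximum(renogram.frame_start_s, w0)
    return np.clip(overlap, 0.0, None) / renogram.frame_duration_s


def _window_counts(renogram: DynamicRenogram, mask: np.ndarray, window_s) -> float:
    tac = extract_tac(renogram, mask)
    return float(np.sum(tac.counts * frame_window_weights(renogram, window_s)))


def renal_uptake_fractions(
    renogram: DynamicRenogram,
    rois: RoiSet,
    depth: DepthCorrection,
    dose_rate: float,
    variant: str = "blank_background",
    window_s: Tuple[float, float] = (120.0, 180.0),
) -> UptakeResult:
    """Fraction of the injected dose in each kidney over the uptake window.

    For each kidney the window counts are background-subtracted
    (conventional variant only: mean background counts per pixel times the
    kidney pixel count, from that side's background ROI), divided by the
    attenuation factor ``e^(−μ·depth)``, and referenced to the injected
    dose equivalent ``dose_rate × window length``.  Negative
    background-subtracted counts clamp to zero with a warning.
    """
    if variant not in ("conventional", "blank_background"):
        raise ValueError(f"unknown variant {variant!r}")
    if dose_rate <= 0:
        raise ValueError("dose rate must be positive")
    if variant == "conventional" and not rois.has_backgrounds:
        raise ValueError("conventional variant requires background masks")

    w0, w1 = window_s
    dose_equivalent = dose_rate * (w1 - w0)

    uptakes, counts_k, bg_pred = {}, {}, {}
    for side, atten in (
        ("left", depth.attenuation_factor_left),
        ("right", depth.attenuation_factor_right),
    ):
        kidney_mask = rois[f"{side}_kidney"]
        k_counts = _window_counts(renogram, kidney_mask, window_s)
        if variant == "conventional":
            bg_mask = rois[f"{side}_background"]
            bg_counts = _window_counts(renogram, bg_mask, window_s)
            per_pixel = bg_counts / int(bg_mask.sum())
            predicted = per_pixel * int(kidney_mask.sum())
        else:
            predicted = 0.0
        net = k_counts - predicted
        if net < 0:
            warnings.warn(
                f"{side} kidney: background prediction exceeds ROI counts; "
                "clamping net counts to zero",
                stacklevel=2,
            )
            net = 0.0
        uptakes[side] = net / atten / dose_equivalent
        counts_k[side] = k_counts
        bg_pred[side] = predicted

    return UptakeResult(
        uptake_left=uptakes["left"],
        uptake_right=uptakes["right"],
        window_counts_left=counts_k["left"],
        window_counts_right=counts_k["right"],
        background_left=bg_pred["left"],
        background_right=bg_pred["right"],
        variant=variant,
    )


def gates_gfr_from_uptake(
    uptake_total: float, slope: float = 9.8127, intercept: float = 6.82519
) -> float:
    """Total GFR (mL/min) from the total renal uptake fraction.

    Applies the Gates regression ``GFR = slope·(uptake %) − intercept``
    with the result clamped at zero."""
    if not 0.0 <= uptake_total <= 1.0:
        raise ValueError("uptake fraction must lie in [0, 1]")
    return max(0.0, slope * (uptake_total * 100.0) - intercept)


def _geometric_mean_renogram(post: DynamicRenogram, ant: DynamicRenogram) -> DynamicRenogram:
    """√(anterior × posterior) frame stack (optional view mode)."""
    frames = np.sqrt(post.frames.astype(float) * ant.frames.astype(float))
    return DynamicRenogram(
        frames=frames,
        frame_start_s=post.frame_start_s,
        frame_duration_s=post.frame_duration_s,
        detector="posterior",
    )


def gates_pipeline(
    renogram: DynamicRenogram,
    rois: RoiSet,
    biometrics: PatientBiometrics,
    injection: InjectionRecord,
    variant: str = "blank_background",
    config: Optional[ToolConfig] = None,
    anterior: Optional[DynamicRenogram] = None,
) -> GatesResult:
    """Full Gates chain: depth → dose → uptake → regression → split → BSA.

    ``variant`` selects conventional background subtraction (gGFR) or the
    blank-background processing (gGFR').  Deterministic: identical inputs
    give identical results.
    """
    config = config or ToolConfig()
    problems = validate_study(renogram, rois, biometrics, injection)
    if problems:
        raise ValueError("invalid study: " + "; ".join(problems))
    if config.view == "geometric_mean":
        if anterior is None:
            raise ValueError("geometric_mean view requires an anterior renogram")
        renogram = _geometric_mean_renogram(renogram, anterior)

    dl, dr = kidney_depth(biometrics, config)
    depth = DepthCorrection(depth_left_cm=dl, depth_right_cm=dr, mu_per_cm=config.mu_per_cm)
    dose_rate = net_injected_counts(
        injection,
        decay_correct=config.decay_correct_syringe,
        half_life_h=config.half_life_h,
    )
    up = renal_uptake_fractions(
        renogram, rois, depth, dose_rate, variant=variant, window_s=config.window_s
    )
    total_uptake = up.uptake_left + up.uptake_right
    gfr_total = gates_gfr_from_uptake(
        total_uptake, slope=config.gates_slope, intercept=config.gates_intercept
    )
    if total_uptake > 0:
        gfr_left = gfr_total * up.uptake_left / total_uptake
        gfr_right = gfr_total - gfr_left
    else:
        gfr_left = gfr_right = 0.0

    normalized = bool(config.normalize_bsa)
    if normalized:
        bsa = body_surface_area(biometrics, config.bsa_formula)
        gfr_left = normalize_to_bsa(gfr_left, bsa)
        gfr_right = normalize_to_bsa(gfr_right, bsa)

    return GatesResult(
        gfr_left=gfr_left,
        gfr_right=gfr_right,
        uptake_left=up.uptake_left,
        uptake_right=up.uptake_right,
        variant=variant,
        normalized=normalized,
    )
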