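"""Shared domain types for split-GFR quantification.

Conventions used throughout the package:

* Image stacks are indexed ``(frame, row, col)``, 0-based.
* Time origin ``t = 0`` is the moment of tracer injection; ``frame_start_s``
  is the leading edge of each frame.
* The posterior detector view is the default for analysis; anterior frames
  are carried but unused unless a geometric-mean mode is requested.

Types are plain dataclasses that *store* whatever they are given; structural
problems are reported (not raised) through :func:`validate_study`, so that a
malformed study can be inspected rather than rejected at construction time.
Computational operations elsewhere raise ``ValueError`` when their
preconditions are broken.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

#: ROI roles recognised by the Gates processing chain.
KIDNEY_ROLES = ("left_kidney", "right_kidney")
BACKGROUND_ROLES = ("left_background", "right_background")
ROI_ROLES = KIDNEY_ROLES + BACKGROUND_ROLES

DETECTOR_VIEWS = ("posterior", "anterior")

#: Physical half-life of Tc-99m in hours.
TC99M_HALF_LIFE_H = 6.0058


@dataclass
class DynamicRenogram:
    """A time-stamped planar frame stack from a dynamic renal acquisition.

    Parameters
    ----------
    frames
        3-D count array ``(frame, row, col)``.  Counts are non-negative;
        acquired data are integers, while noise-free phantom expectations
        may carry real-valued counts.
    frame_start_s
        Seconds post-injection at the leading edge of each frame.
    frame_duration_s
        Duration of each frame in seconds.
    detector
        ``"posterior"`` (default analysis view) or ``"anterior"``.
    """

    frames: np.ndarray
    frame_start_s: np.ndarray
    frame_duration_s: np.ndarray
    detector: str = "posterior"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.frame_start_s = np.asarray(self.frame_start_s, dtype=float)
        self.frame_duration_s = np.asarray(self.frame_duration_s, dtype=float)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def image_shape(self) -> tuple:
        return tuple(self.frames.shape[1:])

    @property
    def frame_mid_s(self) -> np.ndarray:
        """Frame mid-times in seconds post-injection."""
        return self.frame_start_s + self.frame_duration_s / 2.0

    @property
    def frame_end_s(self) -> np.ndarray:
        return self.frame_start_s + self.frame_duration_s

    def violations(self) -> List[str]:
        v: List[str] = []
        if self.frames.ndim != 3:
            v.append("frames must be a 3-D (frame, row, col) array")
            return v
        n = self.n_frames
        if len(self.frame_start_s) != n or len(self.frame_duration_s) != n:
            v.append("time arrays must match the frame axis length")
        if np.any(np.diff(self.frame_start_s) <= 0):
            v.append("frame_start_s must be strictly increasing")
        if np.any(self.frame_duration_s <= 0):
            v.append("frame_duration_s must be positive")
        if np.any(self.frames < 0):
            v.append("frame counts must be non-negative")
        if self.detector not in DETECTOR_VIEWS:
            v.append(f"detector must be one of {DETECTOR_VIEWS}")
        return v


@dataclass
class RoiSet:
    """Named binary masks on the frame grid.

    ``masks`` maps a role (``left_kidney``, ``right_kidney`` and optionally
    ``left_background``, ``right_background``) to a boolean image with the
    same row/col shape as the frames.
    """

    masks: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.masks = {k: np.asarray(m, dtype=bool) for k, m in self.masks.items()}

    def __getitem__(self, role: str) -> np.ndarray:
        return self.masks[role]

    def __contains__(self, role: str) -> bool:
        return role in self.masks

    @property
    def has_backgrounds(self) -> bool:
        return all(r in self.masks for r in BACKGROUND_ROLES)

    def violations(self, image_shape: Optional[tuple] = None) -> List[str]:
        v: List[str] = []
        for role, m in self.masks.items():
            if role not in ROI_ROLES:
                v.append(f"unknown ROI role {role!r}")
            if image_shape is not None and m.shape != tuple(image_shape):
                v.append(f"mask {role!r} shape {m.shape} does not match frames")
        for role in KIDNEY_ROLES:
            if role not in self.masks:
                v.append(f"missing kidney mask {role!r}")
            elif not self.masks[role].any():
                v.append(f"kidney mask {role!r} is empty")
        if all(r in self.masks for r in KIDNEY_ROLES):
            lk, rk = self.masks["left_kidney"], self.masks["right_kidney"]
            if lk.shape == rk.shape and np.any(lk & rk):
                v.append("kidney masks overlap")
        for bg_role in BACKGROUND_ROLES:
            if bg_role not in self.masks:
                continue
            bg = self.masks[bg_role]
            for k_role in KIDNEY_ROLES:
                k = self.masks.get(k_role)
                if k is not None and k.shape == bg.shape and np.any(bg & k):
                    v.append(f"background mask {bg_role!r} overlaps {k_role!r}")
        return v


@dataclass(frozen=True)
class PatientBiometrics:
    """Height (cm) and weight (kg), as recorded before the acquisition."""

    height_cm: float
    weight_kg: float

    def violations(self) -> List[str]:
        v: List[str] = []
        if not (50.0 <= self.height_cm <= 250.0):
            v.append("height_cm must lie in [50, 250]")
        if not (2.0 <= self.weight_kg <= 300.0):
            v.append("weight_kg must lie in [2, 300]")
        return v


@dataclass(frozen=True)
class InjectionRecord:
    """Syringe counting record used to establish the net injected dose.

    The full syringe is counted before injection and the empty syringe
    after; offsets are recorded so the rates can be decay-corrected to the
    injection time when the two countings happen in separate sessions.
    """

    full_syringe_counts: float
    full_count_duration_s: float
    empty_syringe_counts: float
    empty_count_duration_s: float
    full_count_time_offset_s: float = 0.0  # seconds *before* injection
    empty_count_time_offset_s: float = 0.0  # seconds *after* injection

    def violations(self) -> List[str]:
        v: List[str] = []
        if self.full_syringe_counts < 0 or self.empty_syringe_counts < 0:
            v.append("syringe counts must be non-negative")
        if self.full_count_duration_s <= 0 or self.empty_count_duration_s <= 0:
            v.append("count durations must be positive")
        else:
            full_rate = self.full_syringe_counts / self.full_count_duration_s
            empty_rate = self.empty_syringe_counts / self.empty_count_duration_s
            if full_rate - empty_rate <= 0:
                v.append("net injected count rate must be positive")
        return v


@dataclass(frozen=True)
class PlasmaStudy:
    """Injected dose and two timed plasma samples for slope-intercept GFR.

    ``D`` (injected dose, counts) and ``P1``/``P2`` (counts per mL) must
    share one counting calibration; ``T1``/``T2`` are minutes post-injection.
    """

    D: float
    P1: float
    P2: float
    T1: float
    T2: float

    def violations(self) -> List[str]:
        v: List[str] = []
        if self.D <= 0:
            v.append("injected dose D must be positive")
        if not (self.P1 > self.P2 > 0):
            v.append("plasma counts must satisfy P1 > P2 > 0")
        if not (self.T2 > self.T1 > 0):
            v.append("sample times must satisfy T2 > T1 > 0")
        return v


@dataclass
class GatesResult:
    """Per-kidney Gates GFR and uptake fractions.

    ``variant`` records whether conventional background subtraction
    (``"conventional"``, gGFR) or the blank-background variant
    (``"blank_background"``, gGFR') produced the numbers; ``normalized``
    says whether the GFRs are per 1.73 m² BSA or raw.
    """

    gfr_left: float
    gfr_right: float
    uptake_left: float
    uptake_right: float
    variant: str
    normalized: bool

    @property
    def gfr_total(self) -> float:
        return self.gfr_left + self.gfr_right

    def violations(self) -> List[str]:
        v: List[str] = []
        if not (0.0 <= self.uptake_left <= 1.0 and 0.0 <= self.uptake_right <= 1.0):
            v.append("uptake fractions must lie in [0, 1]")
        if self.variant not in ("conventional", "blank_background"):
            v.append("variant must be 'conventional' or 'blank_background'")
        return v


@dataclass
class SplitGfrResult:
    """Precise per-kidney GFR obtained by apportioning the plasma tGFR."""

    pgfr_left: float
    pgfr_right: float
    tgfr: float
    split_fraction_left: float

    def violations(self) -> List[str]:
        v: List[str] = []
        tol = 4.0 * np.spacing(max(abs(self.tgfr), 1.0))
        if abs(self.pgfr_left + self.pgfr_right - self.tgfr) > tol:
            v.append("pgfr_left + pgfr_right must equal tgfr")
        if not (0.0 <= self.split_fraction_left <= 1.0):
            v.append("split_fraction_left must lie in [0, 1]")
        return v


@dataclass
class RaterTable:
    """Subjects × raters matrix of one scalar measure (input to Kendall's W)."""

    values: np.ndarray
    subject_ids: Optional[Sequence] = None
    rater_ids: Optional[Sequence] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if self.subject_ids is None:
            self.subject_ids = list(range(n))
        if self.rater_ids is None:
            self.rater_ids = list(range(m))

    @property
    def n_subjects(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_raters(self) -> int:
        return int(self.values.shape[1])

    def violations(self) -> List[str]:
        v: List[str] = []
        if self.values.ndim != 2:
            v.append("values must be a 2-D subjects × raters matrix")
            return v
        if self.n_subjects < 2:
            v.append("need at least 2 subjects")
        if self.n_raters < 2:
            v.append("need at least 2 raters")
        if len(self.subject_ids) != self.n_subjects:
            v.append("subject_ids length mismatch")
        if len(self.rater_ids) != self.n_raters:
            v.append("rater_ids length mismatch")
        if np.any(~np.isfinite(self.values)):
            v.append("table must have no missing cells")
        return v


def validate_study(
    renogram: DynamicRenogram,
    rois: RoiSet,
    biometrics: PatientBiometrics,
    injection: InjectionRecord,
) -> List[str]:
    """Collect every invariant violation of a study bundle.

    Returns a list of human-readable violation strings (empty list means the
    study is valid).  Pure: never mutates its inputs, and two calls on the
    same inputs yield identical reports.
    """
    report: List[str] = []
    report += [f"renogram: {m}" for m in renogram.violations()]
    shape = renogram.image_shape if renogram.frames.ndim == 3 else None
    report += [f"rois: {m}" for m in rois.violations(shape)]
    report += [f"biometrics: {m}" for m in biometrics.violations()]
    report += [f"injection: {m}" for m in injection.violations()]
    return report


def to_dict(obj) -> dict:
    """Serialise a scalar core dataclass to a plain dict (JSON-ready)."""
    return dataclasses.asdict(obj)
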