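"""Total GFR from two-sample (slope-intercept) plasma clearance.

The dual-plasma method assumes the late plasma concentration of
Tc-99m-DTPA decays mono-exponentially, ``P(t) = P0·e^(−kt)``.  From the
injected dose ``D`` and two timed samples ``(P1, T1)``, ``(P2, T2)`` the
clearance is

    GFR = D·ln(P1/P2)/(T2−T1) · exp[(T1·ln P2 − T2·ln P1)/(T2−T1)]

which is algebraically ``D·k/P0`` for the mono-exponential through the two
samples.  Times are minutes post-injection; dose and plasma counts must
share one counting calibration, so GFR comes out in mL/min.

No single-compartment overestimation correction is applied by default: the
slope-intercept output itself is the method's tGFR.  A Brøchner-Mortensen
hook exists for users who want the corrected value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import PatientBiometrics, PlasmaStudy, TC99M_HALF_LIFE_H

__all__ = [
    "PlasmaGfr",
    "dual_plasma_gfr",
    "body_surface_area",
    "normalize_to_bsa",
    "decay_correct_counts",
    "plasma_gfr",
    "process_plasma_table",
]

BSA_FORMULAS = {
    # name -> (coefficient, weight exponent, height exponent); W kg, H cm
    "dubois": (0.007184, 0.425, 0.725),
    "haycock": (0.024265, 0.5378, 0.3964),
}


@dataclass(frozen=True)
class PlasmaGfr:
    """Raw and BSA-normalised total GFR with the BSA used."""

    gfr_raw: float  # mL/min
    gfr_bsa: float  # mL·min⁻¹·(1.73 m²)⁻¹
    bsa_m2: float


def _slope_intercept_gfr(D: float, P1: float, P2: float, T1: float, T2: float) -> float:
    """The clearance formula with no precondition guards (internal).

    Evaluated as ``D·(L/Δt)·e^(−T1·L/Δt)/P1`` with ``L = ln(P1/P2)``, which
    is algebraically identical to the textbook slope-intercept expression
    ``D·ln(P1/P2)/Δt · exp[(T1·lnP2 − T2·lnP1)/Δt]`` but avoids the
    catastrophic cancellation of ``T1·lnP2 − T2·lnP1``.
    """
    dt = T2 - T1
    L = math.log(P1 / P2)
    return D * (L / dt) * math.exp(-T1 * L / dt) / P1


def dual_plasma_gfr(study: PlasmaStudy, *, brochner_mortensen: bool = False) -> float:
    """Total GFR (mL/min) from a two-sample plasma study.

    Parameters
    ----------
    study
        Injected dose and the two timed plasma samples.
    brochner_mortensen
        Apply the Brøchner-Mortensen single-compartment correction
        ``0.990778·G − 0.001218·G²`` to the slope-intercept value.
        Off by default: the uncorrected value is the method's tGFR.

    Raises
    ------
    ValueError
        If counts/times are non-positive, the samples are out of order, or
        the plasma activity is non-decreasing (``P2 ≥ P1``), which would
        imply a non-positive clearance.
    """
    if study.D <= 0:
        raise ValueError("injected dose D must be positive")
    if study.P2 <= 0 or study.P1 <= 0:
        raise ValueError("plasma counts must be positive")
    if not (study.T2 > study.T1 > 0):
        raise ValueError("sample times must satisfy T2 > T1 > 0")
    if study.P2 >= study.P1:
        raise ValueError("non-decreasing plasma activity (P2 >= P1)")
    gfr = _slope_intercept_gfr(study.D, study.P1, study.P2, study.T1, study.T2)
    if brochner_mortensen:
        gfr = 0.990778 * gfr - 0.001218 * gfr * gfr
    return gfr


def body_surface_area(biometrics: PatientBiometrics, formula: str = "dubois") -> float:
    """Body surface area in m² from height and weight.

    ``formula`` selects DuBois (default, ``0.007184·W^0.425·H^0.725``) or
    Haycock (``0.024265·W^0.5378·H^0.3964``).
    """
    if biometrics.height_cm <= 0 or biometrics.weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    try:
        c, we, he = BSA_FORMULAS[formula]
    except KeyError:
        raise ValueError(f"unknown BSA formula {formula!r}") from None
    return c * biometrics.weight_kg**we * biometrics.height_cm**he


def normalize_to_bsa(gfr_raw: float, bsa_m2: float) -> float:
    """Scale a raw GFR (mL/min) to the 1.73 m² reference surface."""
    if bsa_m2 <= 0:
        raise ValueError("BSA must be positive")
    return gfr_raw * 1.73 / bsa_m2


def decay_correct_counts(
    counts: float, elapsed_h: float, half_life_h: float = TC99M_HALF_LIFE_H
) -> float:
    """Correct a count (rate) measured ``elapsed_h`` hours after a reference
    time back to that reference: multiply by ``2^(elapsed/half_life)``.
    Negative ``elapsed_h`` corrects a measurement taken *before* the
    reference forward to it."""
    return counts * 2.0 ** (elapsed_h / half_life_h)


def plasma_gfr(
    study: PlasmaStudy,
    biometrics: PatientBiometrics,
    formula: str = "dubois",
    *,
    brochner_mortensen: bool = False,
) -> PlasmaGfr:
    """Convenience wrapper: clearance plus BSA normalisation in one call."""
    raw = dual_plasma_gfr(study, brochner_mortensen=brochner_mortensen)
    bsa = body_surface_area(biometrics, formula)
    return PlasmaGfr(gfr_raw=raw, gfr_bsa=normalize_to_bsa(raw, bsa), bsa_m2=bsa)


def process_plasma_table(df, formula: str = "dubois"):
    """Process a table of plasma studies (one row per study).

    Expects columns ``D, P1, P2, T1_min, T2_min, height_cm, weight_kg``;
    returns a copy with ``gfr_raw``, ``bsa_m2`` and ``gfr_bsa`` appended.
    """
    required = {"D", "P1", "P2", "T1_min", "T2_min", "height_cm", "weight_kg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plasma table missing columns: {sorted(missing)}")
    out = df.copy()
    raws, bsas, norms = [], [], []
    for row in df.itertuples(index=False):
        study = PlasmaStudy(D=row.D, P1=row.P1, P2=row.P2, T1=row.T1_min, T2=row.T2_min)
        bio = PatientBiometrics(height_cm=row.height_cm, weight_kg=row.weight_kg)
        res = plasma_gfr(study, bio, formula)
        raws.append(res.gfr_raw)
        bsas.append(res.bsa_m2)
        norms.append(res.gfr_bsa)
    out["gfr_raw"] = raws
    out["bsa_m2"] = bsas
    out["gfr_bsa"] = norms
    return out
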