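"""Tool configuration: every literature constant in one auditable block.

The Gates regression constants, kidney-depth coefficients and attenuation
coefficient are published values the processing chain depends on; they are
deliberately not hard-coded inside operations so that a reviewer can swap
alternatives.  Sources:

* Gates GW, AJR 1982 — GFR (mL/min) = 9.8127 × (% renal uptake) − 6.82519.
* Tønnesen KH et al., 1974 — kidney depth (cm) from weight/height:
  left 13.2·(W/H) + 0.7, right 13.3·(W/H) + 0.7 (W in kg, H in cm).
* μ = 0.153 cm⁻¹: linear attenuation coefficient of 140 keV photons in
  soft tissue, used for depth correction e^(−μ·depth).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Tuple

import yaml


@dataclass
class ToolConfig:
    # Gates uptake → GFR regression (uptake expressed in percent)
    gates_slope: float = 9.8127
    gates_intercept: float = 6.82519
    # Tønnesen depth estimate: depth = a·(weight/height) + b, cm
    depth_coeff_left: Tuple[float, float] = (13.2, 0.7)
    depth_coeff_right: Tuple[float, float] = (13.3, 0.7)
    mu_per_cm: float = 0.153
    # Renal uptake integration window, seconds post-injection [start, end)
    window_s: Tuple[float, float] = (120.0, 180.0)
    # Body-surface-area normalisation
    bsa_formula: str = "dubois"  # or "haycock"
    normalize_bsa: bool = True
    # Formula-1 input: apportion the BSA-normalised tGFR (matching the
    # standard reporting unit) or the raw mL/min value
    pgfr_uses_bsa_tgfr: bool = True
    # Detector handling
    view: str = "posterior"  # or "geometric_mean"
    # Physical decay handling (Tc-99m half-life, hours)
    half_life_h: float = 6.0058
    decay_correct_syringe: bool = False
    decay_correct_plasma: bool = False
    # Slope-intercept overestimation correction hook (off: the plasma method
    # is used exactly as printed)
    brochner_mortensen: bool = False
    # Concordance analysis
    tie_correction: bool = True
    stacking: str = "stacked"  # left+right kidneys as separate subjects
    # Top-level seed for any randomised step
    seed: int = 0

    def violations(self) -> list:
        v = []
        if self.gates_slope <= 0:
            v.append("gates_slope must be positive")
        if self.mu_per_cm <= 0:
            v.append("mu_per_cm must be positive")
        if not self.window_s[0] < self.window_s[1]:
            v.append("window start must precede window end")
        if self.bsa_formula not in ("dubois", "haycock"):
            v.append("bsa_formula must be 'dubois' or 'haycock'")
        if self.view not in ("posterior", "geometric_mean"):
            v.append("view must be 'posterior' or 'geometric_mean'")
        if self.stacking not in ("stacked", "per_kidney"):
            v.append("stacking must be 'stacked' or 'per_kidney'")
        return v

    # -- round-trippable serialisation -----------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["depth_coeff_left"] = list(d["depth_coeff_left"])
        d["depth_coeff_right"] = list(d["depth_coeff_right"])
        d["window_s"] = list(d["window_s"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ToolConfig":
        kwargs = dict(d)
        for key in ("depth_coeff_left", "depth_coeff_right", "window_s"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ToolConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
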