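"""Signalling fields: morphogen profile, Fj gradient, Ds expression rule.

The morphogen (an abstract superposition of Dpp and Wg) is radially
symmetric, decays exponentially with radius with a decay length that
scales with disc size, and its amplitude grows exponentially in time:

    M(r, t) = C0 * exp(t / t0 - A * r / R)

Ds expression is a repressive Hill function of the morphogen, producing a
sigmoidal radial profile whose steep "transition region" (the Ds front)
moves outward as the amplitude grows.  Fj falls off linearly with radius;
its intercept rises as the disc grows but its slope is constant, so the
Fj difference between adjacent cells is roughly constant in time.

Default calibration: A = 2.5, M_half = 0.5 and C0 = 0.5 * exp(A / 5),
which puts the t = 0 front of a 40 um disc at exactly 8 um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

A_WILDTYPE = 2.5
C0_WILDTYPE = 0.5 * math.exp(A_WILDTYPE / 5.0)  # front(t=0, R=40) == 8 um

__all__ = [
    "MorphogenField",
    "FjProfile",
    "DsExpressionRule",
    "morphogen_at",
    "fj_level_at",
    "ds_rate_at",
    "front_radius",
    "A_WILDTYPE",
]


@dataclass
class MorphogenField:
    """Morphogen profile parameters.

    C0: initial central concentration (a.u.); A: dimensionless ratio of
    disc radius to decay length; t0: e-folding time of the amplitude,
    minutes (experimental Dpp value ~1200).
    """

    C0: float = C0_WILDTYPE
    A: float = A_WILDTYPE
    t0: float = 1200.0
    mode: str = "wildtype"          # wildtype | uniform | none
    uniform_level: float = math.e   # used by uniform mode (= C0 * e)

    def __post_init__(self):
        if self.C0 <= 0 or self.A <= 0 or self.t0 <= 0:
            raise ValueError("C0, A and t0 must be positive")
        if self.mode not in ("wildtype", "uniform", "none"):
            raise ValueError(f"unknown morphogen mode {self.mode!r}")


@dataclass
class FjProfile:
    """Linear Fj concentration profile: fj_min + slope * (R - r)."""

    slope: float = 2.5e-2   # a.u. per um
    fj_min: float = 0.1     # a.u., value at the disc edge
    mode: str = "graded"    # graded | uniform | absent
    uniform_level: float = 10.0

    def __post_init__(self):
        if self.mode not in ("graded", "uniform", "absent"):
            raise ValueError(f"unknown Fj mode {self.mode!r}")


@dataclass
class DsExpressionRule:
    """Ds expression rate as a repressive Hill function of morphogen.

    rate_high is the low-morphogen (peripheral) plateau, ~20 molecules per
    minute; rate_low the high-morphogen plateau.  M_half is the morphogen
    concentration at half-maximal repression (the front); hill_n sets the
    width of the transition region.  In stationary-front mode the
    inflection is pinned at a fixed relative radius instead of tracking
    the morphogen.  ``uniform_rate`` (overexpression genotypes) bypasses
    the Hill rule entirely.
    """

    rate_high: float = 20.0   # molecules / min
    rate_low: float = 0.5     # molecules / min
    M_half: float = 0.5       # a.u.
    hill_n: float = 8.0
    front_mode: str = "moving"          # moving | stationary
    stationary_rel_radius: float = 0.85  # fraction of R
    uniform_rate: float | None = None

    def __post_init__(self):
        if not (self.rate_high > self.rate_low >= 0):
            raise ValueError("need rate_high > rate_low >= 0")
        if self.hill_n < 1:
            raise ValueError("hill_n must be >= 1")
        if self.front_mode not in ("moving", "stationary"):
            raise ValueError(f"unknown front mode {self.front_mode!r}")


def morphogen_at(r, t, R, field: MorphogenField):
    """Morphogen concentration at radius r (um) and time t (minutes)."""
    if R <= 0:
        raise ValueError("disc radius must be positive")
    r = np.asarray(r, dtype=float)
    if field.mode == "none":
        out = np.zeros_like(r)
    elif field.mode == "uniform":
        out = np.full_like(r, field.uniform_level)
    else:
        out = field.C0 * np.exp(t / field.t0 - field.A * r / R)
    return float(out) if out.ndim == 0 else out


def fj_level_at(r, t, R, profile: FjProfile):
    """Fj concentration at radius r.  The graded profile is linear in r
    with a time-constant slope; its central value rises as R grows."""
    r = np.asarray(r, dtype=float)
    if profile.mode == "absent":
        out = np.zeros_like(r)
    elif profile.mode == "uniform":
        out = np.full_like(r, profile.uniform_level)
    else:
        if R <= 0:
            raise ValueError("disc radius must be positive")
        out = profile.fj_min + profile.slope * np.maximum(0.0, R - r)
    return float(out) if out.ndim == 0 else out


def ds_rate_at(cell_r, t, R, field: MorphogenField, rule: DsExpressionRule):
    """Ds expression rate (molecules/min) for a cell at radius cell_r."""
    cell_r = np.asarray(cell_r, dtype=float)
    if rule.uniform_rate is not None:
        out = np.full_like(cell_r, rule.uniform_rate)
        return float(out) if out.ndim == 0 else out
    n = rule.hill_n
    if rule.front_mode == "stationary":
        # Same Hill form and front steepness as the moving variant, but the
        # inflection is pinned at a fixed relative radius instead of
        # tracking a critical morphogen concentration: the Hill acts on the
        # (time-frozen) morphogen shape relative to its value at the pinned
        # front, exp(A (rel - r/R)), so the transition width stays R/(n A).
        if R <= 0:
            raise ValueError("disc radius must be positive")
        z = n * field.A * (rule.stationary_rel_radius - cell_r / R)
        frac = 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))
    else:
        M = np.asarray(morphogen_at(cell_r, t, R, field), dtype=float)
        frac = rule.M_half ** n / (rule.M_half ** n + M ** n)
    out = rule.rate_low + (rule.rate_high - rule.rate_low) * frac
    return float(out) if out.ndim == 0 else out


def front_radius(t, R, field: MorphogenField, rule: DsExpressionRule):
    """Radius of the Ds transition region (um), or None if undefined.

    Moving mode: closed-form inversion of the morphogen profile at the
    half-repression concentration, r* = (R/A) * (t/t0 + ln(C0 / M_half)),
    clipped to [0, R].  Stationary mode: the pinned relative radius.
    """
    if rule.front_mode == "stationary":
        if R <= 0:
            raise ValueError("disc radius must be positive")
        return float(rule.stationary_rel_radius * R)
    if field.mode != "wildtype":
        return None  # uniform or absent morphogen: no front
    if R <= 0:
        raise ValueError("disc radius must be positive")
    r_star = (R / field.A) * (t / field.t0 + math.log(field.C0 / rule.M_half))
    return float(min(max(r_star, 0.0), R))
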