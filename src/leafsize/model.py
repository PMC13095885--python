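"""Core equations of the expolinear-logistic individual leaf size model.

Blade length or width y(x) at leaf position x (counted 1-based from the
bottom of the main culm; the flag leaf is position TLN) is

    y(x) = L1 + (cm/rm) * ln(1 + exp(rm*(x - tb - 1)))          for x < xs
    y(x) = Ymax*Yslevel / (Ymax + (Yslevel-Ymax)*exp(dr*(x-xs)))  for x >= xs

with Ymax the expolinear value at xs and Yslevel = Ymax + dsl.  The two
branches agree at x = xs by construction.  Leaf area is length * width *
shape factor (0.71, or 0.635 for the flag leaf).  The legacy one-equation
bell-shaped area profile is provided as a comparison baseline.

The expolinear term is evaluated through a softplus (``logaddexp``) so that
large exponent arguments cannot overflow; the logistic term is evaluated in
log space for the same reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterDomainError, PositionDomainError, TlnRangeError
from .params import (
    BellParams,
    ProfileParams,
    SpeciesParameterSet,
    TlnLinearRule,
    TlnPlateauRule,
    TlnSegmentedRule,
    Trait,
    XsRule,
    warn_xs_out_of_range,
)

__all__ = [
    "expolinear_value",
    "y_max",
    "logistic_value",
    "leaf_dimension",
    "bell_leaf_area",
    "leaf_area",
    "xs_from_tln",
    "dr_from_tln",
    "build_params",
    "predict_profile",
    "LeafProfile",
]


def _softplus(z):
    # log(1 + e^z), exact for any finite z: logaddexp switches formulation
    # internally so exponents up to ~1e308 stay finite.
    return np.logaddexp(0.0, z)


def _expolinear_raw(x, L1, cm, rm, tb):
    return L1 + (cm / rm) * _softplus(rm * (np.asarray(x, dtype=float) - tb - 1.0))


def _logistic_raw(x, ymax, dsl, dr, xs):
    if dsl == 0.0:
        # Degenerate: upper asymptote coincides with the maximum, so the
        # decay phase is flat at Ymax.
        return np.broadcast_to(ymax, np.shape(np.asarray(x, dtype=float))).copy() \
            if np.ndim(x) else float(ymax)
    x = np.asarray(x, dtype=float)
    # Ymax*Ys / (Ymax + dsl*e^{dr(x-xs)}) computed in log space.
    log_num = np.log(ymax) + np.log(ymax + dsl)
    log_den = np.logaddexp(np.log(ymax), np.log(dsl) + dr * (x - xs))
    out = np.exp(log_num - log_den)
    return out if out.ndim else float(out)


def expolinear_value(x, p: ProfileParams):
    """Expolinear (pre-peak) branch at leaf position(s) ``x``, in mm.

    Strictly increasing in x; tends to L1 as x -> -inf and to the line
    ``L1 + cm*(x - tb - 1)`` for large x.
    """
    p.validate()
    out = _expolinear_raw(x, p.L1, p.cm, p.rm, p.tb)
    return out if np.ndim(out) else float(out)


def y_max(p: ProfileParams) -> float:
    """Maximum blade dimension, attained at x = xs (same code path as
    :func:`expolinear_value`)."""
    return float(expolinear_value(p.xs, p))


def logistic_value(x, p: ProfileParams):
    """Logistic decay (post-peak) branch at leaf position(s) ``x``, in mm.

    Equals Ymax at x = xs and decreases strictly for x > xs when dr > 0 and
    dsl > 0; with dsl = 0 or dr = 0 it degenerates to the constant Ymax.
    """
    p.validate()
    return _logistic_raw(x, y_max(p), p.dsl, p.dr, p.xs)


def leaf_dimension(x, p: ProfileParams):
    """Blade length or width at position(s) ``x >= 1``: expolinear for
    x < xs, logistic for x >= xs (continuous at xs)."""
    p.validate()
    x = np.asarray(x, dtype=float)
    if np.any(x < 1.0):
        raise PositionDomainError("leaf positions start at 1")
    ymax = y_max(p)
    out = np.where(
        x < p.xs,
        _expolinear_raw(x, p.L1, p.cm, p.rm, p.tb),
        _logistic_raw(x, ymax, p.dsl, p.dr, p.xs),
    )
    return out if out.ndim else float(out)


def bell_leaf_area(x, bp: BellParams):
    """Legacy bell-shaped baseline: area = Y0*exp(a*(x-x0)^2 + b*(x-x0)^3)."""
    bp.validate()
    d = np.asarray(x, dtype=float) - bp.x0
    out = bp.Y0 * np.exp(bp.a * d**2 + bp.b * d**3)
    return out if out.ndim else float(out)


def leaf_area(length, width, is_flag: bool, pset: SpeciesParameterSet):
    """Blade area (mm^2) = length * width * shape factor.

    The flag leaf (topmost) uses the flag shape factor (default 0.635),
    every other leaf the standard factor (default 0.71).
    """
    length = np.asarray(length, dtype=float)
    width = np.asarray(width, dtype=float)
    if np.any(length < 0) or np.any(width < 0):
        raise PositionDomainError("blade dimensions must be >= 0")
    out = length * width * pset.shape_factor(is_flag)
    return out if out.ndim else float(out)


def xs_from_tln(rule: XsRule, tln: int) -> float:
    """Position of the largest leaf for a given total leaf number."""
    if tln < 2:
        raise TlnRangeError(f"tln={tln} must be >= 2")
    if not isinstance(rule, (TlnLinearRule, TlnSegmentedRule)):
        raise TypeError(f"unsupported xs rule type: {type(rule).__name__}")
    xs = float(rule(tln))
    warn_xs_out_of_range(xs, tln)
    return xs


def dr_from_tln(rule: TlnPlateauRule, tln: int) -> float:
    """Logistic decay rate for a given total leaf number (declining line up
    to the breakpoint, constant plateau beyond)."""
    if tln < 2:
        raise TlnRangeError(f"tln={tln} must be >= 2")
    dr = float(rule(tln))
    if dr <= 0:
        raise ParameterDomainError(
            f"dr rule yields non-positive decay rate {dr:.4g} at tln={tln}"
        )
    return dr


def build_params(pset: SpeciesParameterSet, trait: Trait, tln: int) -> ProfileParams:
    """Assemble the seven profile parameters for one species/trait/TLN.

    Fixed parameters come straight from the set; xs and dr are derived from
    the TLN rules.  ``tln`` must fall inside the set's plausibility range
    (default 8-45, the observed extremes across the three species).
    """
    lo, hi = pset.tln_range
    if not lo <= tln <= hi:
        raise TlnRangeError(
            f"tln={tln} outside the plausible range [{lo}, {hi}] for "
            f"{pset.species.value}"
        )
    tp = pset.trait(trait)
    return ProfileParams(
        L1=tp.L1,
        cm=tp.cm,
        rm=tp.rm,
        tb=tp.tb,
        xs=xs_from_tln(tp.xs_rule, tln),
        dr=dr_from_tln(tp.dr_rule, tln),
        dsl=tp.dsl,
    ).validate()


@dataclass(frozen=True)
class LeafProfile:
    """Predicted per-position blade length, width and area for one axis."""

    species: str
    tln: int
    positions: np.ndarray
    length_mm: np.ndarray
    width_mm: np.ndarray
    area_mm2: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tln": self.tln,
                "position": self.positions,
                "length_mm": self.length_mm,
                "width_mm": self.width_mm,
                "area_mm2": self.area_mm2,
                "is_flag": self.positions == self.tln,
            }
        )


def predict_profile(pset: SpeciesParameterSet, tln: int) -> LeafProfile:
    """Predict length, width and area for every leaf position 1..tln."""
    positions = np.arange(1, tln + 1)
    dims = {}
    for trait in Trait:
        p = build_params(pset, trait, tln)
        dims[trait] = leaf_dimension(positions, p)
    length = dims[Trait.BLADE_LENGTH]
    width = dims[Trait.BLADE_WIDTH]
    factors = np.where(
        positions == tln, pset.shape_factor_flag, pset.shape_factor_standard
    )
    return LeafProfile(
        species=pset.species.value,
        tln=tln,
        positions=positions,
        length_mm=length,
        width_mm=width,
        area_mm2=length * width * factors,
    )
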