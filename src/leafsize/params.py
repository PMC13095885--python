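"""Parameter containers for the expolinear-logistic leaf size model.

The model describes blade length or blade width (mm) of successive leaves on
the main culm as a three-phase curve: an expolinear rise up to the position
``xs`` of the largest leaf, followed by a logistic decay towards the flag
leaf.  Seven parameters describe one trait curve on one axis:

``L1``   size of the first (coleoptile) leaf, mm
``cm``   maximum slope of the linear phase, mm per leaf
``rm``   rate constant of the exponential phase, per leaf
``tb``   position offset of the expolinear term, leaf-position units
``xs``   position of the largest leaf (real-valued)
``dr``   decay rate of the logistic phase, per leaf
``dsl``  offset of the upper logistic asymptote above the maximum, mm

Across a species, ``xs`` and ``dr`` are not free constants but functions of
the total leaf number (TLN) of the axis: ``xs`` is linear in TLN (segmented
for sorghum, with a breakpoint at TLN 20.5), while ``dr`` declines linearly
with TLN up to a species breakpoint and is constant beyond it.  The
remaining five parameters are fixed per species and trait.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Union

from .errors import ParameterDomainError

__all__ = [
    "Trait",
    "SpeciesId",
    "ProfileParams",
    "BellParams",
    "TlnLinearRule",
    "TlnSegmentedRule",
    "TlnPlateauRule",
    "TraitParams",
    "SpeciesParameterSet",
    "SHAPE_FACTOR_STANDARD",
    "SHAPE_FACTOR_FLAG",
    "DEFAULT_TLN_RANGE",
]

#: Leaf shape factor converting the length x width bounding rectangle to
#: blade area, for all leaves except the flag leaf.
SHAPE_FACTOR_STANDARD = 0.71
#: Shape factor for the flag leaf (position = TLN).
SHAPE_FACTOR_FLAG = 0.635

#: Default plausibility range for total leaf number, spanning the extremes
#: observed in the training data across the three species (min 9, max 44).
DEFAULT_TLN_RANGE = (8, 45)


class Trait(str, enum.Enum):
    """Which blade dimension a curve describes."""

    BLADE_LENGTH = "blade_length"
    BLADE_WIDTH = "blade_width"


class SpeciesId(str, enum.Enum):
    MAIZE = "maize"
    SORGHUM = "sorghum"
    PEARL_MILLET = "pearl_millet"


@dataclass(frozen=True)
class ProfileParams:
    """The seven parameters of one trait curve for one axis (all mm-based)."""

    L1: float
    cm: float
    rm: float
    tb: float
    xs: float
    dr: float
    dsl: float

    def validate(self) -> "ProfileParams":
        """Check domain invariants, raising :class:`ParameterDomainError`.

        ``dr = 0`` and/or ``dsl = 0`` are accepted degenerate settings that
        flatten the post-peak phase.  ``xs <= tb + 1`` is permitted (the
        packaged pearl-millet blade-width set has tb > xs - 1): the peak
        then falls on the lower, curved part of the expolinear term.
        """
        for name, value, ok in (
            ("L1", self.L1, self.L1 > 0),
            ("cm", self.cm, self.cm > 0),
            ("rm", self.rm, self.rm > 0),
            ("dr", self.dr, self.dr >= 0),
            ("dsl", self.dsl, self.dsl >= 0),
        ):
            if not ok:
                raise ParameterDomainError(
                    f"parameter {name}={value!r} violates its invariant "
                    f"({'> 0' if name in ('L1', 'cm', 'rm') else '>= 0'})"
                )
        return self

    def replace(self, **changes) -> "ProfileParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class BellParams:
    """Parameters of the legacy bell-shaped leaf-area-by-position baseline.

    ``Y0`` is the mature area of the largest leaf (mm^2), ``x0`` its
    position, ``a`` the breadth and ``b`` the skewness of the bell.
    """

    Y0: float
    x0: float
    a: float
    b: float

    def validate(self) -> "BellParams":
        if not self.Y0 > 0:
            raise ParameterDomainError(f"parameter Y0={self.Y0!r} must be > 0")
        if not self.x0 > 0:
            raise ParameterDomainError(f"parameter x0={self.x0!r} must be > 0")
        return self


@dataclass(frozen=True)
class TlnLinearRule:
    """xs = intercept + slope * TLN (maize and pearl millet)."""

    intercept: float
    slope: float

    def __call__(self, tln: float) -> float:
        return self.intercept + self.slope * tln


@dataclass(frozen=True)
class TlnSegmentedRule:
    """Continuous two-slope rule for xs versus TLN (sorghum).

    Below the breakpoint: ``intercept + slope_low * TLN``; above it the line
    continues from its value at the breakpoint with ``slope_high``.  A single
    intercept plus two slopes and a breakpoint only identifies the continuous
    form, which is what is used here.
    """

    intercept: float
    slope_low: float
    slope_high: float
    breakpoint: float

    def __call__(self, tln: float) -> float:
        if tln <= self.breakpoint:
            return self.intercept + self.slope_low * tln
        return (
            self.intercept
            + self.slope_low * self.breakpoint
            + self.slope_high * (tln - self.breakpoint)
        )


@dataclass(frozen=True)
class TlnPlateauRule:
    """Decline-then-constant (hockey-stick) rule for dr versus TLN.

    ``intercept + slope * TLN`` up to the breakpoint; beyond it dr stays at
    the line's value at the breakpoint (continuity defines the plateau).
    """

    intercept: float
    slope: float
    breakpoint: float

    @property
    def plateau(self) -> float:
        return self.intercept + self.slope * self.breakpoint

    def __call__(self, tln: float) -> float:
        return self.intercept + self.slope * min(tln, self.breakpoint)


XsRule = Union[TlnLinearRule, TlnSegmentedRule]


@dataclass(frozen=True)
class TraitParams:
    """Fixed parameters plus TLN rules for one trait of one species.

    ``std_errors`` maps parameter names (``L1``, ``cm``, ``rm``, ``tb``,
    ``dsl``, ``xs.a``, ``xs.b``, ``xs.c``, ``dr.a``, ``dr.b``, ``dr.xs``) to
    their standard errors; entries may be absent when unknown.
    """

    L1: float
    cm: float
    rm: float
    tb: float
    dsl: float
    xs_rule: XsRule
    dr_rule: TlnPlateauRule
    std_errors: Mapping[str, float] = field(default_factory=dict)

    def validate(self) -> "TraitParams":
        for name, value in (("L1", self.L1), ("cm", self.cm), ("rm", self.rm)):
            if not value > 0:
                raise ParameterDomainError(f"parameter {name}={value!r} must be > 0")
        if self.dsl < 0:
            raise ParameterDomainError(f"parameter dsl={self.dsl!r} must be >= 0")
        if any(se < 0 for se in self.std_errors.values()):
            raise ParameterDomainError("standard errors must be >= 0")
        return self


@dataclass(frozen=True)
class SpeciesParameterSet:
    """Complete parameterization of one species: both traits + shape factors."""

    species: SpeciesId
    traits: Mapping[Trait, TraitParams]
    shape_factor_standard: float = SHAPE_FACTOR_STANDARD
    shape_factor_flag: float = SHAPE_FACTOR_FLAG
    tln_range: tuple[int, int] = DEFAULT_TLN_RANGE

    def validate(self) -> "SpeciesParameterSet":
        missing = [t for t in Trait if t not in self.traits]
        if missing:
            raise ParameterDomainError(
                f"parameter set for {self.species.value} lacks traits: "
                f"{[t.value for t in missing]}"
            )
        for factor, name in (
            (self.shape_factor_standard, "shape_factor_standard"),
            (self.shape_factor_flag, "shape_factor_flag"),
        ):
            if not 0 < factor <= 1:
                raise ParameterDomainError(f"{name}={factor!r} must be in (0, 1]")
        for tp in self.traits.values():
            tp.validate()
        return self

    def trait(self, trait: Trait) -> TraitParams:
        return self.traits[Trait(trait)]

    def shape_factor(self, is_flag: bool) -> float:
        return self.shape_factor_flag if is_flag else self.shape_factor_standard


def warn_xs_out_of_range(xs: float, tln: int) -> None:
    """Contract check: xs must lie strictly inside (1, tln)."""
    if not 1.0 < xs < tln:
        warnings.warn(
            f"largest-leaf position xs={xs:.3g} falls outside (1, {tln}); "
            "the TLN rule is inconsistent with this total leaf number",
            stacklevel=3,
        )
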