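"""Bidirectional genetic-to-cytological coordinate conversion.

The genetic map and the polytene band map are not linearly related along a
chromosome (recombination is suppressed near the centromere), so
conversion interpolates between reference loci — known genes with both an
experimentally derived cM position and a cytological location — exactly as
one would do by eye against a cytogenetic map.  Interpolation is piecewise
linear on the linearized cytology scale; queries outside the reference
range clamp to the nearest terminal locus with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_types import CytoPosition, ReferenceLocus, ValidationError

__all__ = [
    "ExtrapolationWarning",
    "ReferenceMap",
    "linear_to_cyto",
    "cm_to_linear",
    "cm_to_cyto",
    "cyto_to_cm",
]


class ExtrapolationWarning(UserWarning):
    """A conversion query fell outside the reference-locus range and was
    clamped to the nearest terminal locus."""


@dataclass(frozen=True)
class ReferenceMap:
    """An ordered table of reference loci anchoring cM-cytology conversion.

    Requires >= 2 loci, strictly increasing in cM with strictly increasing
    cytology (co-monotone); violations are rejected at construction since
    a non-monotone table has no consistent interpolant.
    """

    loci: tuple[ReferenceLocus, ...]
    chromosome: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "loci", tuple(self.loci))
        if len(self.loci) < 2:
            raise ValidationError("reference map needs at least 2 loci")
        cms = [l.cM for l in self.loci]
        lins = [l.cyto.linear for l in self.loci]
        for i, (a, b) in enumerate(zip(cms, cms[1:])):
            if b <= a:
                raise ValidationError(
                    f"reference loci not strictly increasing in cM at "
                    f"{self.loci[i + 1].symbol} ({b} after {a})"
                )
        for i, (a, b) in enumerate(zip(lins, lins[1:])):
            if b <= a:
                raise ValidationError(
                    f"cytological order disagrees with genetic order at "
                    f"{self.loci[i + 1].symbol} ({self.loci[i + 1].cyto} after "
                    f"{self.loci[i].cyto})"
                )

    @property
    def cms(self) -> np.ndarray:
        return np.array([l.cM for l in self.loci])

    @property
    def linears(self) -> np.ndarray:
        return np.array([l.cyto.linear for l in self.loci])


_LETTERS = "ABCDEF"
_EPS = 1e-9


def linear_to_cyto(linear: float) -> CytoPosition:
    """Floor a linear cytology value to the (band, letter) grid."""
    band = int(np.floor(linear + _EPS))
    idx = int(np.floor((linear - band) * 6.0 + _EPS))
    idx = min(max(idx, 0), 5)
    return CytoPosition(band=band, letter=_LETTERS[idx])


def _warn_if_clamped(value: float, lo: float, hi: float, what: str) -> None:
    if value < lo or value > hi:
        warnings.warn(
            f"{what} outside reference range [{lo:g}, {hi:g}]; clamped to the "
            f"nearest terminal locus",
            ExtrapolationWarning,
            stacklevel=3,
        )


def cm_to_linear(cM: float, refmap: ReferenceMap) -> float:
    """Interpolated linear cytology value for a genetic position."""
    cms = refmap.cms
    _warn_if_clamped(cM, cms[0], cms[-1], f"genetic position {cM} cM")
    return float(np.interp(cM, cms, refmap.linears))


def cm_to_cyto(cM: float, refmap: ReferenceMap) -> CytoPosition:
    """Convert a genetic map position to a cytological position.

    Returns the lettered division containing the interpolated value (the
    floor on the band/letter grid); resolution finer than one lettered
    division is not claimed.
    """
    return linear_to_cyto(cm_to_linear(cM, refmap))


def cyto_to_cm(pos: CytoPosition, refmap: ReferenceMap) -> float:
    """Convert a cytological position to a genetic map position (inverse
    interpolation on the linear scale, clamped with a warning outside the
    reference range)."""
    lins = refmap.linears
    _warn_if_clamped(pos.linear, lins[0], lins[-1], f"cytological position {pos}")
    return float(np.interp(pos.linear, lins, refmap.cms))
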