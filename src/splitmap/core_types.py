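"""Domain model for dominant-marker recombination mapping.

Chromosomes are described on two coordinate scales: the genetic map
(centiMorgans) and polytene-chromosome cytology (band/letter/subdivision,
e.g. ``95A`` or ``94E7``).  Dominant visible markers live on the genetic
scale; deficiencies live on the cytological scale; the mapping method moves
between the two.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "CytoParseError",
    "ValidationError",
    "CytoPosition",
    "parse_cyto",
    "parse_cyto_span",
    "span_midpoint",
    "linearize_cyto",
    "GeneticMarker",
    "MarkerPair",
    "ChromosomeMap",
    "ProgenyCounts",
    "ReferenceLocus",
    "Deficiency",
    "CHR2_BAND_RANGE",
    "CHR3_BAND_RANGE",
    "MAX_SUBDIVISION",
]


class CytoParseError(ValueError):
    """Raised when a cytological band string cannot be parsed."""


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


#: Valid band ranges per chromosome arm pair (Bridges' polytene map).
CHR2_BAND_RANGE = (21, 60)
CHR3_BAND_RANGE = (61, 100)

#: Fixed upper bound on numbered subdivisions within a lettered division,
#: used only to give subdivisions a consistent sub-letter linearization.
MAX_SUBDIVISION = 30

_LETTERS = "ABCDEF"


@dataclass(frozen=True)
class CytoPosition:
    """A cytological position: numbered band, lettered division, optional
    numbered subdivision (``95A``, ``94E7``).

    ``linear`` maps the position onto a real axis that is strictly monotone
    in (band, letter, subdivision) lexicographic order, enabling distances
    and interpolation.  A missing subdivision linearizes to the start of its
    lettered division.
    """

    band: int
    letter: str
    subdivision: Optional[int] = None

    def __post_init__(self) -> None:
        if self.letter not in _LETTERS:
            raise CytoParseError(f"letter {self.letter!r} outside A-F")
        if self.band < 1:
            raise CytoParseError(f"band {self.band} must be positive")
        if self.subdivision is not None and self.subdivision < 1:
            raise CytoParseError(f"subdivision {self.subdivision} must be >= 1")

    @property
    def letter_index(self) -> int:
        return _LETTERS.index(self.letter)

    @property
    def linear(self) -> float:
        sub = 0 if self.subdivision is None else self.subdivision - 1
        return self.band + self.letter_index / 6.0 + sub / (6.0 * MAX_SUBDIVISION)

    def __str__(self) -> str:
        sub = "" if self.subdivision is None else str(self.subdivision)
        return f"{self.band}{self.letter}{sub}"

    def __lt__(self, other: "CytoPosition") -> bool:
        return self.linear < other.linear


_CYTO_RE = re.compile(r"^(\d{1,3})([A-Fa-f])(\d{1,2})?$")
_SPAN_RE = re.compile(r"^(\d{1,3})([A-Fa-f])([A-Fa-f])$")


def _check_band_range(band: int, band_range: Optional[tuple[int, int]], text: str) -> None:
    if band_range is not None and not band_range[0] <= band <= band_range[1]:
        raise CytoParseError(
            f"band {band} in {text!r} outside configured range {band_range[0]}-{band_range[1]}"
        )


def parse_cyto(text: str, band_range: Optional[tuple[int, int]] = None) -> CytoPosition:
    """Parse a band string such as ``"95A"`` or ``"94E7"``.

    ``band_range`` optionally restricts the numbered band (chr3 arms span
    61-100); violations raise :class:`CytoParseError` naming the token.
    """
    m = _CYTO_RE.match(text.strip())
    if not m:
        raise CytoParseError(f"malformed cytological position {text!r}")
    band = int(m.group(1))
    _check_band_range(band, band_range, text)
    sub = int(m.group(3)) if m.group(3) else None
    return CytoPosition(band=band, letter=m.group(2).upper(), subdivision=sub)


def parse_cyto_span(
    text: str, band_range: Optional[tuple[int, int]] = None
) -> tuple[CytoPosition, CytoPosition]:
    """Parse a position or compact range into a (start, end) span.

    Accepts a single position (``"61A"`` -> (61A, 61A)), a two-letter
    compact range on one band (``"66CD"`` -> (66C, 66D), ``"67BD"`` ->
    (67B, 67D)), or an explicit dash range (``"76A-76D"``).
    """
    text = text.strip()
    if "-" in text:
        lo_s, hi_s = (part.strip() for part in text.split("-", 1))
        lo, hi = parse_cyto(lo_s, band_range), parse_cyto(hi_s, band_range)
    else:
        m = _SPAN_RE.match(text)
        if m:
            band = int(m.group(1))
            _check_band_range(band, band_range, text)
            lo = CytoPosition(band, m.group(2).upper())
            hi = CytoPosition(band, m.group(3).upper())
        else:
            lo = hi = parse_cyto(text, band_range)
    if hi.linear < lo.linear:
        raise CytoParseError(f"span {text!r} is reversed")
    return lo, hi


def span_midpoint(span: tuple[CytoPosition, CytoPosition]) -> float:
    """Linear midpoint of a cytological span (equals ``linear`` for a point)."""
    return 0.5 * (span[0].linear + span[1].linear)


def linearize_cyto(pos: CytoPosition) -> float:
    """Monotone real-axis coordinate of a cytological position."""
    return pos.linear


@dataclass(frozen=True)
class GeneticMarker:
    """A dominant visible marker with a genetic map position.

    ``cM`` is the standard-map position in centiMorgans; ``cyto`` the
    marker's own cytological location when known; ``phenotype_note`` the
    scorable phenotype (free text).
    """

    symbol: str
    cM: float
    cyto: Optional[CytoPosition] = None
    phenotype_note: str = ""

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValidationError("marker symbol must be non-empty")
        if not (self.cM >= 0 and self.cM == self.cM and self.cM != float("inf")):
            raise ValidationError(f"marker {self.symbol}: cM must be finite and >= 0")


@dataclass(frozen=True)
class MarkerPair:
    """An ordered pair of dominant markers used in one mapping cross."""

    left: GeneticMarker
    right: GeneticMarker
    id: str = ""

    def __post_init__(self) -> None:
        if not self.left.cM < self.right.cM:
            raise ValidationError(
                f"pair {self.left.symbol},{self.right.symbol}: left marker must "
                f"precede right marker on the genetic map"
            )
        if not self.id:
            object.__setattr__(self, "id", f"{self.left.symbol},{self.right.symbol}")

    @property
    def span_cM(self) -> float:
        return self.right.cM - self.left.cM


@dataclass(frozen=True)
class ChromosomeMap:
    """An ordered marker set spanning one chromosome, plus the mapping pairs."""

    name: str
    markers: tuple[GeneticMarker, ...]
    pairs: tuple[MarkerPair, ...]
    length_cM: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        object.__setattr__(self, "pairs", tuple(self.pairs))
        symbols = [m.symbol for m in self.markers]
        if len(set(symbols)) != len(symbols):
            raise ValidationError(f"duplicate marker symbols in chromosome {self.name}")
        cms = [m.cM for m in self.markers]
        if any(b <= a for a, b in zip(cms, cms[1:])):
            raise ValidationError(
                f"chromosome {self.name}: markers must be strictly increasing in cM"
            )
        known = set(symbols)
        for p in self.pairs:
            for m in (p.left, p.right):
                if m.symbol not in known:
                    raise ValidationError(
                        f"pair {p.id} references marker {m.symbol} absent from "
                        f"chromosome {self.name}"
                    )
        if cms and self.length_cM < max(cms):
            raise ValidationError(
                f"chromosome {self.name}: length_cM {self.length_cM} shorter than "
                f"last marker at {max(cms)} cM"
            )

    def marker(self, symbol: str) -> GeneticMarker:
        for m in self.markers:
            if m.symbol == symbol:
                return m
        raise KeyError(f"no marker {symbol!r} on chromosome {self.name}")

    def pair(self, pair_id: str) -> MarkerPair:
        for p in self.pairs:
            if p.id == pair_id:
                return p
        raise KeyError(f"no pair {pair_id!r} on chromosome {self.name}")


def _check_count(name: str, value: Optional[int], allow_none: bool = False) -> None:
    if value is None:
        if allow_none:
            return
        raise ValidationError(f"{name} is required")
    if not isinstance(value, (int,)) or isinstance(value, bool) or value < 0:
        raise ValidationError(f"{name} must be a non-negative integer, got {value!r}")


@dataclass(frozen=True)
class ProgenyCounts:
    """Scored F2 class counts for one marker-pair cross.

    ``n_lost_left`` are progeny retaining only the right marker (the left
    marker was lost to recombination); ``n_lost_right`` the mirror class;
    ``n_unmarked`` progeny retaining neither marker.  ``n_both`` (progeny
    retaining both markers) and ``n_balancer`` (balancer-marked progeny set
    aside before scoring) are optional because in practice only the loss
    classes need to be counted.
    """

    pair_id: str
    n_lost_left: int
    n_lost_right: int
    n_unmarked: int
    n_both: Optional[int] = None
    n_balancer: Optional[int] = None

    def __post_init__(self) -> None:
        _check_count("n_lost_left", self.n_lost_left)
        _check_count("n_lost_right", self.n_lost_right)
        _check_count("n_unmarked", self.n_unmarked)
        _check_count("n_both", self.n_both, allow_none=True)
        _check_count("n_balancer", self.n_balancer, allow_none=True)

    @property
    def n_splits(self) -> int:
        """Recombinant progeny that lost exactly one marker."""
        return self.n_lost_left + self.n_lost_right

    @property
    def n_informative(self) -> int:
        """Progeny informative for the inside/outside decision."""
        return self.n_splits + self.n_unmarked

    @property
    def n_scored(self) -> Optional[int]:
        """All scored viable non-balancer progeny, if n_both was recorded."""
        if self.n_both is None:
            return None
        return self.n_both + self.n_informative


@dataclass(frozen=True)
class ReferenceLocus:
    """A locus anchoring the cM-cytology relationship (known gene with an
    experimentally derived genetic map position)."""

    symbol: str
    cM: float
    cyto: CytoPosition


@dataclass(frozen=True)
class Deficiency:
    """A molecularly defined deletion described by its cytological extent."""

    name: str
    cyto_start: CytoPosition
    cyto_end: CytoPosition

    def __post_init__(self) -> None:
        if self.cyto_end.linear < self.cyto_start.linear:
            raise ValidationError(f"deficiency {self.name}: start after end")

    @property
    def center(self) -> float:
        return 0.5 * (self.cyto_start.linear + self.cyto_end.linear)

    def contains(self, linear: float) -> bool:
        return self.cyto_start.linear <= linear <= self.cyto_end.linear
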