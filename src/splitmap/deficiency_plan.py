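"""Deficiency complementation planning and mapping-reliability reporting.

Once recombination analysis places a lesion at an estimated cytological
position, the lesion is crossed to nearby molecularly defined deletions
(a deficiency kit); failure to complement localizes the gene.  This module
ranks kit deficiencies around an estimate, measures estimate-to-hit
distances (in lettered divisions and in intervening kit stocks), records
complementation outcomes, and summarizes mapping reliability as "arrows"
from estimated to actual position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

from .core_types import (
    CytoPosition,
    Deficiency,
    ValidationError,
    parse_cyto_span,
    span_midpoint,
)
from .map_convert import ReferenceMap

__all__ = [
    "DeficiencyKit",
    "ComplementationLedger",
    "MappingRecord",
    "ReliabilityReport",
    "candidate_deficiencies",
    "deficiencies_away",
    "reliability_report",
    "make_tiled_kit",
]

Outcome = Literal["complements", "fails_to_complement", "untested"]


@dataclass(frozen=True)
class DeficiencyKit:
    """A kit of deficiencies sorted along the chromosome; overlaps allowed."""

    deficiencies: tuple[Deficiency, ...]
    name: str = ""

    def __post_init__(self) -> None:
        ordered = tuple(
            sorted(self.deficiencies, key=lambda d: (d.cyto_start.linear, d.name))
        )
        if not ordered:
            raise ValidationError(f"deficiency kit {self.name!r} is empty")
        names = [d.name for d in ordered]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate deficiency names in kit {self.name!r}")
        object.__setattr__(self, "deficiencies", ordered)

    def __iter__(self):
        return iter(self.deficiencies)

    def __len__(self) -> int:
        return len(self.deficiencies)

    def __contains__(self, d: Deficiency) -> bool:
        return any(x.name == d.name for x in self.deficiencies)


@dataclass
class ComplementationLedger:
    """Wet-lab complementation outcomes, one per (mutation, deficiency).

    Outcomes are user-entered observations; the planner cannot infer them.
    """

    records: list[tuple[str, str, Outcome]] = field(default_factory=list)

    def record(self, mutation: str, deficiency: str, outcome: Outcome) -> None:
        if outcome not in ("complements", "fails_to_complement", "untested"):
            raise ValidationError(f"unknown outcome {outcome!r}")
        for i, (m, d, _) in enumerate(self.records):
            if m == mutation and d == deficiency:
                self.records[i] = (mutation, deficiency, outcome)
                return
        self.records.append((mutation, deficiency, outcome))

    def outcome(self, mutation: str, deficiency: str) -> Outcome:
        for m, d, o in self.records:
            if m == mutation and d == deficiency:
                return o
        return "untested"

    def hits(self, mutation: str) -> list[str]:
        return [
            d for m, d, o in self.records if m == mutation and o == "fails_to_complement"
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records, columns=["mutation", "deficiency", "outcome"]
        )


def candidate_deficiencies(
    estimate_cyto: CytoPosition, kit: DeficiencyKit, k_each_side: int
) -> list[Deficiency]:
    """Rank kit deficiencies for complementation testing around an estimate.

    Deficiencies containing the estimate come first; the rest alternate
    outward by center distance on the linear scale, up to ``k_each_side``
    per side.  Ties break by (distance, name) so the plan is deterministic.
    """
    if k_each_side < 0:
        raise ValueError("k_each_side must be >= 0")
    est = estimate_cyto.linear
    containing = [d for d in kit if d.contains(est)]
    left = [d for d in kit if not d.contains(est) and d.center < est]
    right = [d for d in kit if not d.contains(est) and d.center >= est]
    key = lambda d: (abs(d.center - est), d.name)
    picked = sorted(left, key=key)[:k_each_side] + sorted(right, key=key)[:k_each_side]
    return sorted(containing, key=key) + sorted(picked, key=key)


def deficiencies_away(
    estimate_cyto: CytoPosition, hit: Deficiency, kit: DeficiencyKit
) -> int:
    """Number of kit deficiencies separating the estimate from the hit.

    Zero when the hit contains the estimate.  Otherwise counts kit
    deficiencies whose whole interval lies within the closed gap between
    the estimate and the hit's nearest edge, excluding the hit itself and
    any deficiency containing the estimate; partial overlaps with the gap
    do not count.  This is the "how many stocks away" measure of mapping
    accuracy.
    """
    if hit not in kit:
        raise ValueError(f"deficiency {hit.name!r} is not in kit {kit.name!r}")
    est = estimate_cyto.linear
    if hit.contains(est):
        return 0
    if est < hit.cyto_start.linear:
        lo, hi = est, hit.cyto_start.linear
    else:
        lo, hi = hit.cyto_end.linear, est
    n = 0
    for d in kit:
        if d.name == hit.name or d.contains(est):
            continue
        if lo <= d.cyto_start.linear and d.cyto_end.linear <= hi:
            n += 1
    return n


@dataclass(frozen=True)
class MappingRecord:
    """One mapped mutation: estimated position and complementation hit.

    ``cm_label`` carries the estimate as reported — a cM value or a
    terminal tag such as ``"left of R"``; ``est_cm`` is the parsed number
    (None for terminal records).  Cytology fields keep the reported strings
    (possibly compact spans such as ``"66CD"``).
    """

    mutation: str
    alleles: int
    cm_label: str
    est_cyto: str
    deficiency: str
    actual_cyto: str

    @property
    def est_cm(self) -> Optional[float]:
        try:
            return float(self.cm_label)
        except ValueError:
            return None

    @property
    def terminal(self) -> bool:
        return self.est_cm is None


@dataclass(frozen=True)
class ReliabilityReport:
    table: pd.DataFrame
    summary: dict
    errors: tuple[str, ...] = ()


def reliability_report(
    records: Sequence[MappingRecord],
    refmap: Optional[ReferenceMap] = None,
    band_range: Optional[tuple[int, int]] = None,
    left_arm_max_band: int = 80,
) -> ReliabilityReport:
    """Arrow table measuring estimated-to-actual mapping distance.

    Per record the arrow runs from the estimated cytological position
    (base) to the actual position of the non-complementing deficiency
    (head); its length is the absolute difference on the linear cytology
    scale, with compact spans linearized at their midpoint.  The summary
    gives the record count, terminal-record count, and mean arrow length
    per chromosome arm (arm split at band ``left_arm_max_band``).
    Malformed records are listed in ``errors`` and skipped.

    When a reference map is supplied, an independently interpolated
    cytology column is added for records with a numeric cM estimate, as a
    cross-check of the reported estimated cytology.
    """
    rows = []
    errors: list[str] = []
    for rec in records:
        try:
            est_span = parse_cyto_span(rec.est_cyto, band_range)
            act_span = parse_cyto_span(rec.actual_cyto, band_range)
        except ValueError as exc:
            errors.append(f"{rec.mutation}: {exc}")
            continue
        est_lin = span_midpoint(est_span)
        act_lin = span_midpoint(act_span)
        row = {
            "mutation": rec.mutation,
            "est_cM": rec.cm_label,
            "est_cyto": rec.est_cyto,
            "deficiency": rec.deficiency,
            "actual_cyto": rec.actual_cyto,
            "base_linear": est_lin,
            "head_linear": act_lin,
            "arrow_length": abs(act_lin - est_lin),
            "arm": "L" if est_span[0].band <= left_arm_max_band else "R",
            "terminal": rec.terminal,
        }
        if refmap is not None and rec.est_cm is not None:
            from .map_convert import cm_to_cyto

            row["refmap_cyto"] = str(cm_to_cyto(rec.est_cm, refmap))
        rows.append(row)
    table = pd.DataFrame(rows)
    summary: dict = {"n_records": len(table), "n_errors": len(errors)}
    if len(table):
        summary["n_terminal"] = int(table["terminal"].sum())
        summary["mean_arrow_length"] = float(table["arrow_length"].mean())
        for arm in ("L", "R"):
            sub = table[table["arm"] == arm]
            summary[f"mean_arrow_length_{arm}"] = (
                float(sub["arrow_length"].mean()) if len(sub) else float("nan")
            )
    return ReliabilityReport(table=table, summary=summary, errors=tuple(errors))


def make_tiled_kit(
    n_tiles: int,
    band_start: int = 61,
    bands_per_tile: int = 1,
    name: str = "synthetic-tiled-kit",
) -> DeficiencyKit:
    """Synthetic kit of abutting single-span deficiencies for tests and
    planning dry-runs (tile i spans ``bands_per_tile`` bands from A to F)."""
    tiles = []
    for i in range(n_tiles):
        b0 = band_start + i * bands_per_tile
        b1 = b0 + bands_per_tile - 1
        tiles.append(
            Deficiency(
                name=f"Df(syn)T{i + 1:02d}",
                cyto_start=CytoPosition(b0, "A"),
                cyto_end=CytoPosition(b1, "F"),
            )
        )
    return DeficiencyKit(deficiencies=tuple(tiles), name=name)
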