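"""Inside/outside classification, split-ratio position estimation, and
chromosome-level consensus.

The decision rule: among viable non-balancer F2 progeny, recombinants that
lost exactly one dominant marker ("splits") arise from single crossovers
between a marker and the lethal lesion, while progeny that lost both
markers ("unmarked") require a double crossover when the lesion lies inside
the pair but only a single crossover when it lies outside.  Absent-or-rare
unmarked progeny therefore place the lesion inside the pair, where the
split ratio gives its relative position; common unmarked progeny place it
outside, where the split ratio gives the direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from scipy.stats import binomtest
from statsmodels.stats.proportion import proportion_confint

from .core_types import ChromosomeMap, MarkerPair, ProgenyCounts

__all__ = [
    "ClassifyConfig",
    "PairCall",
    "PositionEstimate",
    "MappingResult",
    "EstimationError",
    "classify_pair",
    "estimate_within_pair",
    "consensus",
]

Verdict = Literal["inside", "outside_left", "outside_right", "ambiguous"]
Status = Literal["localized", "terminal_left", "terminal_right", "gap_region", "inconsistent"]


class EstimationError(ValueError):
    """Raised when a position estimate cannot be computed from the counts."""


@dataclass(frozen=True)
class ClassifyConfig:
    """Thresholds for the inside/outside decision.

    A pair is called inside when the unmarked class is absent or rare:
    either at most ``k0`` unmarked progeny in absolute count, or an
    unmarked fraction u = unmarked/(unmarked + splits) below ``tau``.
    ``tau`` defaults to 0.15, midway between the closed-form expectation
    for a lesion inside the widest bundled pair (u ~ 0.09 for R,D with a
    mid-pair lesion) and for a lesion a few cM outside a pair (u >= 0.19
    five cM out of H,Pr).  Crosses with fewer than ``min_informative``
    informative progeny are called ambiguous rather than guessed.

    When ``require_significant_direction`` is on, an outside direction is
    only reported if a two-sided binomial test on the split counts rejects
    symmetry at ``direction_alpha``; otherwise any count difference sets
    the direction and exact ties are ambiguous.
    """

    k0: int = 1
    tau: float = 0.15
    min_informative: int = 10
    require_significant_direction: bool = False
    direction_alpha: float = 0.05


DEFAULT_CLASSIFY = ClassifyConfig()


@dataclass(frozen=True)
class PairCall:
    pair_id: str
    verdict: Verdict
    unmarked_fraction: float
    support_note: str = ""


@dataclass(frozen=True)
class PositionEstimate:
    """Split-ratio position estimate within a pair.

    ``cM_point`` is left + f*(right-left) with f the lost-left fraction of
    the splits, rounded to one decimal (the method's reporting precision);
    the interval is a Wilson score interval on f mapped through the same
    linear transform and clipped to the pair.
    """

    pair_id: str
    cM_point: float
    cM_low: float
    cM_high: float
    n_splits: int
    fraction: float


@dataclass(frozen=True)
class MappingResult:
    status: Status
    estimate: Optional[PositionEstimate]
    region: Optional[str]
    pair_calls: tuple[PairCall, ...]
    conflicts: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "estimate": None
            if self.estimate is None
            else {
                "pair_id": self.estimate.pair_id,
                "cM_point": self.estimate.cM_point,
                "cM_low": self.estimate.cM_low,
                "cM_high": self.estimate.cM_high,
                "n_splits": self.estimate.n_splits,
                "fraction": self.estimate.fraction,
            },
            "region": self.region,
            "pair_calls": [
                {
                    "pair_id": c.pair_id,
                    "verdict": c.verdict,
                    "unmarked_fraction": c.unmarked_fraction,
                    "support_note": c.support_note,
                }
                for c in self.pair_calls
            ],
            "conflicts": list(self.conflicts),
        }


def classify_pair(
    counts: ProgenyCounts, config: ClassifyConfig = DEFAULT_CLASSIFY
) -> PairCall:
    """Call the lesion inside or outside the pair from the scored classes."""
    informative = counts.n_informative
    if informative < config.min_informative:
        return PairCall(
            pair_id=counts.pair_id,
            verdict="ambiguous",
            unmarked_fraction=float("nan") if informative == 0 else counts.n_unmarked / informative,
            support_note=(
                f"only {informative} informative progeny "
                f"(< {config.min_informative}); score more progeny"
            ),
        )
    u = counts.n_unmarked / informative
    if counts.n_unmarked <= config.k0 or u < config.tau:
        return PairCall(
            pair_id=counts.pair_id,
            verdict="inside",
            unmarked_fraction=u,
            support_note=f"unmarked rare ({counts.n_unmarked}/{informative})",
        )
    nl, nr = counts.n_lost_left, counts.n_lost_right
    if nl == nr:
        return PairCall(
            pair_id=counts.pair_id,
            verdict="ambiguous",
            unmarked_fraction=u,
            support_note=f"unmarked common but splits tied ({nl}:{nr})",
        )
    if config.require_significant_direction:
        p = binomtest(nl, nl + nr, 0.5).pvalue
        if p >= config.direction_alpha:
            return PairCall(
                pair_id=counts.pair_id,
                verdict="ambiguous",
                unmarked_fraction=u,
                support_note=(
                    f"direction not significant (binomial p={p:.3g} "
                    f">= {config.direction_alpha})"
                ),
            )
    verdict: Verdict = "outside_right" if nl > nr else "outside_left"
    return PairCall(
        pair_id=counts.pair_id,
        verdict=verdict,
        unmarked_fraction=u,
        support_note=f"unmarked common ({counts.n_unmarked}/{informative}), splits {nl}:{nr}",
    )


def estimate_within_pair(
    counts: ProgenyCounts,
    pair: MarkerPair,
    confidence: float = 0.95,
) -> PositionEstimate:
    """Place the lesion within the pair from the ratio of the splits.

    The lost-left fraction of the splits is mapped linearly onto the cM
    interval between the markers — the method's defining arithmetic, kept
    deliberately free of any map-function correction.
    """
    n = counts.n_splits
    if n < 1:
        raise EstimationError(
            f"pair {pair.id}: no split progeny scored; score more progeny to "
            f"estimate a position"
        )
    f = counts.n_lost_left / n
    span = pair.span_cM
    point = round(pair.left.cM + f * span, 1)
    lo_f, hi_f = proportion_confint(
        counts.n_lost_left, n, alpha=1.0 - confidence, method="wilson"
    )
    lo = max(pair.left.cM, pair.left.cM + float(lo_f) * span)
    hi = min(pair.right.cM, pair.left.cM + float(hi_f) * span)
    lo, hi = min(lo, point), max(hi, point)
    return PositionEstimate(
        pair_id=counts.pair_id,
        cM_point=point,
        cM_low=lo,
        cM_high=hi,
        n_splits=n,
        fraction=f,
    )


def _direction_conflicts(
    inside_pair: MarkerPair,
    estimate: Optional[PositionEstimate],
    outside: Sequence[tuple[PairCall, MarkerPair]],
) -> list[str]:
    """Outside calls whose direction excludes the inside estimate.

    Comparisons use the estimate's confidence interval so sampling noise at
    a shared marker does not raise spurious conflicts.
    """
    lo = estimate.cM_low if estimate is not None else inside_pair.left.cM
    hi = estimate.cM_high if estimate is not None else inside_pair.right.cM
    conflicts = []
    for call, pair in outside:
        if call.verdict == "outside_right" and hi < pair.right.cM:
            conflicts.append(
                f"{call.pair_id} points right of {pair.right.symbol} "
                f"({pair.right.cM} cM) but the inside estimate tops out at {hi:.1f} cM"
            )
        elif call.verdict == "outside_left" and lo > pair.left.cM:
            conflicts.append(
                f"{call.pair_id} points left of {pair.left.symbol} "
                f"({pair.left.cM} cM) but the inside estimate starts at {lo:.1f} cM"
            )
    return conflicts


def consensus(
    calls_and_estimates: Sequence[tuple[PairCall, Optional[PositionEstimate]]],
    chromosome: ChromosomeMap,
    edge_margin_cM: float = 2.0,
) -> MappingResult:
    """Combine per-pair calls into one chromosome-level mapping result.

    Outcomes: a single corroborated inside call localizes the lesion;
    unanimous outward directions give a terminal call; directions that
    bracket an uncovered inter-pair region give a gap call naming the
    flanking markers (this is what lets the centromeric pair be skipped);
    two inside calls or contradictory directions are flagged inconsistent —
    the signature of multiple lesions on one chromosome.

    Edge rule: a lone inside call on the first (last) pair whose estimate
    pins to within ``edge_margin_cM`` of the terminal marker, with every
    other pair pointing further out, is reported as a terminal call.  A
    lesion beyond a terminal marker produces almost no unmarked progeny in
    that pair's cross (the lesion-marker interval is tiny), so it is
    indistinguishable from a lesion at the marker itself; the unanimous
    outward direction of the other pairs is then the honest summary.
    """
    if not calls_and_estimates:
        raise ValueError("consensus requires results for at least one pair")
    calls = tuple(c for c, _ in calls_and_estimates)
    informative = [
        (c, e) for c, e in calls_and_estimates if c.verdict != "ambiguous"
    ]
    if not informative:
        return MappingResult(
            status="inconsistent",
            estimate=None,
            region=None,
            pair_calls=calls,
            conflicts=("no informative pair calls",),
        )
    insides = [(c, e) for c, e in informative if c.verdict == "inside"]
    outsides = [
        (c, chromosome.pair(c.pair_id))
        for c, _ in informative
        if c.verdict.startswith("outside")
    ]
    first_marker = chromosome.markers[0]
    last_marker = chromosome.markers[-1]

    if len(insides) >= 2:
        conflicts = []
        ids = [c.pair_id for c, _ in insides]
        for i, (ci, _) in enumerate(insides):
            for cj, _ in insides[i + 1 :]:
                pi, pj = chromosome.pair(ci.pair_id), chromosome.pair(cj.pair_id)
                shared = {pi.left.symbol, pi.right.symbol} & {
                    pj.left.symbol,
                    pj.right.symbol,
                }
                note = f" (pairs share marker {', '.join(sorted(shared))})" if shared else ""
                conflicts.append(
                    f"both {ci.pair_id} and {cj.pair_id} called inside{note}"
                )
        return MappingResult(
            status="inconsistent",
            estimate=None,
            region=None,
            pair_calls=calls,
            conflicts=tuple(conflicts),
        )

    if len(insides) == 1:
        call, est = insides[0]
        pair = chromosome.pair(call.pair_id)
        others = [(c, p) for c, p in outsides]
        conflicts = _direction_conflicts(pair, est, others)
        if conflicts:
            return MappingResult(
                status="inconsistent",
                estimate=est,
                region=None,
                pair_calls=calls,
                conflicts=tuple(conflicts),
            )
        # terminal edge rule (see docstring)
        if (
            others
            and pair.left.symbol == first_marker.symbol
            and all(c.verdict == "outside_left" for c, _ in others)
            and est is not None
            and est.cM_low <= pair.left.cM + edge_margin_cM
        ):
            return MappingResult(
                status="terminal_left",
                estimate=est,
                region=f"left of {first_marker.symbol}",
                pair_calls=calls,
            )
        if (
            others
            and pair.right.symbol == last_marker.symbol
            and all(c.verdict == "outside_right" for c, _ in others)
            and est is not None
            and est.cM_high >= pair.right.cM - edge_margin_cM
        ):
            return MappingResult(
                status="terminal_right",
                estimate=est,
                region=f"right of {last_marker.symbol}",
                pair_calls=calls,
            )
        return MappingResult(
            status="localized", estimate=est, region=None, pair_calls=calls
        )

    # no inside call: direction geometry
    rights = [(c, p) for c, p in outsides if c.verdict == "outside_right"]
    lefts = [(c, p) for c, p in outsides if c.verdict == "outside_left"]
    if lefts and not rights:
        return MappingResult(
            status="terminal_left",
            estimate=None,
            region=f"left of {first_marker.symbol}",
            pair_calls=calls,
        )
    if rights and not lefts:
        return MappingResult(
            status="terminal_right",
            estimate=None,
            region=f"right of {last_marker.symbol}",
            pair_calls=calls,
        )
    # both directions present: either they bracket an uncovered region or
    # they cross (contradiction)
    _, a_pair = max(rights, key=lambda cp: cp[1].right.cM)
    _, b_pair = min(lefts, key=lambda cp: cp[1].left.cM)
    a_marker, b_marker = a_pair.right, b_pair.left
    if a_marker.cM <= b_marker.cM:
        return MappingResult(
            status="gap_region",
            estimate=None,
            region=f"between {a_marker.symbol} and {b_marker.symbol}",
            pair_calls=calls,
        )
    conflicts = tuple(
        f"{cr.pair_id} points right of {pr.right.symbol} ({pr.right.cM} cM) "
        f"but {cl.pair_id} points left of {pl.left.symbol} ({pl.left.cM} cM)"
        for cr, pr in rights
        for cl, pl in lefts
        if pr.right.cM > pl.left.cM
    )
    return MappingResult(
        status="inconsistent",
        estimate=None,
        region=None,
        pair_calls=calls,
        conflicts=conflicts,
    )
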