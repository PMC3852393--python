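"""Forward simulator of the two-generation dominant-marker mapping cross.

The modelled scheme: F1 females heterozygous for a doubly marked chromosome
over a mutagenized chromosome carrying one or more recessive lethal lesions
are backcrossed to males carrying the mutant chromosome over a balancer.
Maternal meiosis recombines between the marker and mutant chromosomes; the
paternal contribution is either the balancer (recombination-suppressed,
dominantly marked, set aside at scoring) or the mutant chromosome, which
kills any progeny whose maternal gamete also carries a lethal lesion.
Surviving non-balancer progeny are classified by which dominant markers
they retain.

Under the default crossover model, each interval between consecutive
tracked loci recombines independently with the Haldane map-function
probability r(d) = (1 - exp(-2d/100))/2 for d in cM (no interference).  A
gamma-renewal chiasma model with positive interference is available for
sensitivity runs.

Randomness uses numpy's default PCG64 generator; identical seeds reproduce
identical counts bit-for-bit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core_types import ChromosomeMap, MarkerPair, ProgenyCounts, ValidationError

__all__ = [
    "haldane_r",
    "CrossDesign",
    "GameteHaplotype",
    "sample_gamete",
    "simulate_backcross",
    "simulate_scored",
    "expected_class_frequencies",
]

HALDANE = "haldane_independent"
GAMMA = "gamma_interference"


def haldane_r(d_cM: float | np.ndarray) -> float | np.ndarray:
    """Haldane recombination fraction for a map distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM) / 100.0))


@dataclass(frozen=True)
class CrossDesign:
    """One mapping cross: a marker pair and the lethal lesion(s) to map.

    ``lethal_cM`` holds >= 1 positions on the mutant chromosome; more than
    one emulates multiply hit chromosomes from chemical mutagenesis.
    ``paternal_balancer_fraction`` is the probability a backcross father
    transmits the balancer rather than the mutant chromosome.
    ``misscore_rate`` optionally flips each scored marker phenotype
    independently with the given probability (default 0: perfect scoring).
    """

    chromosome: ChromosomeMap
    pair: MarkerPair
    lethal_cM: tuple[float, ...]
    crossover_model: str = HALDANE
    gamma_shape: Optional[float] = None
    paternal_balancer_fraction: float = 0.5
    misscore_rate: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "lethal_cM", tuple(float(x) for x in self.lethal_cM))
        if len(self.lethal_cM) < 1:
            raise ValidationError("at least one lethal locus is required")
        for x in self.lethal_cM:
            if not 0.0 <= x <= self.chromosome.length_cM:
                raise ValidationError(
                    f"lethal locus at {x} cM outside [0, {self.chromosome.length_cM}]"
                )
        if self.crossover_model not in (HALDANE, GAMMA):
            raise ValidationError(f"unknown crossover model {self.crossover_model!r}")
        if self.crossover_model == GAMMA:
            if self.gamma_shape is None or not self.gamma_shape > 0:
                raise ValidationError("gamma interference model requires gamma_shape > 0")
        if not 0.0 <= self.paternal_balancer_fraction <= 1.0:
            raise ValidationError("paternal_balancer_fraction must lie in [0, 1]")

    @property
    def tracked_loci(self) -> tuple[tuple[float, str], ...]:
        """(cM, role) for every tracked locus, sorted by position.

        Roles are ``left``/``right`` for the pair's markers and ``lethal``
        for each lesion.  Coincident positions are kept as separate
        zero-length intervals.
        """
        loci = [(self.pair.left.cM, "left"), (self.pair.right.cM, "right")]
        loci += [(x, "lethal") for x in self.lethal_cM]
        return tuple(sorted(loci, key=lambda t: (t[0], t[1])))


@dataclass(frozen=True)
class GameteHaplotype:
    """Origin of each tracked locus in one maternal gamete.

    ``origins`` holds True where the gamete carries the marker-chromosome
    allele.  Dominant markers travel with the marker chromosome; lethal
    alleles travel with the mutant chromosome, so the gamete is lethal-free
    exactly when every lethal-role locus has a marker-chromosome origin.
    """

    loci: tuple[tuple[float, str], ...]
    origins: tuple[bool, ...]

    def _role_origin(self, role: str) -> bool:
        for (pos, r), o in zip(self.loci, self.origins):
            if r == role:
                return o
        raise KeyError(role)

    @property
    def has_left_marker(self) -> bool:
        return self._role_origin("left")

    @property
    def has_right_marker(self) -> bool:
        return self._role_origin("right")

    @property
    def carries_lethal(self) -> bool:
        return any(
            not o for (pos, r), o in zip(self.loci, self.origins) if r == "lethal"
        )


def _interval_recomb_fractions(design: CrossDesign) -> np.ndarray:
    loci = design.tracked_loci
    d = np.diff([pos for pos, _ in loci])
    return haldane_r(d)


def _sample_origins(
    design: CrossDesign, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean array (n, n_loci): True = marker-chromosome origin."""
    loci = design.tracked_loci
    k = len(loci)
    if design.crossover_model == HALDANE:
        switches = np.empty((n, k), dtype=bool)
        switches[:, 0] = rng.random(n) < 0.5  # initial origin, equiprobable
        r = _interval_recomb_fractions(design)
        switches[:, 1:] = rng.random((n, k - 1)) < r
        # cumulative XOR of switches gives origin at each locus
        return np.logical_xor.accumulate(switches, axis=1)
    return _sample_origins_gamma(design, n, rng)


def _sample_origins_gamma(
    design: CrossDesign, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Gamma-renewal chiasma process with 1/2 thinning (interference model).

    Chiasma interarrivals along the bivalent are Gamma(shape, scale) in
    Morgans with mean 1/2 Morgan, so that after independent thinning the
    per-chromatid crossover density is 1 per Morgan, matching the map
    length.  A burn-in upstream of the tracked region approximates the
    stationary process.
    """
    loci = design.tracked_loci
    positions_M = np.array([pos for pos, _ in loci]) / 100.0
    lo, hi = positions_M[0] - 5.0, positions_M[-1]
    shape = float(design.gamma_shape)  # type: ignore[arg-type]
    scale = 0.5 / shape
    out = np.empty((n, len(loci)), dtype=bool)
    for i in range(n):
        x = lo
        crossovers = []
        while x < hi:
            x += rng.gamma(shape, scale)
            if x < hi and rng.random() < 0.5:
                crossovers.append(x)
        xo = np.asarray(crossovers)
        counts = np.searchsorted(xo, positions_M)
        origin0 = rng.random() < 0.5
        out[i] = np.logical_xor(origin0, (counts % 2).astype(bool))
    return out


def sample_gamete(design: CrossDesign, rng: np.random.Generator) -> GameteHaplotype:
    """Draw one maternal gamete from an F1 female of the mapping cross."""
    origins = _sample_origins(design, 1, rng)[0]
    return GameteHaplotype(loci=design.tracked_loci, origins=tuple(bool(o) for o in origins))


def _classify_batch(
    design: CrossDesign, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Simulate n conceptuses; return per-individual flags for survivors."""
    loci = design.tracked_loci
    origins = _sample_origins(design, n, rng)
    roles = [r for _, r in loci]
    i_left = roles.index("left")
    i_right = roles.index("right")
    lethal_ix = [i for i, r in enumerate(roles) if r == "lethal"]
    lethal_free = origins[:, lethal_ix].all(axis=1)
    balancer = rng.random(n) < design.paternal_balancer_fraction
    # non-balancer progeny inherit the paternal mutant chromosome and die
    # if the maternal gamete also carries a lethal allele
    scored = ~balancer & lethal_free
    left_p = origins[:, i_left].copy()
    right_p = origins[:, i_right].copy()
    if design.misscore_rate > 0:
        left_p ^= rng.random(n) < design.misscore_rate
        right_p ^= rng.random(n) < design.misscore_rate
    return {
        "balancer": balancer,
        "scored": scored,
        "left": left_p,
        "right": right_p,
    }


def _tally(design: CrossDesign, flags: dict[str, np.ndarray]) -> ProgenyCounts:
    s = flags["scored"]
    left, right = flags["left"][s], flags["right"][s]
    return ProgenyCounts(
        pair_id=design.pair.id,
        n_both=int((left & right).sum()),
        n_lost_left=int((~left & right).sum()),
        n_lost_right=int((left & ~right).sum()),
        n_unmarked=int((~left & ~right).sum()),
        n_balancer=int(flags["balancer"].sum()),
    )


def simulate_backcross(
    design: CrossDesign,
    n_progeny: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> ProgenyCounts:
    """Simulate ``n_progeny`` conceptuses of the backcross and score them.

    Balancer-carrying progeny are tallied in ``n_balancer`` and excluded
    from marker scoring; non-balancer progeny whose maternal gamete carries
    a lethal allele die.  The four scored classes sum to the number of
    surviving non-balancer conceptuses.
    """
    if n_progeny < 1:
        raise ValueError("n_progeny must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    return _tally(design, _classify_batch(design, n_progeny, rng))


def simulate_scored(
    design: CrossDesign,
    n_scored: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> ProgenyCounts:
    """Simulate until exactly ``n_scored`` viable non-balancer progeny.

    Conceptuses are drawn in batches and the first ``n_scored`` survivors
    (in draw order) are kept, so the stopping rule introduces no class
    bias.  Convenience for study designs phrased in scored progeny rather
    than conceptuses.
    """
    if n_scored < 1:
        raise ValueError("n_scored must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    # expected scored fraction is ~ (1 - balancer fraction) / 2; oversample
    frac = max(1e-3, (1.0 - design.paternal_balancer_fraction) * 0.5)
    kept: list[dict[str, np.ndarray]] = []
    n_kept = 0
    n_balancer = 0
    while n_kept < n_scored:
        batch = int(max(1000, 1.5 * (n_scored - n_kept) / frac))
        flags = _classify_batch(design, batch, rng)
        idx = np.flatnonzero(flags["scored"])
        take = idx[: n_scored - n_kept]
        n_balancer += int(flags["balancer"][: (take[-1] + 1) if take.size else batch].sum())
        kept.append({"left": flags["left"][take], "right": flags["right"][take]})
        n_kept += take.size
    left = np.concatenate([k["left"] for k in kept])
    right = np.concatenate([k["right"] for k in kept])
    return ProgenyCounts(
        pair_id=design.pair.id,
        n_both=int((left & right).sum()),
        n_lost_left=int((~left & right).sum()),
        n_lost_right=int((left & ~right).sum()),
        n_unmarked=int((~left & ~right).sum()),
        n_balancer=n_balancer,
    )


def expected_class_frequencies(design: CrossDesign) -> dict[str, float]:
    """Exact conditional class probabilities among viable non-balancer F2.

    Enumerates initial origin and every interval recombination pattern
    under the no-interference model, conditions on the gamete carrying no
    lethal allele (the viability selection), and returns probabilities for
    the four scored classes.  For a single lethal strictly inside the pair
    this reduces to the textbook weights both=(1-r1)(1-r2),
    lost_left=r1(1-r2), lost_right=(1-r1)r2, unmarked=r1*r2 (normalized).
    """
    if design.crossover_model != HALDANE:
        raise NotImplementedError(
            "closed-form class frequencies are only available for the "
            "interval-independence (Haldane) model"
        )
    loci = design.tracked_loci
    roles = [r for _, r in loci]
    rfracs = np.asarray(_interval_recomb_fractions(design))
    k = len(rfracs)
    weights = {"both": 0.0, "lost_left": 0.0, "lost_right": 0.0, "unmarked": 0.0}
    total_viable = 0.0
    for origin0 in (True, False):
        for pattern in itertools.product((False, True), repeat=k):
            p = 0.5
            origin = origin0
            origins = [origin0]
            for switch, r in zip(pattern, rfracs):
                p *= r if switch else (1.0 - r)
                origin ^= switch
                origins.append(origin)
            if any(not o for o, role in zip(origins, roles) if role == "lethal"):
                continue  # gamete carries a lethal allele; dies over mutant chrom
            total_viable += p
            left = origins[roles.index("left")]
            right = origins[roles.index("right")]
            cls = (
                "both" if left and right
                else "lost_left" if right
                else "lost_right" if left
                else "unmarked"
            )
            weights[cls] += p
    if total_viable <= 0:
        raise ValidationError("no viable gamete class has positive probability")
    return {cls: w / total_viable for cls, w in weights.items()}
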