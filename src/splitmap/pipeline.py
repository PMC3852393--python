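"""End-to-end mapping pipeline and reproducible synthetic scenarios.

``run_pipeline`` ties the stages together for one mutation: obtain scored
counts for each marker pair (from a file of wet-lab counts or from the
cross simulator), classify each pair, estimate a position within the
inside pair, form the chromosome-level consensus, convert the genetic
position to cytology, and rank kit deficiencies for complementation
testing.  All randomness flows from one user-visible seed recorded in the
manifest.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import fixtures, io
from .core_types import ChromosomeMap, CytoPosition, ProgenyCounts, ValidationError
from .deficiency_plan import Deficiency, DeficiencyKit, candidate_deficiencies
from .estimator import (
    ClassifyConfig,
    DEFAULT_CLASSIFY,
    MappingResult,
    PairCall,
    PositionEstimate,
    classify_pair,
    consensus,
    estimate_within_pair,
)
from .map_convert import ExtrapolationWarning, ReferenceMap, cm_to_cyto
from .meiosis_sim import CrossDesign, simulate_scored

__all__ = [
    "PipelineConfig",
    "PipelineOutcome",
    "StageFailure",
    "run_pipeline",
    "Scenario",
    "generate_fixture_scenarios",
    "run_scenario",
]

BUNDLED = "bundled"
NONE = "none"


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for one pipeline run.

    ``markers``/``refmap``/``kit`` accept a TSV path, ``"bundled"`` for the
    shipped chromosome-3 tables, or ``"none"`` to skip the stage (refmap
    and kit only).  Counts come either from ``counts`` (a TSV of scored
    wet-lab counts) or, when that is absent, from the cross simulator using
    ``lethal_cM``, ``n_scored`` per pair, and ``seed``.
    """

    markers: str = BUNDLED
    pair_ids: tuple[str, ...] = fixtures.CHR3_PAIR_IDS
    counts: Optional[str] = None
    lethal_cM: tuple[float, ...] = ()
    n_scored: int = 150
    seed: Optional[int] = None
    refmap: str = BUNDLED
    kit: str = BUNDLED
    k_each_side: int = 5
    confidence: float = 0.95
    classify: ClassifyConfig = DEFAULT_CLASSIFY
    out_dir: Optional[str] = None

    @classmethod
    def from_mapping(cls, raw: dict) -> "PipelineConfig":
        """Build from a flat string mapping (the key=value config format)."""
        kwargs: dict = {}
        classify_kwargs: dict = {}
        for key, value in raw.items():
            if key in ("markers", "counts", "refmap", "kit"):
                kwargs[key] = value
            elif key == "pairs":
                kwargs["pair_ids"] = tuple(
                    p.strip() for p in value.split(";") if p.strip()
                )
            elif key == "lethal_cm":
                kwargs["lethal_cM"] = tuple(
                    float(x) for x in value.replace(",", " ").split()
                )
            elif key in ("n_scored", "seed", "k_each_side"):
                kwargs[key] = int(value)
            elif key == "confidence":
                kwargs[key] = float(value)
            elif key == "out_dir":
                kwargs[key] = value
            elif key == "tau":
                classify_kwargs["tau"] = float(value)
            elif key == "k0":
                classify_kwargs["k0"] = int(value)
            elif key == "min_informative":
                classify_kwargs["min_informative"] = int(value)
            else:
                raise ValidationError(f"unknown config key {key!r}")
        if classify_kwargs:
            kwargs["classify"] = ClassifyConfig(**classify_kwargs)
        return cls(**kwargs)

    def validate(self) -> None:
        for label, value in (("markers", self.markers),):
            if value != BUNDLED and not Path(value).exists():
                raise ValidationError(f"{label} path {value!r} does not exist")
        for label, value in (("refmap", self.refmap), ("kit", self.kit)):
            if value not in (BUNDLED, NONE) and not Path(value).exists():
                raise ValidationError(f"{label} path {value!r} does not exist")
        if self.counts is not None and not Path(self.counts).exists():
            raise ValidationError(f"counts path {self.counts!r} does not exist")
        if self.counts is None:
            if not self.lethal_cM:
                raise ValidationError(
                    "simulate mode needs lethal_cM (or provide a counts file)"
                )
            if self.seed is None:
                raise ValidationError("simulate mode needs a seed")


@dataclass(frozen=True)
class StageFailure:
    stage: str
    message: str


@dataclass
class PipelineOutcome:
    result: Optional[MappingResult]
    counts: list[ProgenyCounts]
    cyto: Optional[CytoPosition]
    cyto_extrapolated: bool
    plan: list[Deficiency]
    notices: list[str]
    failures: list[StageFailure]
    manifest: dict

    @property
    def ok(self) -> bool:
        return not self.failures


def _load_chromosome(config: PipelineConfig) -> ChromosomeMap:
    if config.markers == BUNDLED:
        chrom = fixtures.load_chr3_map()
        if tuple(config.pair_ids) != fixtures.CHR3_PAIR_IDS:
            chrom = dataclasses.replace(
                chrom,
                pairs=tuple(chrom.pair(pid) for pid in config.pair_ids),
            )
        return chrom
    return io.read_chromosome_map(config.markers, config.pair_ids)


def _obtain_counts(
    config: PipelineConfig, chromosome: ChromosomeMap
) -> list[ProgenyCounts]:
    if config.counts is not None:
        wanted = set(config.pair_ids)
        counts = [c for c in io.read_counts(config.counts) if c.pair_id in wanted]
        missing = wanted - {c.pair_id for c in counts}
        if missing:
            raise ValidationError(
                f"counts file lacks rows for pair(s): {', '.join(sorted(missing))}"
            )
        return counts
    out = []
    for i, pid in enumerate(config.pair_ids):
        design = CrossDesign(
            chromosome=chromosome,
            pair=chromosome.pair(pid),
            lethal_cM=config.lethal_cM,
        )
        rng = np.random.default_rng([int(config.seed), i])
        out.append(simulate_scored(design, config.n_scored, rng=rng))
    return out


def run_pipeline(config: PipelineConfig) -> PipelineOutcome:
    """Run classify -> estimate -> consensus -> convert -> plan.

    A stage error is recorded with its stage name and downstream stages are
    skipped; earlier results are still returned.  When ``out_dir`` is set,
    counts, result JSON, the deficiency plan, and a manifest (inputs with
    hashes, config, seed) are written there.
    """
    config.validate()
    notices: list[str] = []
    failures: list[StageFailure] = []
    manifest: dict = {
        "config": _config_dict(config),
        "seed": config.seed,
        "inputs": {},
    }
    for label in ("markers", "counts", "refmap", "kit"):
        value = getattr(config, label)
        if value not in (None, BUNDLED, NONE):
            manifest["inputs"][label] = {
                "path": str(value),
                "sha256": io.sha256_file(value),
            }

    result: Optional[MappingResult] = None
    counts: list[ProgenyCounts] = []
    cyto: Optional[CytoPosition] = None
    cyto_extrapolated = False
    plan: list[Deficiency] = []

    chromosome = _load_chromosome(config)
    try:
        counts = _obtain_counts(config, chromosome)
    except Exception as exc:
        failures.append(StageFailure("counts", str(exc)))
        counts = []

    if not failures:
        try:
            pairs_results: list[tuple[PairCall, Optional[PositionEstimate]]] = []
            for c in counts:
                call = classify_pair(c, config.classify)
                est = None
                if call.verdict == "inside":
                    est = estimate_within_pair(
                        c, chromosome.pair(c.pair_id), confidence=config.confidence
                    )
                pairs_results.append((call, est))
            result = consensus(pairs_results, chromosome)
        except Exception as exc:
            failures.append(StageFailure("estimate", str(exc)))

    if result is not None and not failures:
        if result.estimate is None:
            notices.append(
                f"conversion skipped: no point estimate (status {result.status})"
            )
        elif config.refmap == NONE:
            notices.append("conversion skipped: no reference map configured")
        else:
            try:
                refmap = (
                    fixtures.load_chr3_refmap()
                    if config.refmap == BUNDLED
                    else io.read_refmap(config.refmap)
                )
                import warnings as _warnings

                with _warnings.catch_warnings(record=True) as caught:
                    _warnings.simplefilter("always", ExtrapolationWarning)
                    cyto = cm_to_cyto(result.estimate.cM_point, refmap)
                    cyto_extrapolated = any(
                        issubclass(w.category, ExtrapolationWarning) for w in caught
                    )
            except Exception as exc:
                failures.append(StageFailure("convert", str(exc)))

    if cyto is not None and not failures:
        if config.kit == NONE:
            notices.append("planning skipped: no deficiency kit configured")
        else:
            try:
                kit = (
                    fixtures.load_table1_kit()
                    if config.kit == BUNDLED
                    else io.read_kit(config.kit)
                )
                plan = candidate_deficiencies(cyto, kit, config.k_each_side)
            except Exception as exc:
                failures.append(StageFailure("plan", str(exc)))

    outcome = PipelineOutcome(
        result=result,
        counts=counts,
        cyto=cyto,
        cyto_extrapolated=cyto_extrapolated,
        plan=plan,
        notices=notices,
        failures=failures,
        manifest=manifest,
    )
    if config.out_dir is not None:
        _write_outputs(config, outcome)
    return outcome


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["classify"] = dataclasses.asdict(config.classify)
    return d


def _write_outputs(config: PipelineConfig, outcome: PipelineOutcome) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if outcome.counts:
        io.write_counts(outcome.counts, out / "counts.tsv")
    result_obj = {
        "result": None if outcome.result is None else outcome.result.to_dict(),
        "cyto": None if outcome.cyto is None else str(outcome.cyto),
        "cyto_extrapolated": outcome.cyto_extrapolated,
        "plan": [d.name for d in outcome.plan],
        "notices": outcome.notices,
        "failures": [dataclasses.asdict(f) for f in outcome.failures],
    }
    io.write_json(result_obj, out / "result.json")
    manifest = dict(outcome.manifest)
    manifest["timestamp"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    io.write_json(manifest, out / "manifest.json")


# ---------------------------------------------------------------------------
# Synthetic truth-labelled scenarios


@dataclass(frozen=True)
class Scenario:
    """A simulator scenario with the outcome its geometry implies."""

    name: str
    lethal_cM: tuple[float, ...]
    pair_ids: tuple[str, ...]
    n_scored: int
    seed: int
    expected_status: str
    expected_pair_id: Optional[str] = None
    expected_region: Optional[str] = None
    note: str = ""


def generate_fixture_scenarios(seed: int) -> list[Scenario]:
    """Truth-labelled scenarios spanning the method's qualitative outcomes.

    Covers a lesion inside each of the four pairs, both terminal regions,
    the centromeric gap resolved by three-pair triangulation (skipping the
    Gl,Sb cross), and a doubly hit chromosome that defeats the method.
    Scenario n is 10^4 scored progeny per cross so the truth labels hold
    with high probability; at vial scale (~150) the same geometries are
    noisy, which is the method's real operating regime.

    Centromeric scenarios place the lesion at 52 cM: at 50 cM the R,D
    cross's expected unmarked fraction sits exactly on the inside/outside
    decision boundary and the gap call becomes a coin flip at any n.
    """
    four = fixtures.CHR3_PAIR_IDS
    three = ("R,D", "Sb,H", "H,Pr")
    n = 10_000
    base = [
        Scenario("inside_R_D", (20.0,), four, n, 0, "localized", "R,D"),
        Scenario("inside_Gl_Sb", (52.0,), four, n, 0, "localized", "Gl,Sb"),
        Scenario("inside_Sb_H", (64.0,), four, n, 0, "localized", "Sb,H"),
        Scenario("inside_H_Pr", (80.1,), four, n, 0, "localized", "H,Pr"),
        Scenario(
            "terminal_left", (0.5,), four, n, 0, "terminal_left",
            expected_region="left of R",
        ),
        Scenario(
            "terminal_right", (95.0,), four, n, 0, "terminal_right",
            expected_region="right of Pr",
        ),
        Scenario(
            "gap_skip_Gl_Sb", (52.0,), three, n, 0, "gap_region",
            expected_region="between D and Sb",
            note="three-pair triangulation of the centromeric region",
        ),
        Scenario(
            "two_lesions", (20.0, 85.0), four, n, 0, "inconsistent",
            note="multiple-lesion signature: two pairs call inside",
        ),
    ]
    return [
        dataclasses.replace(s, seed=int((seed * 1009 + i * 101) % 2**31))
        for i, s in enumerate(base)
    ]


def run_scenario(scenario: Scenario) -> PipelineOutcome:
    """Run the pipeline on a scenario (bundled markers, conversion and
    planning included for localized outcomes)."""
    config = PipelineConfig(
        pair_ids=scenario.pair_ids,
        lethal_cM=scenario.lethal_cM,
        n_scored=scenario.n_scored,
        seed=scenario.seed,
    )
    return run_pipeline(config)
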