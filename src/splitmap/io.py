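"""TSV / JSON / flat-config readers and writers for all table schemas.

All tables are tab-separated with a header row; lines starting with ``#``
are comments.  Optional counts are encoded as empty fields.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .core_types import (
    ChromosomeMap,
    Deficiency,
    GeneticMarker,
    MarkerPair,
    ProgenyCounts,
    ReferenceLocus,
    ValidationError,
    parse_cyto,
    parse_cyto_span,
)
from .deficiency_plan import DeficiencyKit, MappingRecord
from .map_convert import ReferenceMap

__all__ = [
    "read_markers",
    "build_chromosome_map",
    "read_chromosome_map",
    "read_counts",
    "write_counts",
    "read_refmap",
    "read_kit",
    "read_mapping_records",
    "read_config",
    "write_json",
    "sha256_file",
]

PathLike = Union[str, Path]


def _read_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def read_markers(path: PathLike) -> list[GeneticMarker]:
    """Read a marker table (columns: symbol, cM, optional cyto and
    phenotype_note)."""
    df = _read_tsv(path)
    markers = []
    for row in df.itertuples(index=False):
        cyto = getattr(row, "cyto", "")
        markers.append(
            GeneticMarker(
                symbol=row.symbol,
                cM=float(row.cM),
                cyto=parse_cyto(cyto) if cyto else None,
                phenotype_note=getattr(row, "phenotype_note", ""),
            )
        )
    return markers


def build_chromosome_map(
    markers: Sequence[GeneticMarker],
    pair_ids: Sequence[str],
    name: str = "3",
    length_cM: Optional[float] = None,
) -> ChromosomeMap:
    """Assemble a ChromosomeMap from markers and ``"A,B"`` pair labels."""
    by_symbol = {m.symbol: m for m in markers}
    pairs = []
    for pid in pair_ids:
        try:
            l_sym, r_sym = (s.strip() for s in pid.split(","))
        except ValueError as exc:
            raise ValidationError(f"pair id {pid!r} is not of the form 'A,B'") from exc
        for sym in (l_sym, r_sym):
            if sym not in by_symbol:
                raise ValidationError(f"pair {pid!r} references unknown marker {sym!r}")
        pairs.append(MarkerPair(left=by_symbol[l_sym], right=by_symbol[r_sym]))
    ordered = tuple(sorted(markers, key=lambda m: m.cM))
    if length_cM is None:
        length_cM = max(m.cM for m in ordered) + 20.0
    return ChromosomeMap(name=name, markers=ordered, pairs=tuple(pairs), length_cM=length_cM)


def read_chromosome_map(
    path: PathLike,
    pair_ids: Sequence[str],
    name: str = "3",
    length_cM: Optional[float] = None,
) -> ChromosomeMap:
    return build_chromosome_map(read_markers(path), pair_ids, name=name, length_cM=length_cM)


def read_counts(path: PathLike) -> list[ProgenyCounts]:
    """Read a progeny-count table (one row per pair cross)."""
    df = _read_tsv(path)
    out = []
    for row in df.itertuples(index=False):
        opt = lambda v: None if v == "" else int(v)
        out.append(
            ProgenyCounts(
                pair_id=row.pair_id,
                n_both=opt(getattr(row, "n_both", "")),
                n_lost_left=int(row.n_lost_left),
                n_lost_right=int(row.n_lost_right),
                n_unmarked=int(row.n_unmarked),
                n_balancer=opt(getattr(row, "n_balancer", "")),
            )
        )
    return out


def write_counts(counts: Sequence[ProgenyCounts], path: PathLike) -> None:
    rows = [
        {
            "pair_id": c.pair_id,
            "n_both": "" if c.n_both is None else c.n_both,
            "n_lost_left": c.n_lost_left,
            "n_lost_right": c.n_lost_right,
            "n_unmarked": c.n_unmarked,
            "n_balancer": "" if c.n_balancer is None else c.n_balancer,
        }
        for c in counts
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_refmap(path: PathLike, chromosome: str = "3") -> ReferenceMap:
    """Read a reference-locus table (columns: symbol, cM, cyto)."""
    df = _read_tsv(path)
    loci = tuple(
        ReferenceLocus(symbol=row.symbol, cM=float(row.cM), cyto=parse_cyto(row.cyto))
        for row in df.itertuples(index=False)
    )
    return ReferenceMap(loci=loci, chromosome=chromosome)


def read_kit(path: PathLike, name: str = "") -> DeficiencyKit:
    """Read a deficiency-kit table (columns: name, cyto_start, cyto_end)."""
    df = _read_tsv(path)
    defs = tuple(
        Deficiency(
            name=row.name,
            cyto_start=parse_cyto_span(row.cyto_start)[0],
            cyto_end=parse_cyto_span(row.cyto_end)[1],
        )
        for row in df.itertuples(index=False)
    )
    return DeficiencyKit(deficiencies=defs, name=name or str(path))


def read_mapping_records(path: PathLike) -> list[MappingRecord]:
    """Read a mapped-mutation table (columns: mutation, alleles, est_cM,
    est_cyto, df, actual_cyto)."""
    df = _read_tsv(path)
    return [
        MappingRecord(
            mutation=row.mutation,
            alleles=int(row.alleles),
            cm_label=row.est_cM,
            est_cyto=row.est_cyto,
            deficiency=row.df,
            actual_cyto=row.actual_cyto,
        )
        for row in df.itertuples(index=False)
    ]


def read_config(path: PathLike) -> dict[str, str]:
    """Read a flat ``key = value`` config file; ``#`` starts a comment."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValidationError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key] = value
    return out


def write_json(obj: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def sha256_file(path: PathLike) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
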