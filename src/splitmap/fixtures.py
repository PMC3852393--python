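"""Bundled data: the chromosome-3 dominant-marker set, a reference-locus
table for cM-cytology conversion, the published mapped-mutation table, and
the deficiency sub-kit derived from it.

Marker cM and cytology values are community-standard Drosophila map
constants (the standard genetic map does not ship with the mapping counts
themselves); the reference table is a clearly labelled substitute assembled
from classical loci and can be replaced by any user table in the same TSV
format.
"""

from __future__ import annotations

from importlib import resources

from .core_types import ChromosomeMap
from .deficiency_plan import DeficiencyKit, MappingRecord
from .map_convert import ReferenceMap

__all__ = [
    "CHR3_PAIR_IDS",
    "CHR3_LENGTH_CM",
    "load_chr3_map",
    "load_chr3_refmap",
    "load_table1_records",
    "load_table1_kit",
]

#: The four mapping pairs spanning chromosome 3: R,D on the left arm,
#: Gl,Sb across the centromere, Sb,H and H,Pr on the right arm.
CHR3_PAIR_IDS = ("R,D", "Gl,Sb", "Sb,H", "H,Pr")

#: Nominal genetic length of chromosome 3 (bounds marker/lesion positions).
CHR3_LENGTH_CM = 106.0

_DATA = resources.files("splitmap.data")


def _path(name: str):
    return resources.as_file(_DATA / name)


def load_chr3_map() -> ChromosomeMap:
    from .io import read_chromosome_map

    with _path("chr3_markers.tsv") as p:
        return read_chromosome_map(
            p, CHR3_PAIR_IDS, name="3", length_cM=CHR3_LENGTH_CM
        )


def load_chr3_refmap() -> ReferenceMap:
    from .io import read_refmap

    with _path("chr3_reference_map.tsv") as p:
        return read_refmap(p, chromosome="3")


def load_table1_records() -> list[MappingRecord]:
    from .io import read_mapping_records

    with _path("table1_psg.tsv") as p:
        return read_mapping_records(p)


def load_table1_kit() -> DeficiencyKit:
    from .io import read_kit

    with _path("dk3_table1_kit.tsv") as p:
        return read_kit(p, name="DK3 (mapped-mutation subset)")
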