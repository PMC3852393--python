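"""Complementation planning, distance-in-deficiencies, reliability arrows."""

import numpy as np
import pandas as pd
import pytest

import splitmap as sm
from splitmap.core_types import CytoPosition, Deficiency


LETTERS = "ABCDEF"


def random_kit(rng, n_min=3, n_max=12):
    n = int(rng.integers(n_min, n_max + 1))
    defs = []
    for i in range(n):
        start = float(rng.uniform(61, 99))
        end = start + float(rng.uniform(0.0, 2.0))
        b0, l0 = int(start), LETTERS[int((start % 1) * 6)]
        b1, l1 = int(min(end, 100.8)), LETTERS[int((min(end, 100.8) % 1) * 6)]
        if (b1, l1) < (b0, l0):
            b1, l1 = b0, l0
        defs.append(
            Deficiency(f"Df(r){i:02d}", CytoPosition(b0, l0), CytoPosition(b1, l1))
        )
    return sm.DeficiencyKit(deficiencies=tuple(defs), name="random")


def brute_force_plan(est, kit, k):
    """Independent oracle: greedy take-by-distance with per-side quotas."""
    e = est.linear
    containing = sorted(
        (d for d in kit if d.cyto_start.linear <= e <= d.cyto_end.linear),
        key=lambda d: (abs(d.center - e), d.name),
    )
    rest = sorted(
        (d for d in kit if d not in set(containing)),
        key=lambda d: (abs(d.center - e), d.name),
    )
    quotas = {"left": k, "right": k}
    picked = []
    for d in rest:
        side = "left" if d.center < e else "right"
        if quotas[side] > 0:
            quotas[side] -= 1
            picked.append(d)
    return containing + picked


class TestCandidateDeficiencies:
    def test_toy_tiled_ordering(self):
        kit = sm.make_tiled_kit(7)
        est = CytoPosition(64, "C", 15)  # center of tile 4 (bands 61..67)
        got = [d.name for d in sm.candidate_deficiencies(est, kit, 2)]
        assert got == ["Df(syn)T04", "Df(syn)T03", "Df(syn)T05", "Df(syn)T02", "Df(syn)T06"]

    def test_containing_ranked_first(self):
        kit = sm.make_tiled_kit(5)
        est = sm.parse_cyto("63B")
        got = sm.candidate_deficiencies(est, kit, 1)
        assert got[0].name == "Df(syn)T03"

    def test_zero_k_without_containment_is_empty(self):
        kit = sm.make_tiled_kit(3)
        est = sm.parse_cyto("70A")  # beyond the tiles
        assert sm.candidate_deficiencies(est, kit, 0) == []

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            sm.candidate_deficiencies(sm.parse_cyto("63B"), sm.make_tiled_kit(3), -1)

    def test_matches_brute_force_on_random_kits(self):
        rng = np.random.default_rng(424242)
        for _ in range(100):
            kit = random_kit(rng)
            est = CytoPosition(int(rng.integers(61, 100)), LETTERS[rng.integers(0, 6)])
            k = int(rng.integers(0, 5))
            got = sm.candidate_deficiencies(est, kit, k)
            assert [d.name for d in got] == [d.name for d in brute_force_plan(est, kit, k)]


def reflect(pos_linear):
    # letter-grid reflection: band b, letter index i -> band 161-b, index 5-i
    return 161 + 5 / 6 - pos_linear


def reflect_cyto(pos):
    return CytoPosition(161 - pos.band, LETTERS[5 - pos.letter_index])


def reflect_kit(kit):
    return sm.DeficiencyKit(
        deficiencies=tuple(
            Deficiency(d.name, reflect_cyto(d.cyto_end), reflect_cyto(d.cyto_start))
            for d in kit
        ),
        name="mirror",
    )


class TestDeficienciesAway:
    def test_containing_hit_is_zero(self):
        kit = sm.make_tiled_kit(7)
        est = sm.parse_cyto("64C")
        hit = kit.deficiencies[3]
        assert sm.deficiencies_away(est, hit, kit) == 0

    def test_toy_tiled_one_between(self):
        kit = sm.make_tiled_kit(7)
        est = sm.parse_cyto("64C")  # tile 4
        hit = kit.deficiencies[5]  # tile 6
        assert sm.deficiencies_away(est, hit, kit) == 1

    def test_psg24_style_topology(self):
        # estimate at 95A, hit at 94E, one kit deficiency wholly between
        kit = sm.DeficiencyKit(
            deficiencies=(
                Deficiency("Df(t)hit", sm.parse_cyto("94D"), sm.parse_cyto("94E")),
                Deficiency("Df(t)mid", sm.parse_cyto("94F"), sm.parse_cyto("94F")),
                Deficiency("Df(t)far", sm.parse_cyto("95C"), sm.parse_cyto("95D")),
            ),
            name="toy",
        )
        est = sm.parse_cyto("95A")
        hit = kit.deficiencies[0]
        assert hit.name == "Df(t)hit"
        assert sm.deficiencies_away(est, hit, kit) == 1

    def test_hit_not_in_kit_rejected(self):
        kit = sm.make_tiled_kit(3)
        rogue = Deficiency("Df(x)", sm.parse_cyto("61A"), sm.parse_cyto("61B"))
        with pytest.raises(ValueError):
            sm.deficiencies_away(sm.parse_cyto("61A"), rogue, kit)

    def test_reflection_symmetry(self):
        rng = np.random.default_rng(777)
        for _ in range(50):
            kit = random_kit(rng)
            est = CytoPosition(int(rng.integers(61, 100)), LETTERS[rng.integers(0, 6)])
            hit = kit.deficiencies[rng.integers(0, len(kit))]
            forward = sm.deficiencies_away(est, hit, kit)
            mirrored_kit = reflect_kit(kit)
            mirrored_hit = next(d for d in mirrored_kit if d.name == hit.name)
            backward = sm.deficiencies_away(reflect_cyto(est), mirrored_hit, mirrored_kit)
            assert forward == backward


class TestReliabilityReport:
    def test_bundled_table_has_28_arrows(self, table1_records):
        rep = sm.reliability_report(table1_records)
        assert rep.summary["n_records"] == 28
        assert not rep.errors

    def test_printed_cytology_pairs_unchanged(self, table1_records):
        rep = sm.reliability_report(table1_records)
        assert list(rep.table["est_cyto"]) == [r.est_cyto for r in table1_records]
        assert list(rep.table["actual_cyto"]) == [r.actual_cyto for r in table1_records]

    def test_worked_example_arrow_length(self, table1_records):
        # estimated 95A, actual 94E: two lettered divisions on the linear scale
        rep = sm.reliability_report(table1_records)
        row = rep.table[rep.table["mutation"] == "psg24"].iloc[0]
        assert row["arrow_length"] == pytest.approx(2 / 6)

    def test_terminal_records_counted(self, table1_records):
        rep = sm.reliability_report(table1_records)
        assert rep.summary["n_terminal"] == 4

    def test_zero_length_arrow(self, table1_records):
        rep = sm.reliability_report(table1_records)
        row = rep.table[rep.table["mutation"] == "psg17"].iloc[0]
        assert row["arrow_length"] == 0.0

    def test_malformed_record_listed_and_skipped(self, table1_records):
        bad = sm.MappingRecord(
            mutation="broken", alleles=1, cm_label="12",
            est_cyto="12Z", deficiency="Df(x)", actual_cyto="61A",
        )
        rep = sm.reliability_report(list(table1_records) + [bad])
        assert rep.summary["n_records"] == 28
        assert any("broken" in e for e in rep.errors)

    def test_refmap_cross_check_column(self, table1_records, refmap):
        rep = sm.reliability_report(table1_records, refmap=refmap)
        assert "refmap_cyto" in rep.table.columns


class TestComplementationLedger:
    def test_one_outcome_per_pair(self):
        ledger = sm.ComplementationLedger()
        ledger.record("psg24", "Df(3R)BSC619", "untested")
        ledger.record("psg24", "Df(3R)BSC619", "fails_to_complement")
        assert len(ledger.records) == 1
        assert ledger.outcome("psg24", "Df(3R)BSC619") == "fails_to_complement"
        assert ledger.hits("psg24") == ["Df(3R)BSC619"]

    def test_unknown_outcome_rejected(self):
        with pytest.raises(sm.ValidationError):
            sm.ComplementationLedger().record("m", "d", "maybe")

    def test_frame_round_trip(self):
        ledger = sm.ComplementationLedger()
        ledger.record("m1", "d1", "complements")
        df = ledger.to_frame()
        assert list(df.columns) == ["mutation", "deficiency", "outcome"]
        assert len(df) == 1
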