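"""Plan complementation tests around an estimated position.

Given the ~95A estimate from the worked example, rank the bundled
deficiency kit for testing: deficiencies containing the estimate first,
then alternating outward, a few on each side.
"""

import splitmap as sm

kit = sm.fixtures.load_table1_kit()
estimate = sm.parse_cyto("95A")

plan = sm.candidate_deficiencies(estimate, kit, k_each_side=5)
print(f"test order around {estimate} ({len(plan)} stocks):")
for i, d in enumerate(plan, 1):
    print(f"  {i:2d}. {d.name:18s} {d.cyto_start}-{d.cyto_end}")

ledger = sm.ComplementationLedger()
for d in plan:
    ledger.record("psg-demo", d.name, "complements")
hit = next(d for d in kit if d.name == "Df(3R)BSC619")
ledger.record("psg-demo", hit.name, "fails_to_complement")
print(f"\nrecorded hit: {ledger.hits('psg-demo')}")

away = sm.deficiencies_away(estimate, hit, kit)
print(
    f"estimate-to-hit distance: {away} kit deficiency(ies) in between — the "
    f"practical\nmeasure of how much extra crossing the estimate cost."
)
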