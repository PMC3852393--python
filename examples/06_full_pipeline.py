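"""End-to-end run: simulate the six-cross protocol and recover the lesion.

Three pairs (R,D / Sb,H / H,Pr — the centromeric Gl,Sb cross can be
skipped) are simulated for a lesion at 80.1 cM, classified, combined into
a consensus, converted to cytology, and turned into a complementation
plan.
"""

import splitmap as sm

config = sm.PipelineConfig(
    pair_ids=("R,D", "Sb,H", "H,Pr"),
    lethal_cM=(80.1,),
    n_scored=10_000,
    seed=17,
)
outcome = sm.run_pipeline(config)

print("per-pair calls:")
for call in outcome.result.pair_calls:
    print(f"  {call.pair_id:6s} {call.verdict:14s} "
          f"(unmarked fraction {call.unmarked_fraction:.3f})")

est = outcome.result.estimate
print(f"\nconsensus: {outcome.result.status} in {est.pair_id} at "
      f"{est.cM_point} cM (CI {est.cM_low:.1f}-{est.cM_high:.1f})")
print(f"cytology: ~{outcome.cyto}")
print("complementation plan (first five):")
for d in outcome.plan[:5]:
    print(f"  {d.name}")
print(
    "\nThe simulated truth was 80.1 cM; the split-ratio consensus recovers "
    "it to within\na fraction of a cM and the plan starts at the "
    "deficiencies nearest the converted band."
)
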