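"""Convert between genetic (cM) and cytological (band) coordinates.

The two scales are not linearly related (the centromere suppresses
recombination), so conversion interpolates between reference loci with
known positions on both scales.
"""

import warnings

import splitmap as sm

refmap = sm.fixtures.load_chr3_refmap()
print("reference loci (symbol, cM, cytology):")
for locus in refmap.loci:
    print(f"  {locus.symbol:8s} {locus.cM:6.1f}  {locus.cyto}")

for cm in (30.0, 48.0, 80.1):
    print(f"\n{cm} cM -> {sm.cm_to_cyto(cm, refmap)}")

pos = sm.parse_cyto("94E")
print(f"94E -> {sm.cyto_to_cm(pos, refmap):.1f} cM")

with warnings.catch_warnings(record=True) as caught:
    warnings.simplefilter("always")
    clamped = sm.cm_to_cyto(105.0, refmap)
print(
    f"\n105 cM is beyond the last reference locus: clamped to {clamped} "
    f"({len(caught)} extrapolation warning)"
)
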