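# Methods

## Model of the mapping cross

The simulator (`meiosis_sim`) models the two-generation scheme explicitly:

1. **Maternal meiosis.** The F1 female is heterozygous for the doubly
   marked chromosome over the mutagenized chromosome. Tracked loci are the
   two markers of the pair and every lethal lesion. Under the default
   `haldane_independent` model each interval between consecutive tracked
   loci recombines independently with probability
   `r(d) = (1 − e^(−2d/100))/2` (`d` in cM) — the Haldane map function,
   i.e. crossovers without interference. The gamete's initial origin is
   equiprobable and flips at each recombinant interval.
2. **Paternal draw.** The backcross father transmits the balancer with
   probability `paternal_balancer_fraction` (default 0.5), otherwise the
   mutant chromosome. The balancer is modelled as fully
   recombination-suppressed and always scorable; transmission distortion
   can be emulated by changing the fraction.
3. **Viability selection.** Non-balancer progeny die when the maternal
   gamete carries any lethal allele. Balancer progeny are tallied and
   excluded from marker scoring, matching bench practice.
4. **Scoring.** Survivors are classified as both / lost-left / lost-right
   / unmarked by dominant-marker presence. An optional per-marker
   mis-scoring rate (default 0) flips observed phenotypes.

`expected_class_frequencies` enumerates initial origin × all interval
recombination patterns exactly and conditions on lethal-free gametes; for
one lesion strictly inside the pair it reduces to the product weights
`both=(1−r1)(1−r2)`, `lost_left=r1(1−r2)`, `lost_right=(1−r1)r2`,
`unmarked=r1·r2` (normalized). This closed form is the oracle for the
Monte-Carlo tests and for every scenario-design calculation below.

A `gamma_interference(shape)` crossover model (stationary gamma-renewal
chiasma process, 1/2 thinning, mean interarrival 0.5 Morgan) is available
for sensitivity runs; it has no closed form here and is excluded from
oracle checks. Randomness uses numpy's PCG64; identical seeds give
bit-identical counts.

## Estimator

`classify_pair` calls a cross *inside* when the unmarked class is absent
or rare: at most `k0` unmarked progeny (default 1) **or** an unmarked
fraction `u = unmarked/(unmarked + splits)` below `tau`. Both are
configurable; `min_informative` (default 10) progeny are required before
any verdict, otherwise the call is *ambiguous* with an explanatory note
rather than an exception.

**Choice of `tau` = 0.15.** The field description of the rule is
qualitative ("absent or rare"), so the threshold is set from the
closed-form class frequencies of the actual marker geometry: with a lesion
mid-pair, `u` at expectation is ≈0.005–0.05 for the ~11–20 cM pairs and
≈0.09 for the ~40 cM R,D pair, while a lesion even 5 cM outside a pair
gives `u` ≥ 0.19. 0.15 sits between the widest-pair inside value and the
just-outside value, and keeps the vial-scale (150 scored progeny) inside
call rate for a mid-H,Pr lesion at ≈0.98. A stricter threshold (e.g.
0.05) would misclassify a large fraction of genuinely inside vials purely
through Poisson noise in 1–2 unmarked flies.

`estimate_within_pair` maps the lost-left fraction of the splits linearly
onto the cM interval — deliberately without a map-function correction,
because the linear arithmetic *is* the method (`69.5 + 14/27·20.5 = 80.1`)
and its residual bias is part of what the reliability report measures.
Closed-form analysis shows the bias is small for ~20 cM pairs (the
expected estimate for a lesion at 80.13 cM is 80.127 cM). The interval is
a two-sided Wilson score interval (no continuity correction; computed via
statsmodels) on the split fraction, mapped through the same transform and
clipped to the pair; Wilson is used for its small-count stability. The
point estimate is reported at one decimal, the method's working precision.
Which split class of a printed "13:14" ratio lost the left marker is fixed
by back-computation against the 80.1 result: lost-left = 14.

Direction for *outside* calls is the majority split class (more lost-left
⇒ lesion right of the pair); raw counts are used, with an optional
per-pair two-sided binomial gate (`require_significant_direction`,
unadjusted across pairs — calls are mechanistic, not hypothesis tests).

`consensus` combines pairs: one corroborated inside call localizes; only
outward directions give a terminal call; directions bracketing an
uncovered inter-pair interval give a gap call naming the flanking markers
(this is what lets the centromeric Gl,Sb cross be skipped — the other
three pairs triangulate lesions between D and Sb); two inside calls or
crossing directions are flagged inconsistent, the signature of multiply
hit chromosomes. Corroboration compares each outside direction against
the inside estimate's confidence interval, so sampling noise at a shared
marker does not raise spurious conflicts.

**Terminal edge rule.** A lesion left of the leftmost marker R can never
make the R,D cross's unmarked class common: the lesion–R interval is at
most 1.4 cM, so the unmarked class (which requires a crossover there)
stays rare and the cross always looks "inside" with the estimate pinned at
the left edge. A lesion at R ± ε is therefore unidentifiable from that
cross alone. Consensus handles this honestly: a lone inside call on the
first (last) pair whose interval estimate reaches within `edge_margin_cM`
(default 2.0) of the terminal marker, with every other pair pointing
further out, is reported as `terminal_left` (`terminal_right`). The cost
is that lesions genuinely inside but within ~2 cM of a terminal marker are
also reported terminal — at vial scale the data cannot distinguish them.

## Coordinates and conversion

Cytological positions are band / letter / optional subdivision (e.g.
`94E7`), linearized as `band + letter_index/6 + (subdivision−1)/(6·30)`;
a missing subdivision linearizes to the start of its lettered division
(the bundled tables report letter-level resolution). Band ranges are
per-chromosome configuration (chr3: 61–100, chr2: 21–60), so the method
generalizes to the second chromosome. Compact spans ("66CD", "67BD") parse
to (start, end) pairs and linearize at their midpoint.

`map_convert` interpolates piecewise-linearly between reference loci,
strictly co-monotone in cM and cytology (violations rejected at load);
queries outside the table clamp to the nearest terminal locus with an
`ExtrapolationWarning`. Output floors to the lettered division: finer
resolution is not claimed. The bundled 13-locus reference table is a
**substitute** assembled from community-standard positions of classical
loci (ru, h, D, st, p, cu, Sb, sr, gl, e, E(spl), ro, ca); with it,
80.1 cM converts to 95B, within one lettered division of 95A. Users can
supply their own table in the same TSV format; conversion fidelity is
bounded by the local density of reference loci.

## Deficiency planning and reliability

`candidate_deficiencies` ranks a kit around an estimate: containing
deficiencies first, then alternating outward by center distance, up to
`k_each_side` per side (default 5), ties broken by (distance, name).
`deficiencies_away` counts kit stocks whose whole interval lies in the
closed gap between the estimate and the hit's nearest edge (excluding the
hit and anything containing the estimate) — partial overlaps do not count.
The closed-gap convention makes abutting tiled kits count interior tiles
as expected. `reliability_report` turns a mapped-mutation table into
plot-ready arrows (base = estimated cytology, head = actual), with
per-arm mean lengths (arm split at band 80) and terminal-record counts;
malformed rows are listed and skipped, not fatal.

## Synthetic scenarios: what they do and do not show

`generate_fixture_scenarios` emits eight truth-labelled scenarios: a
lesion inside each of the four pairs, both terminal regions, the
centromeric gap triangulated by three pairs, and a doubly hit chromosome
(lesions at 20 and 85 cM) that produces two inside calls and an
`inconsistent` flag. Scenario size is 10^4 scored progeny per cross so
the labels hold with high probability; the same geometries at vial scale
(~150) are noisy — that is the method's real operating regime, and the
vial-scale tests quantify it separately. The default simulated vial is
150 scored progeny: cross-level totals are not standardized anywhere
authoritative, so this is a package choice, configurable per run.

The centromeric scenarios place the lesion at 52 cM. At 50 cM the R,D
cross's expected `u` is 0.1498 — numerically on the 0.15 decision
boundary — so the inside/outside call there is a coin flip at any sample
size. That is a genuine identifiability limit of the design near the
centromere, not a software artifact; 52 cM is ≥4σ from the boundary at
the scenario's n.

The simulator emulates: Haldane crossovers, viability selection, balancer
exclusion, transmission distortion, mis-scoring. It does **not** emulate
crossover interference by default, viability differences among marker
classes, maternal-age or temperature effects on recombination, or
centromeric recombination suppression beyond what the marker spacing
itself encodes. Passing tests therefore show the estimator is faithful to
its own genetic model, not that real crosses achieve the same error rates.

## Known limitations

- **Wide pairs.** For the ~40 cM R,D pair, a mid-pair lesion's unmarked
  class is no longer rare (`u` ≈ 0.09 at expectation), and the vial-scale
  inside-call rate drops to ≈0.89 — no threshold separates it cleanly from
  a lesion a couple of cM outside a pair. This is the left arm's price for
  marker spacing; the property tests assert ≥0.925 (among decided calls)
  for the ≤20 cM pairs and ≥0.80 for R,D.
- **Near-marker lesions.** Within ~2 cM of a marker, inside vs. outside is
  effectively unidentifiable at vial scale (see the terminal edge rule).
- **Linear split-ratio estimate.** The estimate is biased toward the pair
  interior for lesions outside or at the edges of a pair; only the
  consensus across pairs corrects for it.
- The X-chromosome male-scoring variant, multi-generation pedigrees, male
  recombination, and base-pair coordinates are out of scope; positions are
  cM and cytology only.
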