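# splitmap

Recombination mapping with **pairs of dominant visible markers** in
*Drosophila melanogaster*: a toolkit for the two-generation mapping
strategy in which a recessive lethal mutation is localized on a chromosome
from the ratio of viable F2 recombinants that lost one of two dominant
markers, and the resulting estimate is turned into a short deficiency
complementation-test plan.

It is written for fly geneticists running (or teaching) forward genetic
screens, and for anyone who wants to simulate and study the statistical
behaviour of this mapping design before committing vials to it.

## The method

An F1 female heterozygous for a doubly marked chromosome (markers *A*, *B*
at map positions `L < R` cM) over a mutagenized chromosome carrying a
recessive lethal `m` is backcrossed to `m / Balancer` males. Balancer
progeny are set aside; non-balancer progeny survive only if the maternal
gamete is free of `m`. Among the surviving progeny, the informative
classes are the recombinants:

- **splits** — progeny that lost exactly one marker (single crossover
  between that marker and `m`);
- **unmarked** — progeny that lost both markers: a *double* crossover if
  `m` is inside the pair (rare), a *single* crossover if outside (common).

Decision rule: if unmarked progeny are absent or rare, `m` is inside the
pair and the split ratio places it linearly between the markers,

```
f = n_lost_left / (n_lost_left + n_lost_right)
position = L + f · (R − L)
```

with a Wilson score interval on `f` mapped through the same transform. If
unmarked progeny are common, `m` is outside and the majority split class
gives the direction. Three or four pairs span the chromosome, so exactly
one cross should call "inside"; the other crosses corroborate it.

The cM estimate is converted to a polytene-band (cytological) position by
piecewise-linear interpolation over reference loci with known positions on
both scales, and nearby deficiencies are ranked for complementation
testing.

## Worked example

```python
import splitmap as sm

chromosome = sm.fixtures.load_chr3_map()          # R, D, Gl, Sb, H, Pr
counts = sm.ProgenyCounts(pair_id="H,Pr", n_lost_left=14,
                          n_lost_right=13, n_unmarked=0)

sm.classify_pair(counts).verdict                  # 'inside'
est = sm.estimate_within_pair(counts, chromosome.pair("H,Pr"))
est.cM_point                                      # 80.1
sm.cm_to_cyto(est.cM_point, sm.fixtures.load_chr3_refmap())  # 95B
```

A cross of the H,Pr pair (69.5–90.0 cM) produced 14 progeny that lost H,
13 that lost Pr, and none that lost both: the lesion is inside the pair,
14/27 of the way from H, i.e. `69.5 + 14/27 · 20.5 = 80.1` cM, which the
bundled reference map converts to around band 95A/95B. Ranking the bundled
deficiency kit around that band puts `Df(3R)BSC619` (94E) first in the
test order.

The `examples/` directory has one short script per capability — cross
simulation against the closed-form class probabilities, the worked example
above, coordinate conversion, complementation planning, the
reliability-arrow report over the bundled table of 28 mapped mutations,
and the full simulate→estimate→convert→plan pipeline. Each prints the
numbers it computes and a line on what they mean.

A thin CLI mirrors the pipeline stages:

```sh
splitmap simulate --pair H,Pr --lethal-cm 80.1 --n-scored 500 --seed 17 --out counts.tsv
splitmap estimate --counts counts.tsv
splitmap convert --cm 80.1
splitmap plan --cyto 95A -k 5
splitmap report --out arrows.tsv
splitmap run --config run.cfg
```

## Bundled data

All bundled tables are plain TSV under `src/splitmap/data/`: the six
chromosome-3 dominant markers with community-standard map positions, a
clearly labelled substitute reference-locus table for cM↔cytology
interpolation (13 classical loci), the 28-row mapped-mutation table, and
the 24 deficiencies it names. Marker and reference-locus coordinates are
external map constants, not measurements made by this package; see
`docs/methods.md`.

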