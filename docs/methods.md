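# Methods

## The index

The unit of analysis is the **lake-country unit**: the portion of a lake
lying within one country, with its own surface area. Working at national
scope reflects how conservation is funded and enforced; a lake shared by
several countries is scored once per riparian state.

For a unit in a country with `Wt` assessed lakes (lakes that survived the
cleaning pipeline — not all lakes known to exist in the country), each
species found in `Ws` of them has relative rarity `SRR = 1 − Ws/Wt`, and
the unit's rarity is the plain sum `RRw = Σ SRR` over its **distinct**
species. Distinctness matters: the index scores species sets, not record
counts, so duplicate sightings are collapsed when units are built and raw
counts survive only in the filter audit.

Each species carries a Red List category with weight
`ET = 7, EXw = 6, CR = DD = NE = 5, EN = 4, VU = 3, NT = 2, LC = 1`.
Putting data-deficient and not-evaluated species at the critically
endangered weight is a deliberate precautionary stance — a species whose
status is unknown should not be treated as safe — and for the same reason
species missing from the status table default to NE instead of raising an
error. The weight vector is configurable; these values ship as defaults.
The unit's conservation score is `Cwt = Σ counts × weights`, an integer
between its richness and 7 × richness.

The index is the lake-level product

```
CPI = (Cwt × RRw) / (Aw × k)
```

with `Aw` the unit's area in km² and `k` a positive scaling constant,
default 8 (the number of distinct weight levels among the nine categories:
DD, NE and CR share one). Area enters as a penalty: a proxy for the cost
of conserving the site and for the ecological substitutability available
to species in large systems. CPI is zero exactly when `RRw` is zero — in
particular for the only assessed lake of a country, where no
within-country comparison is possible. Doubling `k` halves every CPI and
never reorders units, so `k` only sets the scale of the classification
threshold.

Classification is strict: high priority iff `CPI > 0.5`. A value exactly
at the threshold is low, because the high class is defined by a strict
inequality and the boundary must land somewhere deterministic. League
tables order by descending CPI with ties broken by descending `Cwt`, then
ascending area, then lake name, so ranking is fully deterministic.

## The cleaning pipeline

Occurrence tables are filtered in five ordered, audited stages:
(1) names without a resolvable specific epithet (`sp.`/`spp.` or a bare
genus) are dropped; (2) records with no waterbody are kept only if an
optional user-supplied point-in-lake lookup resolves their coordinates or
a registry lake name occurs in their locality/habitat text (longest match
wins, ties lexicographic); (3) waterbody names are harmonized to canonical
English names through the registry's synonym map, matched
case-insensitively with accent folding; (4) records whose waterbody is not
in the registry are dropped (no determinable area); (5) records whose
country is not among the lake's registered countries are dropped.
Expert reassignments of individual records (record id → corrected lake)
are applied *before* filtering from a user-supplied override table;
automating such corrections would require range knowledge the data does
not carry. Each stage emits a report, and the identity
`Σ drops + survivors = input` is asserted throughout the tests. Filtering
is idempotent: re-running on survivors changes nothing.

## Statistics

*Correlations.* Pairwise Pearson `r` with `df = n − 2` and two-sided
p-values over richness, `Cwt`, `RRw` and area; constant columns yield NaN
rather than an error.

*Priority-class comparison.* The two classes are independent groups of
unequal size, so the unpaired Mann–Whitney rank-sum test is used. `W` is
the U statistic of the first (low) group. The p-value comes from the
tie-corrected normal approximation with continuity correction, except
that small problems (`n1 + n2 ≤ 12`) are evaluated by exact enumeration
of all `C(n, n1)` group assignments (two-sided by distance of U from its
null mean). The effect size is `r = |z|/√(n1+n2)` with `z` the
tie-corrected standardized statistic *without* continuity correction: the
effect size measures the statistic's displacement, not a tail-area
approximation. The exact path keeps the normal approximation honest: at
group sizes below about 5 the normal p can differ from the exact p by
more than 0.02, which is why enumeration is automatic there.

*Accumulation curve.* Sites are added in random order (default 100
permutations, seeded) and the mean ± sd cumulative distinct-species count
is reported; the final point always equals total richness.

## Classifiers

Features are `area_km2`, `Cwt`, `RRw` plus one-hot country indicators in
sorted order (countries are included to absorb national differences in
assessment effort and species composition). Splits are 70/30 and
stratified by class — with an imbalanced class mix an unstratified test
set can end up single-class, leaving recall or specificity undefined.

The random forest (500 trees by default) tunes its features-per-split by
an out-of-bag search from `⌊√p⌋`, multiplying/dividing by a step factor
of 2 and continuing in a direction while OOB error improves by at least
5%. Its importances are the classic pair: mean decrease in Gini
(impurity) and mean decrease in accuracy, the latter computed by
out-of-bag permutation — for every tree, accuracy on its out-of-bag rows
is compared with accuracy after permuting one feature, and decreases are
averaged over trees. In-bag rows are reconstructed from each tree's
bootstrap seed.

The gradient-boosted model (100 rounds by default) is trained with a
soft-probability multiclass objective and multiclass log-loss — with two
classes this is mathematically binary log-loss, but the soft-probability
setup is kept so the machinery generalizes to more than two priority
classes unchanged. Its importance is per-feature gain normalized to sum
to 1.

Metrics (accuracy, recall, specificity, precision, F1) are computed from
the confusion matrix with **high priority as the positive class** — the
class one acts on. One-class test sets yield NaN for the undefined
metrics with a warning rather than an exception. Partial dependence
clamps one feature across a quantile grid and averages the predicted
high-class probability over the evaluation rows.

## Synthetic data

The generator emulates the statistical structure the index assumes, not
any particular geography: per country, a uniform number of lakes (4–12)
with log-normal areas (μ = 4.0, σ = 1.5 on the log scale, i.e. a median
around 55 km² and a heavy right tail — the size structure of continental
lake registries, where typical class-median areas are of order 1–100
km²); per-lake target richness `c·area^z` with z = 0.3 and log-normal
noise (σ = 0.2), the canonical species–area range; a configurable share
of single-lake endemics (default 0.3) with the remaining species placed
in random multi-lake subsets of their country; and a least-concern-
dominated category mix (≈ 67% LC, with NE and DD the next largest shares
and extinct categories at a few per mille). No species crosses a border,
matching the country-scoped rarity definition.

What it does **not** emulate: spatial lake geometry (coordinates are
decorative), temporal sampling effort, taxonomic uncertainty beyond the
injected `spp.` corruption, or cross-border species — so passing tests
demonstrate the correctness and stability of the computation, not that
any particular real region would yield a particular ranking.

`inject_noise` appends corrupted copies of sampled rows (epithet
truncation to `"Genus spp."`; blanked waterbody/coordinates/locality)
rather than editing rows in place, so the cleaning pipeline can be
asserted to remove *exactly* the injected corruption and return the clean
record set.

The hand fixture (`worked_fixture`) pins the arithmetic end to end:
RRw = 0.5/1.0, Cwt = 6/14, CPI = 0.0375/0.875, classes low/high.

## Numerical and design notes

- All randomness flows from one root seed via `numpy.random.SeedSequence`
  spawning; child seeds stay below 2³¹ so they are valid everywhere.
- Exact-equality assertions (oracle tests) are legitimate because the
  pipeline and the brute-force oracle perform the same real-arithmetic
  operations in the same order on the same inputs; no tolerance is
  hidden behind them.
- Units with missing or nonpositive area are excluded from the index with
  a logged warning, mirroring the upstream discard of lakes whose area
  cannot be determined.
- Validation suites run at deliberately modest problem sizes (tens of
  lakes, a few hundred units, 20 seeded model repeats of ~240 units with
  100-tree forests) — large enough for the recovery properties to be
  stable across seeds, small enough to keep the whole suite fast.

## Known limitations

- Rarity is occupancy-based; abundance and range size within a lake are
  invisible to the index.
- Rivers and other linear habitats are out of scope: damming partitions
  them into distinct ecosystems that would need section-wise treatment.
- The index inherits every bias of the occurrence data: unsampled lakes
  inflate the rarity of species in sampled ones, and `Wt` counts only
  assessed lakes.
- Equal-interval category weights are an assumption, not a measurement;
  the weight vector is exposed precisely because reasonable alternatives
  exist.
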