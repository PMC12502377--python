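# Methods

## Data model and name standardization

The unit of analysis is the *formulary*: all formulations of one
medical system. Each formulation holds a **set** of standardized herb
species — a species listed twice in one recipe (different plant parts
or preparations) counts once, because every statistic downstream is a
formulation-level proportion. Processing methods, dosages and symptom
texts are carried as opaque metadata and never analysed.

Raw ingredient names resolve through two tables: a taxonomy table of
accepted species binomials with ranked lineages (kingdom → genus), and
a synonym table mapping raw spellings onto accepted names. Matching is
case-insensitive and whitespace-normalized; there is **no fuzzy
matching** — reproducibility from the two tables is preferred over
recall, and a curator extends the synonym table rather than trusting a
string-distance guess. Unresolved names are a data state, not an
error; the default policy drops them with a logged count, an
alternative policy keeps them as lineage-less species excluded from
rank rollups.

Non-botanical ingredients (animal products such as honey, minerals)
are excluded by a kingdom whitelist (default Plantae + Algae).
Medicinal fungi are a genuine bookkeeping wrinkle: formularies
described as plant-based sometimes carry a fungus under a plant-style
binomial (*Wolfiporia cocos*). They are excluded by default and can be
admitted by an explicit flag; every admitted fungal species is surfaced
in the ingestion log so the inconsistency is visible rather than
silently normalized away.

Rank rollup maps each herb to its ancestor at a requested rank and
deduplicates per formulation. A species with no value at the requested
rank aborts the rollup with the offending species named: rank-level
statistics must not silently shrink their universe.

## Overlap statistics

Directional overlap is $100\,|A\cap B|/|A|$ — deliberately asymmetric,
matching statements of the form "X% of system A's herbs are also used
by system B". Jaccard is reported alongside as the symmetric
companion. The **multiway shared fraction** across ≥2 systems is
defined here as intersection over union; since "shared" percentages in
the literature often leave the denominator unstated, the raw
intersection and union counts are always emitted so any alternative
denominator can be recomputed. Venn region counts classify every taxon
by the exact subset of systems using it and partition the union (a
tested invariant).

## Pair statistics and dependency mining

Pair support is the fraction of formulations containing both herbs of
an unordered pair; the co-occurrence score of $a$ on $b$ is
$P(b\,|\,a)$ in count arithmetic, i.e. the confidence of the directed
rule $a\to b$. Bayes consistency
($\mathrm{conf}(a\to b)\,|F_a| = \mathrm{conf}(b\to a)\,|F_b| = |F_a\cap F_b|$)
holds exactly and is property-tested. The score matrix (heatmap input)
conditions on the row herb; its diagonal is 1 by convention.

Mining emits every directed rule with pair support **strictly above**
`min_support` (default 0.05 — "exceeding 5%") and confidence **at or
above** `min_conf` (default 0.8). The confidence comparison is
inclusive by default with a strictness flag, because published
example rules all have confidence 1 and satisfy either reading; both
behaviours are config-exposed and oracle-tested. Pairs are unordered
for support, directed for confidence; self-pairs are excluded; pairs
never co-occurring are never materialized (sparse contract). Rules over
three or more herbs are out of scope.

Cross-system pair comparison intersects the per-system sets of
qualifying pairs (support strictly above the mining threshold) and
reports both directional overlaps and Jaccard, again because shared
two-herb-combination percentages have ambiguous denominators.

## Rounding and tie-breaks

Raw fractions are kept everywhere internally; percentages are rounded
half-up (one decimal by default) only at report rendering, matching how
printed tables round. Top-k rankings break support ties
lexicographically by name — an arbitrary but deterministic rule.
Degenerate inputs fail loudly: empty formularies, empty base sets in
directional overlap, and conditioning on a support-0 herb all raise.

## The synthetic formulary generator

The generator emulates the statistical structure of real multi-system
formularies so every pipeline stage can be tested against known ground
truth:

- **Pool sharing.** Per-system herb pools realize either an exact Venn
  design (region → count) or pairwise overlap fractions. The
  study-shape preset uses an exact 15-region integer design solving the
  published constraints simultaneously: pool sizes 135/130/239/272 with
  a 546-herb union, 12 herbs common to all four systems, 42 restricted
  to TCM, 90 of Kampo's 130 herbs shared with TCM (69.2%), 115 of
  Unani's 272 shared with Ayurveda (42.3%), 14 of Ayurveda's 239 shared
  with TCM (5.9%) and 19 of Unani's shared with TCM (7.0%).
- **Popularity.** Herb usage is Zipf-distributed: weight
  $w_r \propto r^{-s}$ for popularity rank $r$, with a per-system
  exponent. Real usage is strongly uneven but unequally so across
  systems (top-herb supports from ~28% to ~72%), so a universal
  exponent would be wrong; the preset's exponents (0.644, 0.816, 0.430,
  0.538) were calibrated once, by bisection over a handful of seeds,
  so the full generator's top-herb supports match the published values
  60.0 / 71.5 / 54.2 / 27.6%. Popularity order and weights are a
  deterministic function of the configuration (keyed-hash scramble of
  the pool), independent of the sampling seed, so planted rules can
  name their herbs and model expectations are computable a priori.
- **Sizes.** Formulation size is $1 + \mathrm{Poisson}(\mu - 1)$,
  giving exact mean $\mu$ (per-system means 6.8 / 7.3 / 12.9 / 8.5 in
  the preset) with a realistic right skew and no empty formulations.
- **Sampling.** Herbs are drawn without replacement by the
  exponential-race scheme (successive weighted sampling): each herb
  gets key $E_i/w_i$ with $E_i \sim \mathrm{Exp}(1)$ and the $m$
  smallest keys win.
- **Planted rules.** After a formulation is drawn, each planted
  dependency $a \to b$ with target confidence $c$ fires with
  probability $c$ whenever $a$ is present without $b$; the consequent
  then **replaces** a uniformly chosen non-planted herb, so formulation
  sizes are preserved exactly (the formulation grows only in the rare
  case that every other herb is itself rule-protected). Mutual
  dependencies are two planted rules, one in each direction. The
  preset plants 6 / 2 / 12 / 0 confidence-1 rules per system, the
  Ayurvedic twelve containing two mutual pairs, with antecedents at
  popularity ranks whose supports sit near 10% (comfortably above the
  5% mining threshold) and consequents among the top-ranked herbs,
  mirroring the hub role the most popular species play in real
  formularies.
- **Coverage.** A final pass swaps every never-drawn pool herb into
  some formulation in place of a herb with count ≥ 2, so the observed
  distinct herb set equals the configured pool and the exact Venn
  design survives into the observed corpus, again without changing
  sizes.
- **Taxonomy.** Genera (3 species each) are assigned to families with
  Zipf-skewed sizes by cumulative rounding — deterministic from the
  configuration — and families group into orders; the preset marks 5
  of the 546 species as algae, the rest Plantae. Every 10th herb gets
  a synonym alias which the table writer uses as the raw name, so
  re-ingesting a generated corpus exercises standardization.

`(config, seed)` fully determines the corpus; identical inputs are
byte-identical after serialization.

### What the generator does not emulate

Herbs are sampled independently given the popularity weights, apart
from the planted rules. Real formularies have block-structured
co-occurrence (therapeutic themes), so their mined rule sets include
*incidental* high-confidence pairs beyond any planted set; the
generator's rule counts are therefore lower bounds on, not
reproductions of, real-data rule counts. The synthetic taxonomy has
uniform genus sizes and no biogeography; dosage, preparation and
indication structure are absent. Passing tests demonstrate the
correctness of the statistics and the recoverability of planted
structure — not that real formularies look like the null model.

## Problem sizes and tolerances in the tests

Brute-force equivalence runs on ≥100 random corpora of ≤10 herbs × ≤8
formulations, where exhaustive enumeration is exact. Calibration
checks on the study-shape preset average 20 seeds at full corpus size
(612 formulations): mean sizes within ±0.3 (±0.5 for the largest
system), top-herb supports within ±5 points, directional pool overlaps
exact by construction. Planted confidence-1 rules must be recovered
with confidence exactly 1 whenever their pair support clears the
mining threshold; a planted confidence-0.9 rule at n=500 must be
estimated within three binomial standard errors below its target
(baseline co-occurrence can only push the estimate up, never down,
which is why the check is one-and-a-half-sided). Monte-Carlo model
expectations use 4–6k draws, well inside the ±5-point bands they feed.

## Known limitations

- Standardization is exact-match only; misspellings require synonym
  table entries.
- The multiway "shared" denominator (union) is a convention; raw counts
  are emitted for recomputation, but a single published percentage with
  an unstated denominator cannot be disambiguated automatically.
- The generator's independence assumption makes mined-rule *counts*
  on synthetic corpora incomparable to real corpora (see above).
- Formulation metadata (dosage, source text, indications) is carried
  but never analysed.
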