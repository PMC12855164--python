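# Methods

## Data model

The unit of analysis is the *sampling event*: all replicate samples of one
substrate (water, sediment, soil) collected at one location on one day.
Event identity is the (location, substrate, date) triple; an `event_id` can
be supplied in the metadata, otherwise it is synthesized from that triple.
Replicate detections are pooled into a species-by-event matrix whose cells
hold the number of *positive replicates* — the count of distinct replicate
samples detecting the species. Incidence is `positives ≥ 1`. Read counts
are carried through curation (and conserved by the merge rule) but do not
survive pooling: every downstream statistic is incidence- or
replicate-count-based, which reflects how multi-substrate vertebrate
surveys are analyzed (read abundances from gel-purified, index-amplified
12S libraries are not a defensible abundance signal).

**Combined-primer pooling.** When both primer datasets are pooled, a
replicate counts as positive for a species if *either* primer detects it
there (union at replicate level, then count). This is the weakest
assumption available — an event-level union would discard the
replicate-count information — and the replicate-level rule is asserted by a
property test: combined incidence equals the element-wise OR of the two
single-primer matrices.

**Genus-rank detections** are rejected by pooling: the curation filter must
resolve them (to a unique documented congener) or exclude them first, so the
final matrix is species-level by construction.

## Curation against an occurrence catalog

Each distinct assigned taxon receives exactly one decision, by fixed
precedence:

1. **blocklist** (domestic animals, humans) and **anthropogenic**
   contaminants (food species such as *Thunnus albacares*, *Salmo salar*)
   → exclude;
2. **override** — curated relabelings with a free-text justification; the
   shipped example is *Canis lupus* → *Lupulella mesomelas*, the case of an
   abundant native congener with a single reference sequence attracting the
   domestic/wolf label;
3. species-rank label **documented** in the region → accept;
4. congener resolution: the candidate set of the label's genus is either
   all documented congeners (`documented_congener_unique`, the default) or
   only documented congeners lacking a marker reference sequence
   (`unreferenced_congener_unique`). Exactly one candidate → reassign;
   none → exclude (`no_congener`); several → exclude
   (`ambiguous_congeners`). Both congener counts are recorded on every
   audit row regardless of mode.

The two ambiguity modes exist because the unique-congener criterion is
genuinely open: counting all documented congeners is the conservative
reading, while restricting to unreferenced congeners models the
misassignment mechanism (a species absent from the reference database
cannot receive its own label, so its reads land on a referenced relative).
Both are implemented and tested; neither is asserted as the only correct
rule. Precedence of blocklist over override is likewise a choice: the audit
invariant tested is that adding a blocklist entry can only change a taxon's
action to exclude.

Names are canonicalized before lookup: whitespace collapse, trinomials
truncated to the binomial (occurrence catalogs are binomial), then a flat
synonym alias table (e.g. *Canis mesomelas* → *Lupulella mesomelas*).
A species absent from the reference catalog is reported as "unknown",
distinct from "no reference"; for congener counting, unknown is treated as
lacking a reference, since absence from the marker listing is exactly the
condition of interest.

## Descriptive statistics

All statistics are exact set arithmetic on the incidence matrix:

* **richness** — distinct species per group (a species counts toward a
  group if incident in ≥ 1 of its events);
* **overlap** — per-level richness, exclusives, pairwise and all-level
  intersections, union; percentages of the union are rounded to the nearest
  integer with ties away from zero;
* **detection frequency** — positive events / denominator; the overall
  denominator is every event in the matrix regardless of substrate, with
  per-substrate columns (and explicit denominators) alongside for
  restricted comparisons;
* **rarity** — rare iff overall frequency < 0.1 (strict; exactly 0.1 is
  abundant); the threshold is a parameter with that default;
* **positives-per-event distribution** — over cells with ≥ 1 positive
  replicate; mode ties resolve to the smallest count;
* **distances** — Jaccard on incidence, Bray–Curtis on positive-replicate
  counts, via scipy's pairwise-distance routines; a pair of events with no
  detections at all has distance 0 by convention (warned). Bray–Curtis on
  replicate counts rather than read counts follows from the data model
  above.

Downstream hypothesis tests (Kruskal–Wallis, Wilcoxon, PERMANOVA, NMDS,
negative-binomial volume regression) are deliberately out of scope: the
package exports tidy tables and distance matrices shaped for standard
statistical routines.

## Accumulation curves and design comparison

Accumulation curves permute event order, take cumulative distinct-species
counts, and report the mean with a confidence band per k. With K ≤ 7
events all K! orderings are enumerated, making the mean exact (the suite
checks it against the hypergeometric closed form
`Σ_s [1 − C(K−n_s, k)/C(K, k)]`). Default 1000 permutations otherwise. The
band is a percentile interval across orderings (no normality assumption),
widened minimally to contain the mean — on strongly skewed permutation
distributions an empirical quantile can cross it; `ci_method="sd"`
(mean ± z·SD) is available for parity with classic ecology toolboxes.

The mixed-substrate comparison first finds *paired days* — (location, day)
with at least `min_replicates` (default 8) replicates in both substrates —
then builds three designs on exactly those days: each single substrate with
its full replicate set, and a mixed design pooling `k_sub` (default 4)
replicates sampled without replacement from each substrate into one event
per day. The default is a single random draw with an explicit seed
(averaging over draws via `n_draws` is available; a single draw is
seed-sensitive and the reported SD refers to across-event spread, not draw
noise). With `k_sub` equal to the full replicate count the mixed event is
exactly the union of the two substrate events — the degenerate case used as
a correctness anchor.

## Synthetic surveys

The generator samples the two-level Bernoulli hierarchy described in the
README. Design choices:

* **Draw discipline** — one `numpy` PCG64 generator; the number and order
  of uniform draws depend only on the survey layout, never on parameter
  values. Two runs with the same seed but different capture probabilities
  therefore share uniforms, so raising any probability can only add
  detections (monotone coupling, tested both pathwise and in expectation).
* **Default survey** (`savanna_preset`) — 3 waterholes × 2 seasons ×
  8 sampling days for water and sediment (8 replicates each), plus 3 trail
  locations × 4 dry-season days of soil (6 replicates): 108 events, 840
  samples, ~95-species pool. Species parameters are drawn once from the
  preset seed with a long-tail profile: availability ψ ~ Beta(1.3, 1.6),
  capture p ~ Beta(1.2, 6) for water/sediment and Beta(1, 9) for soil,
  seasonal multipliers U(0.6, 1) wet / U(0.4, 1) dry, and per-primer
  amplification U(0.5, 1) with probability 0.7 (else near zero, giving
  partial primer overlap). These values were chosen as field-realistic:
  they produce overall detection frequencies spanning ~0.01–0.9 and a
  positives-per-event mode of 1 in water and sediment — the patchiness
  signature of waterhole eDNA.
* **Volume model** — water replicate volumes ~ N(400, 100²) ml (clipped);
  an optional exponent `volume_slope` scales capture by
  `(volume/mean)^slope`, default 0 (no effect). Parameter recovery assumes
  the neutral slope.
* **Read counts** are shifted-geometric decoration and carry no analytical
  weight; this is stated rather than hidden because the emitted tables
  look like real classifier output.

What the generator does **not** emulate: eDNA transport and decay, spatial
autocorrelation between waterholes, PCR error/chimeras, index hopping,
secondary DNA input by scavengers, and any read-abundance biology. Passing
tests therefore demonstrate the correctness of the post-processing
arithmetic and the internal consistency of the detection model — not that
the model describes any real system.

The taxonomy-challenge generator injects curation scenarios
(documented-accept, unique congener, reference-gap congener, ambiguous
congeners, no congener, blocklisted, override) into an assignment table
with the ground-truth decision recorded per label under both ambiguity
modes; the audit is checked for 100% agreement. Catalogs built by
`challenge_catalogs` use synthetic genus/species names.

## Parameter recovery

`recover_detection_params` compares the empirical event-level detection
frequency per species and (substrate, season) stratum with the analytic
expectation, reporting bias and the Monte-Carlo standard error
`sqrt(d(1−d)/n)`; strata with a single event are flagged unusable. At
~2000 simulated events (the scale used by the acceptance script), ≥ 95% of
species/strata fall within 3 MC standard errors.

## Problem sizes and numerical conventions

The test suite and acceptance script run on simulated data sized so each
check is statistically meaningful while the whole suite stays quick:
500 random matrices (≤ 10×10) for oracle equivalence, ~2000 events for
parameter recovery, 200 seeds for the design-dominance property, 100 seeds
for the patchiness property. Determinism: every randomized operation takes
an explicit seed and is bit-reproducible under it; the CLI writes a
manifest recording seeds and input digests per stage. Degenerate inputs
(empty matrices, single events, k_sub = 0, empty event pairs) follow the
documented conventions above rather than erroring where a convention is
defensible.

## Known limitations

* The curation filter is name-based; no fuzzy matching, no sequence-level
  evidence (ASV clustering against reference haplotypes is out of scope).
* Catalog provenance (query filters, basis-of-record choices) is the
  user's responsibility; the filter treats the catalog as ground truth.
* Accumulation CIs describe permutation spread of the realized survey, not
  sampling uncertainty of the underlying community; no asymptotic richness
  estimators (Chao, jackknife) are provided.
* The mixed-design comparison conditions on paired days; surveys without
  complete replicate sets in both substrates yield no comparison.
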