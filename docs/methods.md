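# Methods notes

## The procedure

`ddiscreen` operationalises a compendium-based occurred-DDI analysis of a
spontaneous reporting database. The unit of analysis is the individual case
safety report. The pipeline is deterministic given its inputs: a report
file, a knowledge base (KB) of severity-graded drug pairs with effect-term
sets, and the eligibility criteria.

**Eligibility funnel.** Filters run in a fixed order — vaccine exclusion,
seriousness, causality, minimum drug count — so that the intermediate
exclusion counts are comparable across runs. The final analyzed set is
order-invariant (the filters are pure predicates); only the attribution of
exclusions to stages depends on the order. The funnel counts are exposed in
full, including the causality exclusion as its own stage.

**Drug identity.** A drug contributes its level-5 ATC code when one is
present, otherwise its normalised substance name. This matches how
reporting systems code drugs (ATC) while tolerating free-text substances.
Duplicate mentions of one identity key collapse before pairing, so a report
with *d* distinct keys yields exactly C(d, 2) unordered pairs; suspect and
concomitant drugs are pooled. Interactions among triples or higher are out
of scope — the KB is strictly pair-based.

**Knowledge base.** One merged record per canonical pair (members sorted
lexicographically). Duplicate rows merge to the maximum severity under the
fixed total order contraindicated > major > moderate > minor, with the
union of effect terms; free-text fields are taken from the more severe row
(ties broken lexicographically) so that loading is commutative over row
order. Severity "documentation level"/evidence grading is not modelled.

**Concordance.** Matching is exact set intersection between the report's
reaction term codes and the record's effect terms; one matched term
suffices to judge the interaction occurred. The alternative reading — that
*all* reported reactions must be explained — is stricter than any plausible
clinical adjudication and is not implemented. Clinical judgement that a
human panel would apply (e.g. "any haemorrhagic event realises an
anticoagulant interaction") is externalised into the KB by listing several
preferred-term codes per effect. A record with an empty effect-term set
cannot be machine-matched; such potentials are never counted occurred or
not-occurred but are written to a review queue with full context, keeping
the human-adjudication step auditable rather than silently dropped.

**Groups and statistics.** A = ≥1 occurred DDI, B = potential only,
C = no listed pair; the three labels partition the analyzed set by
construction. Proportion cells use the two-sided Wilson score interval
without continuity correction; this is the interval that reproduces
published summary-table bounds of this analysis type at small counts where
the Wald interval fails (e.g. 17/381 → 2.8–7.0). Means use the t interval;
a zero-variance sample gets a zero-width interval rather than an error.
Percentages are rounded half-away-from-zero to one decimal at presentation
only. Missing age or sex excludes a report pairwise from the affected cell
but not from group counts. Both the mean and the median age are emitted
(analyses of this kind report either). The "contraindicated + major"
percentage is computed over each group's potential-DDI *instances*, not its
reports — which is why it is undefined for group C. Ranked tables break
ties lexicographically on the pair key for run-to-run determinism. The
drug-count stratification uses bands 2–7 and "8+", and the sex-stratified
drug-count summary uses age bands 18–44, 45–64, >64.

Two senses of "drug combination" are both exposed in the census, because
summaries of this kind use both without always saying which: per-report
pair instances (`pair_instances`, `potential_instances`) and distinct pair
keys (`distinct_pairs`, `distinct_potential_pairs`).

## The synthetic generator

The generator emulates the marginal structure such an analysis assumes:
a long-tailed per-report drug count (≈45% single-drug mass, tail to 12),
a two-component age mixture weighted 0.8 toward a 72 ± 12-year component,
≈56% female, physician-dominated reporter mix, half serious, 10%
vaccine-related, and a causality mix with ≈94% in the accepted categories.
A KB over the synthetic repertoire includes each of the C(n_drugs, 2) pairs
independently with probability `kb_pair_density` (default 0.12), with
severities skewed toward *major*. These defaults are documentation-level
choices for realistic demos, not asserted quantities.

Planting: if a report's drugs contain at least one KB pair then, with
conditional probability `p_concordant` (default 0.3), one such pair is
chosen and one of its effect terms is added to the report's reactions.
Effect terms are unique per pair and prefixed `IX_`, disjoint from the
`BG_` background reaction vocabulary, so recovery of planted group labels
by the pipeline is exact — there are no accidental matches. Consequently,
passing recovery tests demonstrates the pipeline's bookkeeping, not
robustness to the fuzziness of real MedDRA coding, narrative-only
reactions, or duplicated cases, none of which the generator emulates.
Reporter recognition is planted per occurred pair (`p_both_suspect`, then
`p_flagged_given_both_suspect`), and fatality is sampled at a higher rate
for occurred reports (`p_fatal_given_occurred` vs `p_fatal_base`),
implemented as a death seriousness criterion.

Randomness: one root seed governs a counter-based substream per report
(report *i* draws from `default_rng([seed, 2, i])`; the KB from
`[seed, 1]`), so output is byte-reproducible and independent of generation
order.

## Numerical and scale choices

- z and t quantiles come from scipy; the Wilson interval itself is the
  closed form, cross-checked in tests against an independent
  implementation (statsmodels) over randomized (k, n, level).
- Interval bounds are clipped to [0, 100]% before rounding.
- Simulation-based tests use 3,000-report sets for the polypharmacy
  gradient and ten 5,000-report replicates for concordance-rate recovery —
  large enough that binomial error (±2 percentage points on the mean
  recovered rate) is comfortably resolved.
- The monotonicity check on the stratified rate curve allows a 7-point dip
  between adjacent strata as sampling slack at these stratum sizes.

## Known limitations

- Exact term matching cannot credit synonymous or hierarchically related
  reaction codes; a production deployment would expand KB effect-term sets
  (or map through a licensed dictionary) and lean on the review queue.
- Causality is consumed as an input attribute; no re-scoring is done.
- The delimited dialect cannot represent two byte-identical drug entries
  in one report (rows are cross-products and duplicates collapse on read);
  the JSON-lines dialect round-trips any valid report set.
- Age confidence intervals in published tables of this kind are not
  reproducible without the underlying dispersion, so no assertion is made
  about them; only proportion cells are reproduced from (k, n).
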