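# Methods

## Data model

A use-report table is a *set* of (informant, species, category) triples
plus a study design.  Two modelling choices matter:

- **A use report is a distinct triple.**  Repeated mentions by the same
  informant of the same species for the same purpose collapse on load.
  UR is defined by counting informants per use category, so multiplicity
  within a triple cannot contribute; deduplication also makes loading
  idempotent and order-independent.
- **N and NC are survey-frame quantities.**  The denominators of CI,
  RFC and CVe use the *total respondents surveyed* (N) and the *designed*
  category count (NC), supplied via `StudyDesign`, not whatever happens
  to appear in a given file.  In the Ghana reference survey N = 258 and
  NC = 6 even though only 251 informant codes carry records; the
  published index values are exactly UR/258 and FC/258.  When no design
  is supplied, both default to the observed distinct counts — convenient
  for exploratory use, but explicit designs should be preferred for any
  comparison across datasets.

Identifier normalization trims and collapses whitespace and case-folds
species and category labels; informant codes keep their case, since
hand-assigned codes like `a1`/`A1` may denote distinct respondents.
Normalization is a load-time option, not baked into the model.

## Indices

For species s: UR_s (distinct informant-category mentions), FC_s
(distinct citing informants), NU_s (distinct categories), and

- CI_s = UR_s / N
- RFC_s = FC_s / N
- RI_s = (RFC_s / max RFC + NU_s / max NU) / 2, maxima over the analyzed
  table — RI is a *within-table* rank composite, so duplicating the
  informant pool leaves it unchanged and only a species attaining both
  maxima reaches 1
- CVe_s = (NU_s / NC) · RFC_s · CI_s

Per category u: Nur_u (use reports), Ns_u (species), and the Trotter–
Logan agreement ratio IAR_u = (Nur_u − Ns_u)/(Nur_u − 1).  IAR is
undefined for Nur ≤ 1 and is reported as NaN with a logged warning
(rendered as an empty field); forcing 0 or 1 there would fabricate a
consensus statement from at most one report.

Fidelity level FL_su = 100 · UR_su / FC_s.  The denominator is FC — the
informants citing the species for *any* use — so a species' FL values
across categories sum to 100·UR_s/FC_s ≥ 100.  This is the convention
under which every single-use species prints FL = 100 and multi-use
species can hold 100 in one category while exceeding zero elsewhere.

All arithmetic is carried at full double precision; display rounding
(half-even, 3 decimals for indices and IAR, 2 for FL) is applied only at
render time, via decimal quantization of the float's shortest repr so
decimal ties round to even rather than inheriting binary representation
error.

Ordering is deterministic everywhere the field's published tables have a
convention: the species index table sorts by UR descending with species
id as tie-break; consensus rows follow the study-design category order;
fidelity rows group by design category and sort by FL descending, then
species id.

## Reference dataset

`ethnosurvey.reference` records the species-by-element informant count
matrix of a published survey of 258 vernacular-building artisans in
Ghana.  The published summary tables (per-species UR/FC/NU and
per-element fidelity percentages) determine this matrix uniquely: each
cell is FL·FC/100, integer in every case, and the reconstruction closes
all margins exactly — 4109 use reports, per-element totals
1183/730/339/539/518/800, and 36 species-element incidences.  Two cells
absent from the published fidelity listing (both completing the thatch
element, notably *Bambusa vulgaris* at FL 49.38) are implied uniquely by
marginal closure and are included.

The expansion to record level assigns informant codes deterministically
(each species' citing informants are the first FC_s codes of the pool,
nested so the anchor element is cited by all of them).  Which individual
informant made which mention is *not* identifiable from published
margins, so informant-level structure — specialisation, co-citation —
is synthetic.  Every statistic this package computes depends on the
margins only and is therefore exact; analyses of informant-level
structure should not be run against the reference expansion.

## Synthetic survey generator

The generative model: informant i cites species s with probability p_s
(independent Bernoulli across informants and species); a citing
informant mentions category u with probability w_su, independently
across categories, with one *anchor* category per species fixed at
w = 1.  The anchor guarantees every citing informant yields at least one
record (so FC equals the anchor-category count) and reproduces the
empirical pattern that each species has a 100%-fidelity purpose.

Closed forms used for parameter-recovery tests: E[FC_s] = N·p_s,
E[UR_s] = N·p_s·Σ_u w_su, E[Nur_u] = N·Σ_s p_s·w_su; CI and RFC scale by
1/N; NU is the count of positive weights (attained a.s. at large N).

The `ghana-building` preset sets p_s = FC_s/258 and w_su = UR_su/FC_s
from the reference matrix, so generated tables match the published
margins in expectation at N = 258.  Default sizes elsewhere follow the
study conditions (N = 258, 26 species, 6 categories); calibration tests
use N = 2000 (3 Monte-Carlo SE bands) and 200 replicates at N = 1000,
sizes at which binomial standard errors are small enough to detect a 2%
relative bias.

Randomness is one PCG64 stream seeded per call, consumed from a single
uniform block indexed informant-major, species-minor, category-innermost;
the same seed yields a byte-identical serialized table on any platform
with the same generator algorithm.

What the generator does **not** model: informant heterogeneity (every
informant has the same citation probabilities), correlation between a
species' categories beyond the anchor, snowball-sampling structure, and
informant covariates.  Passing calibration tests therefore validates the
estimators under independent citation, not under realistic informant
clustering; on real data the indices are descriptive statistics and need
no such assumption.

## Limitations and edge cases

- Empty tables are rejected at construction (`EmptyInputError`); a
  category declared in the design but absent from the data carries
  nur = ns = 0 and undefined IAR.
- Unknown species lookups raise `KeyError`; impossible count
  combinations (FC > N, Ns > Nur, UR_su > FC) raise `ValueError` rather
  than producing out-of-range indices.
- No taxonomic name resolution or fuzzy matching: `"Bambusa  vulgaris "`
  and `"bambusa vulgaris"` merge under whitespace/case normalization,
  but genuine misspellings remain distinct species.
- No bootstrap confidence intervals: the indices are reported as point
  descriptive statistics, as is standard for this family of measures.
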