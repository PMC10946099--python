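# Methods

## Data model

An inventory is a set of species records, one per species, validated on
construction: voucher codes and scientific names are unique; every record
names at least one township of occurrence and at least one of the five use
categories (edible, trade, medicine, forage, ornamental — a closed
vocabulary; no other category is representable); a stored RI must lie in
(0, 2] and a stored UV must be non-negative. Genus is never stored: it is
derived as the first whitespace token of the scientific name with a leading
hybrid sign stripped, so `Paeonia × suffruticosa Andrews` yields `Paeonia`.
Authority strings are kept inside the scientific name and ignored —
identity is the full printed string, which avoids fragile authority
parsing at the cost of treating orthographic variants as distinct.

Life forms are the closed set {herb, shrub, tree, liana}; "vine" is read as
a synonym of liana. Township tokens are normalized to the study codes
HK/LL/LES (full names accepted); a different code vocabulary can be passed
for non-study datasets, including arbitrary simulated designs.

**Use types.** Source tables record use categories and used plant parts as
two independent set-valued columns, without pairing them. The package
therefore defines a species' use types as the cross product: each distinct
(category, part) pair is one type, serialized `category:part`; a record
with no recorded part contributes one type per category. This is the only
deterministic encoding derivable from the two columns, and it is what the
NT component of RI counts. A consequence worth knowing: a species with k
categories always has at least k types.

## Indices

- **UV = Σ Uᵢ / n** over an informant × species matrix of non-negative
  integer citation counts. Exact rational arithmetic is unnecessary; the
  division is a single IEEE operation on an integer sum, reproducible to
  the last bit.
- **RI = NUC + NT**, each component the species' count divided by the
  inventory-wide maximum. The normalization guarantees some species has
  NUC = 1 and some has NT = 1, that 0 < RI ≤ 2, and that RI = 2 exactly
  when one species attains both maxima — the only per-species RI value
  that is structurally forced. Stored (published) RI columns are treated
  as data: with the type-counting convention of the original analysts
  unknown, per-species recomputation is not attempted beyond the forced
  maximum.
- **JI = c/(a+b−c) × 100** on species sets; both sets must be non-empty
  (the denominator can vanish only when both are empty). The matrix form
  excludes empty groups with a logged warning and requires at least two
  non-empty groups; the diagonal is 100 by definition.
- **La = 100 × Σ Aᵢ Cᵢ** with grades Aᵢ ∈ {1, 2, 3, 4} and proportions
  summing to 1 (tolerance 1e−6 at parse time). The result is checked, not
  clamped: a value outside [100, 400] beyond float fuzz raises an
  internal-consistency error. The default class→grade mapping (1 unused or
  bare, 2 forest/grassland/water, 3 cropland/orchard, 4 built or
  artificial surfaces) can be overridden per call; unknown class names
  raise rather than mis-grade silently. Published regional La values are
  not reproduced here — they require the underlying land-cover rasters,
  which are not distributable data.
- **H′ = −Σ pᵢ ln pᵢ** via `scipy.stats.entropy`, which normalizes counts
  to proportions and drops zero entries; natural log. 0 ≤ H′ ≤ ln(richness).

**Rounding.** All results keep full precision; printing conventions are
applied only at the reporting layer, with half-up rounding (not Python's
banker's rounding): JI to 1 decimal, UV/RI/H′/La to 2. Ranking ties are
broken by descending value then alphabetical species name, and ties at a
cutoff are all reported; threshold counts use strict inequality.

## The packaged survey

The Laershan Plateau transcription (152 species, three townships) is the
package's reference dataset. Recounts of it reproduce the published
life-form spectrum, family frequencies, township similarities
(50.5 / 40.7 / 39.0), the eight species with RI > 1.5 and the three
species carrying all five categories. Two published numbers do not
re-derive from the table itself: the genus total (prose says 124; a
first-token recount of the 152 printed names gives 123) and, per the
original demography tables, informant counts that disagree internally.
The transcription is kept verbatim; the recount is reported as computed.
"106 species of both edible and trade plants" matches the per-category
tallies (each is 106); the intersection (90) and union (122) are also
reported so neither reading is privileged.

## Synthetic surveys

The generator emulates the study design, not any richer ecology:

| parameter | default | rationale |
|---|---|---|
| n_species | 150 | study scale (152 observed) |
| n_townships | 3 | study design |
| membership_probs | (0.70, 0.55, 0.55) | observed occupancy 109/80/81 of 152 |
| shared_core | 29% of pool | 44 of 152 species occur in all townships |
| category_probs | (0.70, 0.70, 0.39, 0.20, 0.46) | observed category tallies / 152 |
| n_informants | 112 | study informant panel |
| citation_rate | 0.75 | mean published UV |

Township membership is an independent Bernoulli per (species, township)
via common random numbers — one uniform per cell compared against the
probability — so raising a probability only ever adds occurrences for a
fixed seed. Species that land nowhere are assigned one township drawn
proportionally to the membership probabilities (redrawing would bias the
marginals less transparently); the first `shared_core` species are forced
everywhere. Category sets work the same way with a ≥1-category guarantee.
Citation counts are i.i.d. Poisson with mean `citation_rate` (variance =
mean, the natural single-parameter counting model for "times cited");
a Bernoulli mode covers presence/absence citation designs. Randomness is
split into four independent streams (membership, categories, record
attributes, citations) spawned from one seed, so changing one parameter
group leaves the other draws untouched.

Ground truth travels with the data: township sets, category sets, the
exact pairwise JI (computed through the real index code at generation
time as a self-check) and the expected UV (= citation rate). What the
generator does **not** emulate: informant heterogeneity (all informants
share one rate), correlation between a species' categories and its
citation frequency, spatial structure within townships, and taxonomic
structure (synthetic genera are one per species). Passing tests on
synthetic data therefore validate the algebra and the pipeline, not the
field realism of any particular survey.

## Testing and problem sizes

Deterministic examples are frozen against independent oracles (brute-force
column sums for UV, term-by-term summation for H′, direct set arithmetic
for JI, hand arithmetic for RI and La); invariants (JI symmetry, bounds
and monotonicity; UV linearity and dilution; La as an affine average; H′
permutation-invariance and its ln-k maximum) run as seeded property tests.
Parameter recovery uses 1000–2000 informants at citation rate 1.5 and
checks that ≥95% of species fall within three analytic standard errors
(√(rate/n)) of the rate; the error-shrinkage check compares mean absolute
UV error at 10/100/1000 informants; the category-probability monotonicity
check averages 200 seeds at a 30-species pool. These sizes keep the whole
suite in the low seconds while leaving comfortable statistical margins.

## Known limitations

- Scientific-name identity is the printed string; no taxonomic name
  resolution or synonym collapsing is attempted.
- Per-species RI values other than the structural maximum are not
  recomputable without the original type-counting convention.
- The La index is implemented and tested on constructed tables only; no
  land-cover data ships with the package.
- The Venn partition is reported as counts and species lists per region;
  no diagram is drawn.
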