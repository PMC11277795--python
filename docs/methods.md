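# Methods

## Model and assumptions

`nutridbk` treats a food composition databank as two linked linear
structures.

**The nutrient panel.** Every food and recipe is a fixed 39-field vector
per 100 g edible portion: energy in kJ and kcal, five macronutrient
fields in grams, 22 mineral/vitamin fields in milligrams and 10 trace
fields in micrograms. Missingness is first-class: a field is either a
non-negative float or null ("not analysed"), and the two are never
conflated. When both energy fields are present they must satisfy
kJ ≈ kcal × 4.184 within a relative tolerance (default 2%, configurable),
which absorbs the fact that the two FAO factors (4.184 kJ/kcal and
0.239 kcal/kJ) are independent printed constants rather than inverses.
Each conversion direction uses its own factor and the library never
chains both on one value; which direction applies to which source is
recorded in configuration (the older national edition reports kcal, the
newer one kJ).

**Stage 1 (compilation)** is a priority fold followed by sparse
gap-filling. Merging is record-level: a food present in two tables keeps
the higher-priority record whole, because mixing fields across editions
would create profiles no laboratory ever measured. Gap-filling is
field-level and curated: an explicit item-code → fallback-code mapping
(no string similarity — matching in this workflow is a human judgement,
and a mapping file makes it reviewable), restricted to a configurable
field set defaulting to {carb_g, fibre_g, biotin_ug}. A filled field's
provenance is the fallback source; nothing non-null is ever overwritten.
Foods present only in a fallback table are imported as first-class items
of that source, which keeps per-source counts additive.

**Stage 2 (recipes)** is linear aggregation. Gram resolution:
`g` passes through; `ml` multiplies by per-food density (default
1.0 g/ml); household volumes use configured ml equivalents
(tbsp = 15 ml, tsp = 5 ml) times density; `sprig` maps to a configured
gram equivalent (default 1 g). These equivalents are declared defaults,
not measurements, and live in the config file. Recipe weight is the
supplied cooked weight when present, else the raw ingredient sum — no
yield factor for water loss or uptake is applied, so per-100 g values of
dishes that change weight in cooking are correspondingly biased; this is
a known limitation, not an oversight. Per-serving prefers `n_servings`
over `serving_size_g` when both exist. Under the default null policy a
null ingredient value contributes zero to the sum and flags the result
field incomplete (set exactly when ≥ 1 contributing item was null);
a propagate-null policy is available. Unmatched ingredient lines abort
by default — silent nutrient undercounting is the worse failure — and a
permissive mode instead excludes the line, lowers the recipe's reported
coverage, and drops recipes left with no matched lines.

**Retention.** Cooking losses are multiplicative retention fractions in
[0, 1] over a fixed 17-nutrient covered set (Ca, Fe, Mg, P, K, Na, Zn,
Cu, vitamin C, thiamine, riboflavin, niacin, folic acid, B6, folate,
vitamin A, carotenoids). One factor set per food at most; unassigned
foods keep raw values (implicit 1.0), so both arms of the sensitivity
analysis cover identical recipe sets. Factors are applied to the per-100 g
vector before gram scaling; since both operations are multiplicative the
order is immaterial, and application is provably monotone non-increasing
on covered fields and bit-identical elsewhere.

**Inference.** The with/without comparison uses the two-sided Wilcoxon
signed-rank test per covered nutrient: zero differences discarded
(Wilcoxon's original rule), ties mid-ranked, no multiple-testing
correction by default (a Bonferroni option exists). For effective
n ≤ 25 the exact permutation null is computed by convolving the rank
generating polynomial over doubled mid-ranks (doubling keeps tied
half-ranks integral; counts are exact in 64-bit integers), with
p = min(1, 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w))). Beyond that, scipy's normal
approximation with continuity correction and tie-corrected variance is
used. An all-zero difference panel is reported as degenerate with p = 1
rather than an error.

## Synthetic data generator

The fixture generator emulates the shapes of the real inputs at roughly
one-fifth scale: four source tables contributing 106/74/29/11 items,
15 foods duplicated across the two national editions, 15% missingness on
the gap-fillable fields, ~200 multi-ingredient recipes in four dish
categories plus a block of degenerate cases (a single-ingredient
identity recipe, a "pickles and preserves" recipe with no serving
information, recipes whose only match is a UK or USDA food, and one
deliberately unmatched ingredient for the error path), and a retention
table whose factor spans reflect how cooking-stable each nutrient is
(0.75–1.0 for calcium and zinc, 0.2–1.0 for the most labile, vitamin C,
0.5–1.0 otherwise). Retention
assignment covers 42.62% of ingredient lines; the generator assigns an
exact count of foods rather than sampling each Bernoulli, because recipe
lines draw foods uniformly and the assigned-food fraction then pins the
expected line coverage to the target.

Expected outputs ship with each fixture, computed by a deliberately
naive loop over plain dicts and floats with inline conversion constants —
a code path disjoint from the pipeline, so generator and engine cannot
share a bug. Twelve single-ingredient recipes use foods force-assigned
to one designated factor set, making the generating factors recoverable
from the ratio of arm medians.

What the generator does **not** emulate: nutrient correlation structure
(values are independent uniforms), realistic ingredient co-occurrence,
name messiness (every name maps cleanly), and cooking-weight change.
Passing tests therefore demonstrate arithmetic and bookkeeping
correctness on realistically *shaped* data, not nutritional validity of
any particular real-world table.

## Numerical choices

- All sums are sequential in ingredient order; tests compare outputs at
  1e-9 relative tolerance, far above the ~1e-16 error floor observed.
- Scaling preserves nulls and incomplete flags; the energy-coherence
  check is enforced at vector construction (table loading) and not
  re-applied to derived vectors, whose fields may legitimately diverge
  after flagged summation.
- Degenerate inputs: empty FCT files load as empty collections; an empty
  recipe file, a zero total weight, and a recipe with no matched lines
  are errors; an all-null nutrient stays null through summation.
- Fixture generation uses numpy's PCG64 (`default_rng`) with a single
  user seed; identical seeds produce byte-identical files, verified by
  SHA-256 in the manifest.

## Design choices where the design was open

- CSV is the only interchange format (UTF-8, comma, header row); every
  writer has a lossless reader and round-trip is tested.
- Per-serving precedence (`n_servings` first) and the household-measure
  defaults are declared in configuration since no authoritative values
  exist; the effective config is echoed into every output directory.
- Spices are ordinary ingredient lines with no de-minimis threshold.
- Recipe de-duplication across source books is out of scope (an
  editorial task); the tool assumes unique recipe codes on input.
- The acceptance script reports problem sizes alongside each value; its
  synthetic databank uses the default one-fifth-scale shape, which keeps
  the full two-arm pipeline run and oracle comparison to a few seconds.

## Known limitations

- No yield factors; no packaged/branded foods; no nutrient-adequacy
  evaluation; no energy recomputation from macronutrients.
- Ingredient and gap-fill matching are only as good as the curated
  mapping files; the tool validates referential integrity but cannot
  detect a semantically wrong match.
- The exact signed-rank branch covers the discard-zeros rule only; the
  Pratt rule always uses the normal approximation.
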