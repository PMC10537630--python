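# Methods

This note records the scientific and numerical choices behind
`mnqsar`: what each stage assumes, which knobs matter, and what the
synthetic-data results do and do not establish about real micronucleus
(MN) data.

## Curation model

A record is one (structure, endpoint, binary MN call). Standardization
keeps the single carbon-containing fragment after counter-ion removal,
neutralizes net formal charges by hydrogen addition/removal where
chemically valid (permanent cations such as quaternary ammonium are
left charged), and identifies compounds by the full 27-character
InChIKey. The organic domain is defined by an element whitelist
{H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I}; anything else counts as a
metal and rejects the record (organometallic if carbon is present in
the same fragment, inorganic otherwise). Two or more carbon-containing
fragments reject as a mixture — even when the fragments are copies of
the same molecule, since a multi-component record cannot be attributed
to a single test article. Polymers are recognized only by explicit
wildcard/repeat-unit atoms; no pattern inference is attempted.
Stereoisomers and tautomers with distinct InChIKeys are treated as
distinct compounds.

Deduplication is per (InChIKey, endpoint). Mouse and rat in vivo data
are separate endpoints and never merged. Conflicting labels are either
dropped (`exclude_conflicts`, the default) or resolved in favor of the
single guideline-compliant record when exactly one exists
(`prefer_compliant`). Every dropped input lands in exactly one report
entry, which makes record conservation checkable.

## Enrichment statistics

The odds ratio is the plain cross-product `TP·TN/(FN·FP)` with no
continuity correction by default (an optional Haldane +0.5 is
available); a zero denominator with a positive numerator is reported as
+inf and still satisfies any finite odds threshold, while a 0/0 table
is undefined and never enriched. The Fisher test is one-sided in the
enrichment direction and exact: `P(X >= TP)` for hypergeometric X with
the table's margins, computed from the survival function rather than a
normal approximation. The test suite checks it against brute-force
enumeration of all margin-consistent tables with exact rational
arithmetic for every table of total size ≤ 12.

PPV is the standard `TP/(TP+FP)` — the fraction of chemotype carriers
that are active — so it is a probability and comparable across
chemotypes and endpoints. Cross-endpoint tier cuts are ≥ 0.70 (high)
and the open interval (0.50, 0.70) (moderate); a PPV of exactly 0.50
is poor, keeping "moderate" strictly better than a coin flip among
carriers. Default thresholds for the enriched flag are ODDs ≥ 3 with
p < 0.05; the p cut is configurable for deliberately permissive
screens. No multiple-testing correction is applied: the workflow is a
ranking/screening tool and each chemotype's p-value is reported for the
reader to judge.

The set-level rule classifier predicts positive when a compound carries
at least k enriched chemotypes (default k = 1; k is exposed because the
coverage/precision trade-off between the ≥1 and ≥2 rules is a
legitimate analysis choice).

## Featurization

Descriptors are the full RDKit 1D/2D battery (~210 columns); a molecule
whose descriptors are not all finite is excluded and logged rather than
imputed. The prefilter removes constants, columns with population
standard deviation below 0.5, and for every pair with squared Pearson
correlation above 0.9 drops the later column, which makes the outcome
deterministic and order-stable. Note the variance cut is on raw,
unstandardized descriptors, so it is scale-sensitive by design — it
mirrors common QSAR practice of discarding near-constant fragment
counts.

The GA selector works on fixed-size index subsets: tournament selection
(size 3), crossover by resampling from the union of two parents,
per-gene mutation swapping a member for an unused feature (rate 0.05),
elitism of 1, population 50 × 30 generations by default. Fitness is
mean stratified inner-CV AUC of a baseline random forest on the
candidate subset; fitness values are memoized per subset, and the
whole procedure is reproducible from one seed. These GA settings are
conventional defaults, not tuned values, and are fully configurable.

Hashed fingerprints default to 2048 bits (1024 also conventional);
MACCS is the 166 keyed bits (the generator's placeholder bit 0 is
dropped). The bundled chemotype set is ~30 genotoxicity-relevant SMARTS
(nitroso, nitrosamine, carbamate, sulfonic ester, epoxide, aziridine,
quinone, alkyl halides, PAH cores, steroid scaffold, ...) written for
this package; it plays the structural role of a large proprietary
chemotype library without reproducing its definitions, and any
two-column `name<TAB>SMARTS` file can be loaded instead.

## Imbalance handling

Class weights are `w_c = n/(2·n_c)`, equalizing the weighted mass of
the classes; for XGBoost the same information is passed as
`scale_pos_weight = w_1/w_0`. SMOTE follows its definition exactly:
Euclidean k-NN (k = 5, clamped to minority size − 1) among minority
rows only, uniform interpolation, originals preserved verbatim. The
post-resampling minority/majority ratio is a first-class parameter
(default 1.0, full balance) rather than a hard-coded choice. Binary
fingerprint inputs are interpolated in real space and left unrounded by
default, preserving the algorithm's definition; rounding is the
caller's decision. Resampling is applied inside each training fold,
never before splitting, which both matches the intended protocol and
prevents leakage of validation compounds into synthetic points.

## Modeling and validation

"Ten-fold" evaluation is ten independent stratified 90/10 shuffle
splits (each validation set preserves the class ratio to within one
compound); a disjoint stratified k-fold partition is available as an
alternative mode. Grid search is exhaustive over the configured grid in
an inner stratified ten-fold on the training portion, scored by mean
AUC, with ties kept in grid order for determinism. Default grids (RF
trees 100/300/500 × depth none/10/20; SVM C 0.1/1/10 × gamma
scale/0.01; XGB trees 100/300 × depth 3/6 × learning rate 0.1/0.3) are
conventional starting points.

The Butina split clusters compounds by leader sphere-exclusion on
Tanimoto distance of radius-2/2048-bit circular fingerprints (distance
cutoff 0.4) and assigns whole clusters greedily — largest first, to the
side with the larger remaining deficit — so no cluster straddles the
split. If everything collapses into one cluster the split errors out
rather than silently degenerating.

Majority voting returns labels only, so ensembles report Acc/SE/SP
without AUC. Ties resolve positive: for a hazard endpoint the
precautionary direction is the defensible default. AUC for individual
models is the rank statistic (probability a random positive outscores a
random negative, ties counting one half), invariant under monotone
score transforms.

## Synthetic data: what it emulates and what it does not

The feature generator draws labels to the requested positive fraction
exactly (70/30 for the in-vitro-like endpoint, 32/68 in-vivo-like) and
plants chemotype bits as independent class-conditional Bernoulli draws,
so the population odds ratio is known in closed form
(`p₊(1−p₋)/((1−p₊)p₋)`) and recovery can be tested quantitatively. An
optional mutually-exclusive planting mode draws at most one planted
chemotype per compound (marginal prevalences preserved); paired-endpoint
generation uses it so each carrier's endpoint-B label can be drawn at
its chemotype's target PPV without ambiguity, and non-carriers are
labeled to hit endpoint B's class balance in expectation.

The molecule generator assembles SMILES from three scaffold templates
(benzene, cyclohexane, alkyl chain) with two substituent slots and an
alkyl tail; planted alerts are attachable fragments (carbamate,
nitroso, sulfonic ester, aziridine, quinone, alkyl halides) and inert
decoration deliberately avoids N, S and heavy halogens so it can never
realize an alert by accident. Structures are unique by InChIKey by
construction (the tail is extended on collision), which is why the
generated sets pass curation with zero losses.

For the end-to-end modeling scenario the planted prevalences are
carbamate 55%/5% and nitroso 50%/5% in positives/negatives. These were
chosen from the closed-form separability of two independent alert bits:
with prevalences p₁, p₂ in positives and q₁, q₂ in negatives, the AUC
ceiling of the alert-count score is computable directly, and at
55/50 vs 5/5 it is ≈ 0.86 — a "strong structural alert" regime in which
a working pipeline should reach cross-validated AUC ≥ 0.8 and a broken
one visibly cannot. The enrichment-recovery scenario instead uses a
30%/5% alert at n = 1000, a realistic single-alert effect size.

What passing these tests does **not** show: real MN datasets have
correlated, hierarchical substructures, activity driven by mechanisms
no 2D alert captures (metabolic activation in particular — the in
vitro / in vivo discordance of urethane-like compounds is exactly such
a case), label noise from inter-laboratory variation, and chemical
space far richer than a three-scaffold grammar. Synthetic results
validate the machinery (statistics, resampling geometry, split
hygiene, learnability of planted signal), not field performance.

## Numerical conventions and degenerate inputs

- Column standard deviations use ddof = 0.
- Enrichment tables sort by descending odds (NaN last) then ascending
  p, with a stable sort for reproducibility.
- Correlation prefiltering requires ≥ 3 compounds; enrichment and CV
  require both classes present; SMOTE requires ≥ 2 minority samples.
- All stochastic components (generators, SMOTE, GA, CV splitters,
  learners) take explicit seeds; fixed seeds reproduce outputs
  bit-exactly.
- Problem sizes in the test and acceptance runs (n = 800–2000 compounds,
  100-seed recovery loops, 300-tree forests) are chosen so the full
  suite completes in a few minutes on one CPU while keeping binomial
  noise well inside the asserted margins.

## Known limitations

- The charge neutralizer cannot fix permanent cations/anions; such
  compounds pass through charged.
- Polymer detection is notation-based only.
- The GA selector's fitness is a single baseline learner's CV AUC;
  subsets tuned for one model family may be suboptimal for another.
- `rule_based_classifier` ignores chemotype overlap/hierarchy; two
  highly overlapping enriched chemotypes count as two hits.
- Cross-endpoint tiering inherits all caveats of PPV: it depends on the
  endpoint-B class balance and carrier counts, and small carrier sets
  make tiers unstable (reported as `not_evaluable` only at zero
  carriers).
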