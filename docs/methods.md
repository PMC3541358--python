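# Methods

## Data model

All comparisons operate on presence/absence calls over a flat anatomical
vocabulary.  Each vocabulary entry maps a canonical term to a local term
per species (e.g. canonical "limbs" → zebrafish "pectoral fins"); a term is
*comparable* only when both species have one, and profiles are restricted
to comparable terms before any cross-species operation.  The built-in
vocabulary has twelve major embryonic domains appropriate to the
phylotypic stage (mouse 11.5 dpc ≈ zebrafish 24–48 hpf); it is a plain
YAML file and users are expected to extend it.  No ontology reasoning is
performed — homology is a flat per-term mapping by design, since the
comparisons are deliberately limited to wide, uncontroversially homologous
domains.

Genomic intervals follow the BED convention (0-based, half-open).

## Majority rule

A domain is called present for a (CNE, species, assay) context when the
reporter was observed in at least half of the replicate lines:
`2 × positive ≥ total`, ties inclusive.  The same rule is applied to any
(positive, total) support pair regardless of what a "case" is (line,
embryo, experiment); the package treats support uniformly.  Zero lines is
an error, not an absent call.

## Divergence metric

For one CNE with comparable transgenic domain sets *M* (mouse) and *Z*
(zebrafish), divergence is the fraction of species-specific domains among
the union: `f = (|M\Z| + |Z\M|) / |M∪Z|`.  The denominator is the union of
*annotated-positive* domains, not the whole vocabulary: a fraction of
"affected expression domains" is only well defined over domains that are
active somewhere, and per-category mean domain counts are means of positive
domains.  Categories: `identical` (f = 0), `global` (f ≥ threshold,
default 0.75, inclusive because the intent is "three quarters *or more*"),
else `partial`.  A CNE with an empty union has no defined divergence; the
pipeline excludes it with a warning rather than counting it as identical
(screens of this design ascertain elements by mouse activity, so the case
indicates missing data, not agreement).  Dataset summaries attribute each
mouse-only domain to mouse and each zebrafish-only domain to zebrafish
("ectopic" counts per species).

## Conservation stratification

Ancestry is called from a homology-search hit table: an element is
ancestral when its best hit significance is strictly below 10⁻⁵.  The
column is treated as the e-value that blastn actually reports, even where
upstream descriptions call it p.

Per-element score aggregation is the plain arithmetic mean of per-base
values; group comparisons use the *element* as the unit of observation
(one-way ANOVA on per-element means, unweighted by element length — a
deliberate choice where length weighting would also have been defensible).
The accelerated/constrained comparison counts positions with phyloP
strictly below −1 (accelerated) and strictly above +1 (constrained),
pools counts across elements within each group, reports the ratio
n_accel/n_constrained per group and their fold, and tests the pooled 2×2
table with the Pearson chi-square.  Boundary values (exactly ±1) count in
neither bin.

Alignment identity for a pair of aligned sequences is matches divided by
columns where neither member is gapped, in percent and case-insensitive;
block identity is the unweighted mean over all unordered pairs, excluding
pairs with no gap-free column.  This is the most common convention; the
per-pair values are exposed so a different aggregation can be applied.

Score input is text bedGraph or fixedStep wiggle (1-based starts converted
on read); every base of every element must be covered, since silently
imputing missing conservation scores would bias per-element means.

## Statistical tests

The four tests are implemented directly rather than delegated:

* **Pearson chi-square (2×2)** — `Σ(O−E)²/E`, df = 1, optional Yates
  continuity correction (|O−E| reduced by 0.5, floored at 0).  Zero
  margins are an error.  Default is no correction; reports name the
  variant used.
* **Fisher one-tailed** — exact hypergeometric tail, enumerated with
  integer binomial coefficients and normalised once per margin set
  (cached).  The caller must state the direction; the pipeline passes the
  enrichment direction matching the comparison being reported, since
  "one-tailed" alone under-specifies the test.
* **Two-sample t** — Welch by default (Welch–Satterthwaite df), pooled
  variance on request; two-tailed.  Two constant samples with equal means
  give t = 0, p = 1; unequal constant samples are an error.
* **One-way ANOVA** — F with (k−1, N−k) df.  For two groups F equals the
  square of the pooled t statistic; the test suite checks this identity to
  1e-9 relative tolerance.

Tail probabilities for chi-square, t and F use the scipy.stats
distribution survival functions; the statistics themselves, and the entire
Fisher computation, are package code.  No multiple-testing correction is
applied anywhere — the analyses report a handful of planned comparisons,
not a scan.

## Four-way classification

For a domain with calls (Mt, Zt, Mg, Zg):

* `trans_and_gene` ⇔ Mt ≠ Zt and Mg ≠ Zg and Mt = Mg and Zt = Zg — only
  (+,−,+,−) and (−,+,−,+) qualify; the pattern is symmetric under
  swapping species.
* `notrans_and_gene` ⇔ Mt = Zt and Mg ≠ Zg and Mt = Mg (default,
  *asymmetric* rule).

The asymmetric mouse-side condition is deliberate: the tested sequences
are mammalian, so mouse is the native trans environment and a concordant
reporter that matches the mouse gene is the informative "no trans change,
gene changed anyway" case, whereas (+,+,−,+) — reporters matching the
*zebrafish* gene only — is ambiguous and stays unclassified.  A
`symmetric` variant (any concordant reporter with a diverged gene) is
provided for sensitivity analysis; it only ever relabels unclassified
rows.  Domains negative in all four contexts carry no information and are
omitted from tables.

A CNE is *trans-consistent* when at least one of its domains is
`trans_and_gene`.  The divergence-by-gene-status comparison is a
two-sample t test on per-CNE divergence fractions between CNEs with
divergent vs conserved target genes.

## Synthetic-data generator

The generator emulates the screen's statistical structure, not its
biology:

* Mouse transgenic state per domain ~ Bernoulli(`activity_prob`).
  Elements with no active mouse domain are redrawn (and the redraw count
  logged), mirroring ascertainment of elements by prior mouse activity.
* Zebrafish transgenic state = mouse state flipped independently per
  domain with `trans_change_rate`.  Because flips are independent of
  mouse activity, the probability that a slot is species-specific equals
  the rate exactly, ascertainment notwithstanding; the generator records
  this analytic expectation alongside the data.
* Each species' endogenous gene call equals its transgenic state with
  `gene_mirror_prob`, else flipped.
* Replicate lines are attached to the zebrafish transgenic context (the
  study design this emulates reads mouse calls from a curated database
  and zebrafish calls from ≥ 3 stable lines): per line and domain, a true
  positive is observed with `detection_prob` and a true negative with
  `false_positive_prob`.
* phyloP tracks are Gaussian per base, i.i.d., with (mean, sd) chosen by
  the element's conserved/lost status.  Autocorrelation and heavy tails
  of real conservation tracks are deliberately out of scope, so the
  Gaussian model reproduces mean contrasts between groups but not the
  tail-count ratios real tracks show; tests of the ratio machinery use
  constructed tracks instead.
* One integer seed feeds a root `SeedSequence`; each component (status,
  activity, flips, mirroring, lines, tracks) draws from its own spawned
  substream, so adding a component never perturbs earlier draws and equal
  seeds give byte-identical output files.

Defaults describe a realistic screen of this kind: 47 elements over 12
domains; `activity_prob` 0.2 (≈ 2.4 active domains per element);
`trans_change_rate` 0.14 (≈ 84% of elements get ≥ 1 species-specific
domain); `gene_mirror_prob` 0.85; `lost_fraction` 0.46; 3 lines with
detection 0.9 and false-positive 0.02; phyloP means 0.107 (conserved) vs
0.159 (lost) with per-base sd 1.0 over 200 bp, which puts the two-group
ANOVA near the detection boundary for 20-element groups.

`recover_parameters` runs the real pipeline functions (majority-rule
aggregation, comparable restriction, profile comparison, four-way
classification, stratified ANOVA) on a generated dataset and reports the
recovered divergent-domain fraction, the trans_and_gene fraction among
divergent slots, and the group phyloP means.

What passing simulation tests shows — and does not: they validate the
pipeline's bookkeeping and statistics under a model whose assumptions
(domain independence, symmetric flips, Gaussian scores) real data need
not satisfy.  They say nothing about transgenesis-system artefacts,
correlated domains, or annotation subjectivity in real screens.

## Problem sizes and tolerances

The test suite and the reproduction script use scaled problem sizes
chosen to make binomial error small relative to the asserted tolerances:
rate recovery uses 1000 elements × 8 domains × 20 seeds (SE of the mean
fraction ≈ 0.001, asserted within ±0.04); the stratified-ANOVA power
check uses 40 elements per seed with group means 0.8 vs 0.2 (per-element
SE ≈ 0.007, so rejection at p < 0.01 is essentially certain).  Exact
checks (set algebra, Fisher enumeration ≤ 40, F = t²) run exhaustively or
at 1e-9 relative tolerance.

## Known limitations

* Presence/absence only: no expression-level quantification, no spatial
  subdomain resolution.
* The divergence metric is undefined for elements inactive in both
  species; such elements are excluded, which matters if a user's input is
  not mouse-ascertained.
* The asymmetric notrans rule is a modelling choice; with species-blind
  inputs the symmetric variant may be preferable.
* bedGraph/wiggle reading is for plain text; binary bigWig is not read.
* Gene–CNE association, homology searching and track retrieval are
  upstream of this package: their outputs are consumed as tables.
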