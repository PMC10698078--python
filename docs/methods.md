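# Methods

## Tracer accounting

The package supports exactly two isotope systems: ¹³C on the VPDB scale
(standard ratio ¹³C/¹²C = 0.0111802) and ¹⁵N on the AIR scale
(¹⁵N/¹⁴N = 0.0036765). These are the canonical standard ratios; inputs are
assumed already point-calibrated by the mass-spectrometry workflow, so no
drift correction is applied here. Delta values convert to heavy-atom
fractions via `F = R/(1+R)` with `R = R_std(δ/1000 + 1)`; the conversion is
strictly monotone and inverts to machine precision, which the tests assert
at 10⁻¹² relative tolerance.

Atom-percent excess is the labelled atom fraction minus the control atom
fraction, ×100. The control atom fraction is the mean over all non-labelled
control plants per compartment × element — the least-assumption mapping when
the assignment of controls to samples is not recorded. Negative APE values
(samples that read below the control mean by chance) are retained and
flagged rather than clipped: clipping would bias compartment means upward.

Enrichment concentration multiplies APE/100 by the element concentration of
the sample (element mass over dry mass). Units follow the magnitudes at
which the two labels arrive in roots: ¹³C in mg g⁻¹ and mg, ¹⁵N in µg g⁻¹
and µg; every output table carries an explicit `unit` column. Absolute
amounts are enrichment × compartment dry biomass; the ectomycorrhizal pool
of a plant sums enrichment × per-tip dry biomass × tip number over fungal
species, with tip number = relative abundance × total EM tips. Tip numbers
are kept real-valued internally and rounded only in reports — rounding at
small abundances would bias the summed pool. The ¹³C/¹⁵N transfer ratio
converts both amounts to µg before dividing.

## Community statistics

Root-tip censuses classify tips as vital mycorrhizal, vital non-mycorrhizal
or dry. Colonization (%) excludes dry tips from the denominator; vitality
(%) is vital over all counted tips. Relative abundance divides a species'
tip count by the vital mycorrhizal count; tips not assigned a morphotype are
kept as an explicit `unclassified` column, which is *excluded* from
community comparisons — silently renormalizing would distort Bray–Curtis
distances between plants with different classification completeness.

ANOSIM uses Clarke's statistic: dissimilarities (1 − Bray–Curtis similarity)
are ranked with midranks for ties, and R = (mean between-group rank − mean
within-group rank) / (n(n−1)/4), which is bounded in [−1, 1] and equals 1
for groups with disjoint species support. The p-value is
`(1 + #{permuted R ≥ observed}) / (B + 1)` under seeded random relabelling;
B defaults to 9999 in the API (the end-to-end runner and the test suite use
999 to stay inside time budgets; the seed and B are recorded in every
output). Tests verify agreement with exhaustive enumeration at small n and
with scikit-bio's implementation. Whether the underlying field analysis used
relative abundances or renormalized counts is not recorded; the runner
defaults to relative abundances and exposes
`anosim_on_relative_abundance=False` as the alternative.

## Regression layer

Enrichment ~ C/N and ectomycorrhiza ~ lateral-rootlet fits are ordinary
least squares; `r` is the Pearson correlation and the slope p-value comes
from `t = b/se(b)` on n−2 df. Slopes are tested against a reference (1.0 for
the coupling fits: the "no preferential allocation" line) with the same t
construction; two regression lines are compared by the pooled interaction
test (t on b₁−b₂ with pooled residual variance, n₁+n₂−4 df), which is
algebraically identical to the dummy-variable interaction regression the
tests use as oracle.

The C/N threshold is the x-intercept −a/b of a fitted line, defined only
when the slope is significant at α = 0.05 (the x-intercept of a flat line is
meaningless; requesting it raises). Its confidence interval is a
case-resampling percentile bootstrap (default B = 2000, seeded; degenerate
resamples with constant x are dropped); Fieller's closed-form interval is
available as an alternative and raises when the slope is too close to zero
for a bounded interval. On the stated generating model (slope −2.49,
intercept 57.1, σ = 5, n = 33) the nominal-95% bootstrap interval covers the
true threshold 93.7% of the time over 300 replicates.

Group comparisons (per-species enrichment) use one-way fixed-effects ANOVA
with Tukey–Kramer pairwise p-values from the studentized-range distribution
(unbalanced-safe), and a compact letter display built by the
insertion/absorption algorithm with groups ordered by descending mean for
deterministic output; letters are consistent with the pairwise decisions by
construction and the tests check this exhaustively on every fixture.
Normality is handled by an automated version of visual residual inspection:
a Shapiro–Wilk gate at p < 0.05 triggers a log transform when all responses
are positive (configurable off); reported group means stay on the original
scale and the result is flagged. Labelled-vs-control comparisons are Welch
one-sided t-tests ("greater": under labelling, enrichment can only exceed
natural abundance). The two-way tissue × time analysis is a fixed-effects
additive ANOVA: with only two sampling dates a random time factor is
inestimable, so time enters as a fixed block, matching the practice of
pooling dates when time is non-significant.

## Synthetic studies

The generator emulates the stated study conditions and inverts the analysis
chain: 16 fungal species (7 dominant, jointly ~80% of tips via a Dirichlet
with mass split 80/20 and concentration 40), ~400 tips inspected per plant
with colonization 92.6 ± 2.2% and vitality 89.6 ± 2.1%, total EM tips
29215 ± 4361, species C/N uniform on 7–30, carbon 380–440 mg g⁻¹ with
nitrogen derived as C/(C/N) so that C/N is the generative quantity (nitrogen
then spans ~13–63 mg g⁻¹, wider than the 20–40 mg g⁻¹ display range of the
real assemblage). ¹³C enrichment is `57.1 − 2.49·C/N + N(0, 5)` mg g⁻¹ and
¹⁵N `15.1 − 0.57·C/N + N(0, 2)` µg g⁻¹, both rectified at zero; the attached
lateral rootlet receives the EM enrichment divided by the coupling slope
(1.23 / 0.53) plus noise (1.5 mg g⁻¹ / 1.0 µg g⁻¹ — small enough that the
errors-in-x attenuation of the coupling slope stays below 0.02). Bulk
compartment enrichments are back-solved from published pool sizes over
published biomasses (fine roots 27.1 mg / 3.9 g, coarse 127.0 mg / 12.5 g,
rhizosphere 1.9 mg / 54 g; ¹⁵N analogous; bark set near the fine-root
level). Controls are natural abundance (δ¹³C = −28‰, δ¹⁵N = 0‰, SD 0.5‰,
a realistic IRMS spread). Every enrichment is converted back through APE and
atom fraction to the δ value a mass spectrometer would report, and every
generating value — including the *untruncated* enrichment — is retained in
ground-truth tables. Identical seed + config gives byte-identical output.

What a green test does and does not establish. The generator reproduces the
statistical structure the analysis assumes (linear stoichiometry, coupling,
community composition stable across dates), not field realism: no temporal
tracer kinetics between the two dates, no within-species C/N trends, no
spatial correlation, and the per-sample dry masses are uniform draws from
the 0.5–1.5 mg weighing range rather than morphotype-specific values.

Two structural properties deserve emphasis:

* **Rectification attenuates the ¹³C~C/N slope.** The generating ¹³C line
  crosses zero at C/N = 22.9, inside the stated 7–30 range, so rectifying
  enrichments at zero makes the OLS slope on emitted data ≈ −1.9, not
  −2.49 — a property of the stated generating model, not an estimator
  defect. The tests therefore assert (i) the pipeline's fitted slope equals
  an OLS fit on the emitted ground-truth enrichments (the measurement chain
  adds no bias), (ii) the untruncated ground truth recovers both C/N slopes
  within ±0.1/±0.05, and (iii) the coupling slopes — unaffected by
  rectification because the lateral value is derived from the emitted EM
  value — are recovered within ±0.05 end to end. The desk-scale recovery
  experiments (`mycotrace.recovery`, `scripts/acceptance.py`) generate from
  the plain linear models without rectification, matching their stated
  designs.
* **The default tip biomass makes the synthetic EM pool large.** With
  1–4 × 10⁻⁴ g per tip and ~29215 tips, synthetic EM biomass (~5.8 g per
  plant) exceeds the 3.9 g fine-root biomass, so the synthetic EM share of
  fine-root ¹³C is far above the ~6% the published pool means imply
  (back-solving those pools suggests per-tip biomass of order 10⁻⁶ g; the
  actual per-species values were never printed). The share arithmetic is
  therefore validated directly on the published pool means
  (`analysis/03_pool_arithmetic.py`), and the synthetic default is kept as
  configured — `tip_biomass_range` is the knob to change for realistic pool
  shares.

Open choice, decided here: the published ¹³C/¹⁵N ratio of 259 for roots is
not reconstructible from any printed pool pair (154.1 mg / 142.2 µg gives
1084); the package computes transfer ratios from unit-harmonized amounts and
reports what they are, without forcing agreement. Likewise the published
threshold statement "about 24" differs from the x-intercept of the printed
fit (57.1/2.49 = 22.93); the package reports the x-intercept with its CI.

## Numerical and interface conventions

All tables are tab-separated UTF-8 with headers; units are explicit columns.
Input isotope dialect (δ vs atom fraction) is declared per file, never per
row, and mixed files are rejected. Validation errors carry line numbers;
referential integrity requires every labelled EM measurement's species to
appear in the morphotype table of the same plant. The CLI exits 0 on
success, 2 on validation errors, 3 on unmet statistical preconditions.
Every stochastic procedure (ANOSIM permutations, bootstrap, simulation)
takes an explicit seed that is echoed in the output.

## Limitations

No mixed-effects/REML estimation (fixed-block approximation instead); no
isotope fractionation corrections; no image-based morphotype classification
(identities are input labels); no simulation of tracer kinetics between
sampling dates. The fungal-tissue-fraction analysis takes cross-section
areas as inputs; segmentation is out of scope.
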