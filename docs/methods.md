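# Methods

This note documents the models, conventions and numerical choices behind
`shadescreen`, and what the synthetic data do and do not establish.

## Weighted index of sensitivity

The sensitivity index of genotype *g* for trait *i* is the genotype's
relative IT-vs-SC change normalised by the population-average relative
change:

    IS(g,i) = [(X_r − X_s)/X_s] / [(X_ar − X_as)/X_as]

This form is direction-free: a trait that elongates under shade (stem
length) and one that declines (breaking strength) both give IS = 1 for an
average responder, so no per-trait sign map is needed. Traits whose
population relative change is below `epsilon = 1e-6` (configurable) are
unusable — the normaliser is numerically zero — and are dropped with a
warning.

Trait weights are `w_i = r_i / Σ r_j` with `r_i` the Pearson correlation of
trait *i*'s IS column against the genotype-wise mean IS. Negative `r_i`
are floored at zero by default (a trait anti-correlated with overall
sensitivity carries no information about it); `weight_mode="abs"` is
available for users who prefer unsigned weighting. When the mean IS vector
is constant (exactly opposed traits) no correlation is defined and the
weights are reported degenerate rather than guessed.

Plant-level rows are averaged to genotype × system means before any index
computation; the population references X_ar/X_as are unweighted means of
those genotype means. Classification bins are tolerant < 0.6,
susceptible > 1.2, the closed interval [0.6, 1.2] moderate.

## HPLC quantitation

External-standard calibration is ordinary least squares of area on
concentration (µg/mL); `r_squared` is reported for curve-quality review.
Identification assigns each peak to the nearest reference retention time
within a tolerance of 0.2 min (configurable; the method's gradient spans
0–70 min). Ambiguities resolve to the nearest reference, exact ties to the
analyte earlier in the canonical ordering, both logged. Back-calculation is

    mg/g = [(area − intercept)/slope] × V_extract(mL) / m_sample(mg)

with defaults 100 mg tissue in 5 mL extract; negative back-calculations
(area below the blank intercept) clamp to zero with a warning rather than
propagating negative masses. The bundled retention times and calibration
lines in `data/presets.yaml` are synthetic demonstration values, not
instrument data.

## Derived profiles

The twelve analytes partition two ways: by conjugation form
(T-e, T-g, T-m, T-a) and by skeleton family (To-G, To-D, To-GL). Both
partitions sum exactly to the grand total; this identity is asserted on
every generated table in the test suite. Coefficients of variation use the
sample (n−1) standard deviation, and the default summary level is across
germplasm means (between-genotype variability), with `group_key=None` for
replicate-level summaries.

## OPLS-DA

Labels expand to a one-hot dummy matrix Y (single multi-class model, not
pairwise). Columns of X are mean-centred and unit-variance scaled by
default (`pareto` and `center` alternatives); Y is centred only.
Zero-variance columns are dropped with a warning.

Orthogonal filtering: per round, one provisional NIPALS PLS component is
fitted and its X-loading `p` is projected off an orthonormal basis of the
column space of X'Y. The resulting weight `w_o` satisfies `w_o ⊥ X'Y`, so
the orthogonal score `t_o = X w_o` has exactly zero covariance with every
dummy column (the test suite asserts |r| < 1e-6). X is deflated by
`t_o p_o'` and the process repeats. Predictive components are then standard
NIPALS PLS2 with X- and Y-deflation on the filtered matrix.

Defaults: `n_predictive = n_classes − 1`, `n_orthogonal = 1`. NIPALS
converges on relative score change < 1e-10 (max 500 iterations). If the
requested component count reaches the matrix rank it is reduced with a
warning. Signs are fixed by making the largest-magnitude X-loading of each
component positive, so fits are bit-deterministic.

Variance bookkeeping: because all score vectors are mutually orthogonal,
`‖X‖² = Σ‖t_o p_o'‖² + Σ‖t p'‖² + ‖E‖²` exactly; R²X is reported total and
split into predictive/orthogonal parts. R²Y = 1 − SS_res/SS_tot on the
centred dummy block.

Q² = 1 − PRESS/TSS with stratified interleaved ("venetian blinds") folds:
samples are ordered by class then position and dealt cyclically to k = 7
folds (configurable). The entire pipeline — scaling included — is refitted
inside each training fold; TSS is the class-mean-centred total sum of
squares of the full dummy matrix. Fold assignment is deterministic, so Q²
is a pure function of the inputs. A training fold that misses a class is
possible for very small classes and is logged.

## Correlation screening and Duncan's test

Variable-vs-WIS screening uses Pearson correlation at the germplasm level
(n = 9 scale), with the p-value from the t transform on n−2 degrees of
freedom; Spearman is available behind a flag. Flags are `*` (p < 0.05) and
`**` (p < 0.01). No multiplicity correction is applied across the 20
variables — this is a screening report, and the output carries a note
saying so.

`duncan_mrt` gates on one-way ANOVA at `alpha`; a NaN F statistic (zero
variance everywhere) counts as not significant. The least significant range
for a subset of p ordered means is
`q(protection, p, df) × sqrt(MSE/n_h)` with protection level
`(1−alpha)^(p−1)` from the studentized-range distribution, pooled-error
MSE, and harmonic-mean group size `n_h` for unbalanced designs. Range
testing is step-down with Duncan's containment rule (a difference inside a
non-significant range is non-significant), and the letter display marks the
maximal runs of mutually non-separated ordered means.

## Synthetic data: what it emulates

All noise is truncated-at-zero normal with sd = cv × mean (the underlying
normal's parameters), the simplest model that preserves positivity and
yields relative dispersions of the observed magnitude; at the default CVs
the truncation bias is negligible (< 1e-10 relative).

**Seed presets** (`sichuan9`): nine germplasms, three classes. Each
genotype is built from a target total, an aglycone fraction and a
GL-skeleton share: aglycones split GE:DE:GLE = 0.55:0.30:0.15, conjugated
mass splits malonyl:glucoside:acetyl = 0.58:0.36:0.06 (so
malonylglucosides + β-glucosides exceed 85% of every seed total), and the
G:D remainder splits 0.55:0.45. Aglycone fractions run ~5.5–5.7% in
tolerant, ~3.3–3.8% in moderate and ~1.6–2.0% in susceptible lines;
totals overlap across classes (grand mean 1.825 mg/g) so the class signal
lives in composition, not bulk concentration. Replicate cv defaults to
0.08, and n_reps defaults to 3 replicates.

**Leaf experiment**: cell means for {ND12, C103} × {CK, shade} are anchored
to the target GE and total-isoflavone values per cell; GE is the only
nonzero aglycone, and the non-GE mass is spread over the nine conjugated
forms by a fixed split (MG 0.25, MD 0.20, GEG 0.18, DG 0.15, MGL 0.10,
GLG 0.07, AG/AD 0.02 each, AGL 0.01) since only totals and GE are
constrained for leaves.

**Field trial** (`sichuan9`): sole-crop trait baselines (main stem
45 cm, internode 4 cm, hypocotyl 5 cm, 11 nodes, stem diameter 6 mm,
breaking strength 12 N at the start of bloom) are scaled per genotype by a
factor u_g solving Σ u_g (WIS_g − 1) = 0, and intercropped means are
SC × (1 + resp_i × WIS_g) with population responses (+30%, +35%, +40%,
−10%, −20%, −35%). Under this construction every trait's IS equals WIS_g
identically, so the noise-free pipeline recovers the reference WIS values
exactly — a strong end-to-end oracle. Rows model replication-level means of
ten-plant scores, hence the modest default noise_cv = 0.025; at that level
the tolerance classification is stable across generator seeds even for the
boundary genotype at WIS 0.52.

What passing tests therefore show: the algorithms recover planted
structure — index values, cell means, class geometry, orthogonal
directions — under a well-specified noise model. What they do not show:
performance under real HPLC artefacts (baseline drift, co-elution,
integration error), genotype × environment interaction, non-normal or
correlated trait noise, or class structure weaker than the presets encode.
Headline multivariate statistics quoted for real seed data are not exactly
recomputable from synthetic data; the acceptance checks use the synthetic
bounds instead.

## Problem sizes

Defaults used by the test suite and `scripts/acceptance.py`: 9 genotypes ×
3 seed replicates (27 × 20 block) for OPLS-DA; 200 replicates per cell for
leaf-mean recovery; 10 plants per genotype × system for field trials; 100
permutations for the Q² null; 2,000 simulations for the ANOVA type-I
check; 20 random seeds for the reference-PLS2 equivalence property.

## Known limitations

- The OPLS-DA handles no missing values; impute upstream.
- Duncan's test requires ≥ 2 samples per group and uses the harmonic-mean
  approximation for unbalanced designs.
- The correlation screen is marginal (one variable at a time); collinear
  variables (derived totals vs their constituents) are reported
  individually, not jointly modelled.
- Peak identification is nearest-retention-time only; no spectral
  confirmation.
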