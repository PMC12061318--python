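# Methods

`autogs` implements an environment-aware analysis chain for
multi-environment crop trials: daily weather is condensed into
developmental-stage-aligned environmental covariates, those covariates are
screened for the stage windows that linearly drive a trait across
environments, per-genotype reaction norms summarize phenotypic plasticity,
and a stacked ensemble predicts phenotypes of untested genotypes and
environments from trait-associated markers plus the reduced environmental
profile.

## Environmental parameters

Nine daily environmental parameters (EPs) are derived per environment: day
length (DL, h), growing degree days (GDD, °F·day), precipitation (PRE, mm),
photosynthetically active radiation (PAR, MJ m⁻² d⁻¹), relative humidity
(RH, %), photothermal time (PTT = GDD × DL), photothermal ratio
(PTR = GDD / DL), diurnal temperature range (DTR = Tmax − Tmin, raw
temperatures) and photothermal sensitivity (PTS).

GDD uses the maize convention: Tmax is capped at 86 °F and both
temperatures are floored at the 50 °F base before averaging, so daily
thermal time is non-negative; the base/cap pair is configurable and a °C
mode (base 10, cap 30) is provided.  Tmin is never clipped downward from
above the base — a genotype experiencing a warm night accumulates the
corresponding thermal time.  DTR and PTS are computed from the raw,
unclipped temperatures.

The PTS formula is typographically ambiguous in the envirotyping
literature this package follows; we default to the literal squared reading
(Tmax² − Tmin²) × DL² and expose the halved reading
(Tmax/2 − Tmin/2) × DL/2 as a named alternative.  Since PTS enters every
downstream step only as "some temperature-and-photoperiod covariate", the
choice affects units, not the pipeline's structure.

Missing single weather values are linearly interpolated with a logged
warning; missing whole calendar days are an error — silent gap-filling of
multi-day stretches would corrupt cumulative GDD.

## Stage segmentation and RD_EPs

Each environment's season is segmented into developmental-stage windows by
cumulative GDD from sowing: a day belongs to the first stage whose
cumulative-GDD upper bound strictly exceeds the day's accumulated thermal
time.  The default maize table has 36 stages (V0–V29, R1–R6) with bounds
at 100 + 60·k °F·day through the vegetative phase and wider reproductive
intervals up to 2640 °F·day; an 11-stage table is included for small-season
crops.  The bounds are ordinary configuration — crop- or
population-specific tables are supplied by the user.  Stages a cool or
short season never reaches are returned empty and flagged; their RD_EP
cells are missing (never zero) and are mean-imputed across environments
only where a complete matrix is required (clustering, feature assembly).

Averaging each EP within each stage window gives the 9 × 36 reduced
environmental profile (RD_EP) per environment.  Means over stage spans
A..B are day-count weighted, since windows cover unequal numbers of days.

## Critical-window search

For every EP and every stage span A..B (666 spans at 36 stages), the
Pearson correlation between the across-environment trait means and the
across-environment A..B EP means is computed; spans with |r| ≥ 0.90
(configurable) qualify.  Per EP, overlapping qualifying spans are collapsed
to the best-|r| one; ties break toward smaller spans and earlier stages so
output order is deterministic.  At least three environments are required;
degenerate (constant) trait or EP vectors are skipped with a log record,
and environments missing an EP value are dropped pairwise.

With a handful of environments, thousands of candidate correlations and
strong collinearity between thermal EPs, the search is a screening device,
not an inference: neighbouring windows and correlated EPs (GDD, PTT, PTR)
routinely co-qualify, and the test suite treats any window overlapping the
true driver as a recovery.

## Reaction norms, variance components, heritability

A genotype's plasticity is the OLS regression of its phenotype on the
critical-window EP mean across the environments where it was observed
(≥ 3 required); intercept and slope are the two PP parameters.
Environments are unweighted and no shrinkage is applied across genotypes —
each line is fitted independently.

Variance of the genotype × environment table is decomposed by a two-way
method of moments (exact on balanced data, closed form, hence directly
testable): E[MS_G] = σ²res + L·σ²g, E[MS_E] = σ²res + G·σ²e, with the
residual absorbing G×E and measurement error; negative moment estimates
truncate to zero.  A REML refinement via a crossed random-intercept mixed
model is available for unbalanced tables (validated against lme4 on a
shared fixture during development).  Broad-sense line-mean heritability is
H² = σ²g / (σ²g + σ²e/L) with L the number of environments and σ²e the
residual component — the denominator divides by L because line means
average environmental noise over L trials.

## Genotype features

QC drops markers with > 30% missing calls and multiallelic sites, imputes
remaining missing calls with the per-marker modal genotype class, then
drops markers where any observed genotype class has frequency < 0.02.
(Haplotype-based imputation such as Beagle is deliberately out of scope;
for real data it belongs in pre-processing, and modal-class imputation is
sufficient for the controlled missingness of synthetic tests.)

Trait-associated markers (TAMs) arrive as an external table with
categories Main (environment-stable), G×E, and PP slope/intercept;
E-TAMs = G×E ∪ PP.  Feature sets take each TAM plus flanking markers,
either all markers within ±37 kb or a contiguous LD walk while r² with the
TAM stays ≥ 0.5.  QTL intervals are ±1 Mb around TAMs, merged when
overlapping (coordinates 1-based, closed); co-localization counts interval
overlaps of ≥ 1 bp between two QTL sets.  Two random baselines mirror the
TAM sets: Random1 re-anchors the same number of random markers and expands
them by the same flank rule; Random2 draws uniformly exactly as many
markers as the All-TAMs feature set contains.

The bundled association screen is single-marker OLS with top genotype PCs
as covariates (Frisch–Waugh residualization, Bonferroni flags).  It exists
to generate TAM tables for end-to-end synthetic runs and is calibrated for
family-wise error; it is not a replacement for a multi-locus mixed-model
GWAS, which is an external input at the TAM-table boundary.

## Prediction

Rows are observed (genotype, environment) phenotypes; columns are marker
dosages of a chosen feature class plus, optionally, environmental
covariates — the flattened RD_EP profile (324 columns at 36 stages) or the
raw daily EP series truncated to the shortest common season.  EP columns
are identical for all genotypes within an environment, which is exactly
what lets the model transfer genotype responses to unseen environments.

The ensemble stacks gradient-boosted trees (XGBoost, LightGBM, sklearn
histogram GBM) and a Bayesian ridge regressor.  Each base learner is tuned
by a seeded random search over a documented space (tree depth/leaves,
learning rate on a log scale, subsampling, L2 regularization; 50 trials by
default, scored by internal k-fold MSE); out-of-fold predictions from an
internal 5-fold split train a non-negative linear meta-learner with
intercept.  Non-negativity makes the meta-combination an interpretable
weighting of base models and prevents sign-flipping of a weak learner.
The meta-features are the out-of-fold predictions only (no cascade of raw
features).  Everything is deterministic under the run seed
(single-threaded learners, seeded splits and searches).

A reduced "fast" search space (40–100 boosting rounds, shallow trees) is
provided for design matrices of a few hundred rows, where large capacity
only adds variance; the test-suite and the acceptance script use it
together with reduced simulation sizes (120–500 genotypes, 400–2000
markers, 6–8 environments, tuning budget 1–2, LightGBM + Bayesian ridge)
so full pipelines run in seconds to minutes on one core.

Accuracy is the Pearson correlation (PCC) between observed and predicted
phenotypes, averaged over folds; a fold with a constant vector reports a
missing PCC rather than failing.  Besides plain fivefold CV, three
hold-out designs match the breeding questions: scenario 1 holds out a
random half of the genotypes (all their rows; repeated, default 10 times,
since one random half is an arbitrary draw), scenario 2 holds out each
environment in turn, and scenario 3 crosses the two so neither the test
genotypes nor the test environment appear in training.  Fivefold CV is
unstratified; fold construction asserts the disjointness and exclusion
contracts per fold.

Feature attribution is permutation importance — the mean PCC drop over
seeded column permutations, with the sign of the feature's marginal
association.  It is model-agnostic and directly testable; explainer
libraries can be layered on top but are not a dependency.

## Synthetic trials

The generator emulates a temperate maize multi-environment trial and gives
every pipeline stage ground truth.  Genotypes are 0/1/2 dosages in
LD blocks (haplotypes copied within blocks with a 5% per-marker flip,
10 markers × 5 kb blocks by default, MAF uniform on [0.1, 0.5]).  Weather
is a sinusoidal season per environment with site offsets (SD 6 °F),
planting-phase shifts (±15 d), amplitude jitter (SD 2 °F) and day-to-day
noise (SD 6 °F); day length follows a latitude-like curve.  Seasons are
200 days so every stage is reachable in typical draws (cool draws may
leave late stages empty, which the pipeline flags and handles).

Phenotypes follow the reaction-norm model
y_ge = μ + Σβx + (s̄ + Σγx)·z_e + u_e + ε, where z_e is the standardized
mean of the target EP (default PTT) over the target window (default
V3–V6), computed through the real envparams/envirotyping code path; β and
γ are main- and slope-QTL effects on centered dosages; s̄ = 3 is the
population-average sensitivity; u_e (SD 0.3) is the environment effect not
mediated by the target EP; ε has SD 0.25.  The defaults put most of the
environmental signal through the thermal window — the regime of a
photothermally driven trait, and the regime in which a critical window is
identifiable from eight environments at all.  All components are stored,
so phenotypes reconstruct exactly and fitted slopes, windows, variance
shares and predictions can be compared to truth.

What the generator does not emulate: spatial field trends, unbalanced and
missing phenotypes at scale, dominance/epistasis, multi-trait genetic
correlations, hybrid structure (dosages are not built from parental
crosses), and real weather autocorrelation.  Passing tests therefore
demonstrate the pipeline's contracts and estimator correctness under the
assumed reaction-norm model, not performance on any real breeding program.

## Numerical choices and limitations

- Correlation/OLS degeneracies (constant vectors, < 3 points) raise or are
  skipped with logs, never silently return 0.
- Window-search ties break by |r|, then span, then start stage.
- Empty RD_EP cells are NaN; imputation happens only where a complete
  matrix is structurally required, and is logged.
- Environment clustering standardizes per EP (pooled over environments and
  windows) before Ward linkage on Euclidean distances, so EPs with large
  units do not dominate.
- With few environments, the critical-window r threshold of 0.90 admits
  chance qualifiers among ~6000 candidates; interpret secondary windows
  with caution and prefer the collapsed best-per-EP output.
- The association screen assumes a homogeneous panel; it controls
  population structure only through PCs.
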