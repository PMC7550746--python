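# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic cohort does and does not
emulate, and the numerical conventions that matter for reproducing
results.

## Data model and conventions

A cohort is a wide sample × chemical matrix of concentrations in ng/g
silicone, one row per (participant, timepoint) wristband, with a batch
label, wear metadata, and a chemical metadata table (name, CAS number,
one or more screening-panel categories — a chemical may be, say, both a
commerce chemical and a pesticide ingredient, and then contributes to
both category counts but once to the total).

**Non-detects are zeros.** A concentration of 0 means the chemical was
assayed but not found above the method's quantitation limit. Zeros are
retained in detection fractions, medians/IQRs, standardization and all
downstream analyses; no limit-of-quantitation substitution or censored
likelihood is attempted. This matches how such panels are usually
summarized (lower quartiles of 0 for chemicals detected in under 75% of
samples) and keeps every stage a deterministic function of the observed
matrix. The cost is attenuation: rank correlations and ICCs computed over
tie-blocks of zeros are biased toward 0 for heavily censored chemicals.

**Detection** is strictly `concentration > 0`, and the screening filter
is strictly `detection fraction > threshold` (default 0.60): a chemical
detected in exactly 60% of wristbands is excluded.

**Season of wear** uses meteorological months (Dec–Feb winter, Mar–May
spring, Jun–Aug summer, Sep–Nov fall) applied to the date the band was
first worn. Wear periods are ~7 days, so the start-date convention and
any majority-of-days convention almost never disagree; the mapping is
pure and total, and a season supplied in the input takes precedence.

**Quantiles** are linear-interpolation (type 7), the numpy/R default; the
convention matters only in the second decimal of printed IQRs.

## Batch-median standardization

Per chemical: subtract the batch-specific median, then z-score the pooled
adjusted values to mean 0, SD 1. The SD is the *sample* SD (ddof = 1),
i.e. the `scale()` convention of R, which analyses of this design are
typically run in; the hand-checkable consequence is that a single-batch
chemical with values (1, 2, 3) standardizes to (−1, 0, 1). The transform
parameters (per-batch medians, center, scale) are stored so a transform
fitted on one occasion can be applied unchanged to another. Fitting is
done on the first-occasion samples and applied to the second
(configurable); this keeps the second occasion on the first occasion's
scale rather than re-centering away true temporal change. Chemicals left
constant after median adjustment cannot be scaled and are rejected by
name (in the small repeated subsample the pipeline drops them with a
warning instead, since heavy censoring there is expected).

The transform removes *additive* per-batch offsets exactly — adding any
constant to all samples of one batch leaves the output unchanged — but
not multiplicative batch effects, which the source design controls in the
laboratory instead.

## Reliability

Spearman correlations use midranks, so shared non-detect zeros form tie
blocks rather than spurious agreements; a chemical with all-tied values
has no defined rank correlation and is reported missing with a warning.

The ICC comes from the random-intercept model y_it = μ + β·week_t + u_i +
e_it with Var(u) = σ²_b, Var(e) = σ²_w and ICC = σ²_b/(σ²_b + σ²_w). With
exactly two occasions per participant the REML solution has a closed
form: σ̂²_w = Var(d_i)/2 from the within-pair differences (centering the
differences absorbs the week fixed effect) and σ̂²_b = Var(m_i) − σ̂²_w/2
from the participant means, with sample variances, truncated at zero.
Truncation is why 0.00 point estimates and 0.00 CI lower bounds occur.
The closed form is verified in the tests against a numerically maximized
REML criterion (1e-6) and against statsmodels' MixedLM (1e-4, its
optimizer tolerance).

Confidence intervals are percentile bootstrap over participants — both
occasions resampled together, preserving within-person dependence — with
default 1000 resamples, degenerate resamples contributing ICC 0, and
bounds clamped to [0, 1]. Percentile (not BCa) intervals are the simplest
method consistent with a plain bootstrap description. Coverage for a true
ICC of 0.5 at n = 50 pairs measures ~94% across 200 replicates.
Participants missing either occasion are excluded. Reliability classes
follow the Rosner cutpoints with the boundaries ≤0.4 poor and ≥0.75
excellent.

## Multiply-imputed regression

Chained-equation imputation visits each incomplete variable in turn,
conditioning on all other analysis variables (including the main count
outcome — standard congeniality practice). Methods per type: predictive
mean matching with a Bayesian linear-regression draw and k = 5 donors for
continuous variables; a Bayesian logistic draw for binary variables; a
multinomial-logistic draw for multi-category variables, falling back to
observed marginal frequencies if the likelihood fit fails (e.g.
separation on a small subsample). Defaults: m = 25 datasets, 10 sweeps,
seeded per dataset from the global seed. Observed cells are never
altered; with no missingness the procedure returns m exact copies and the
pooled fit reduces to the complete-data OLS exactly. Variables missing in
>95% of rows are refused.

Analysis models are OLS with dummy coding against fixed reference levels
(less than college graduate; married; White non-Hispanic; parity 0; no
smoke exposure; fall). The total-detects outcome is modelled as
continuous OLS rather than a count GLM, following the linear-regression
convention of the design this mirrors; chemical-concentration outcomes
are the standardized values, so their coefficients are in SD units.
Pooling follows Rubin's rules (T = W + (1 + 1/m)B) with the
Barnard–Rubin small-sample degrees of freedom; the between-imputation
variance is computed after centering on the first fit so that identical
fits give exactly B = 0. No multiple-testing adjustment is applied; each
model reports its own 95% CI.

The a-priori hypothesis suite adds one exposure term at a time to the
shared covariate set. A hypothesis whose target chemical did not survive
the detection screen is skipped with a warning — the honest statement
that the relation is untestable at the achieved detection frequencies.

## SOM profiles and validity consensus

Training is batch-mode Kohonen: per epoch, assign every sample to its
best-matching unit (minimum Euclidean distance; ties to the lowest node
index), then replace every codebook vector with the Gaussian
neighborhood-weighted mean of all samples. The neighborhood radius decays
linearly from max(rows, cols)/2 to 0 over the first 90% of epochs and is
then held, so the final epochs are exact Lloyd (k-means) steps and the
quantization error is non-increasing there. Codebooks initialize from a
seeded sample of the *unique* data rows; rows are brought to a canonical
lexicographic order before training, making the fit invariant to sample
order and to row duplication (a duplicated dataset trains the same map).
Late in the anneal, a node with no best-matching samples is re-seeded
onto the worst-fit sample (classic dead-unit repair, at most one node per
epoch); without it, maps with as many nodes as data points cannot reach
the interpolation limit. Online (per-sample) training is deliberately out
of scope: batch training is deterministic given the seed.

Validity statistics, computed on occupied nodes only: WSS/BSS ratio
(lower better), Calinski–Harabasz, Dunn (single-linkage minimum
inter-cluster distance over maximum intra-cluster diameter, defined as 0
when coincident clusters make the numerator 0), mean silhouette
(singletons contribute 0), and Pearson Gamma (correlation of the pairwise
distance vector with the different-cluster indicator). All five are
checked against brute-force pairwise computations and, where available,
scikit-learn implementations.

Size selection trains every grid (r ≤ c, 4 ≤ r·c ≤ 25) with the shared
seed, ranks candidates per statistic (ordinal ranking, so ranks stay
permutations under ties), and picks the minimum mean rank; ties break
toward fewer profiles, then the squarest shape. "Most agreement across
statistics" has no canonical definition; minimum mean rank is this
package's operationalization and the full candidate × statistic × rank
table is always written so the choice can be audited. Two behaviors to
know: (1) with clearly separated planted profiles the consensus recovers
the planted count and memberships almost exactly (ARI = 1.0 on the ±3 SD
benchmark in 20/20 seeds); (2) on *structureless* data the consensus has
no well-defined optimum — WSS/BSS and Dunn improve mechanically with map
size, so the selected map tends to be fine-grained rather than minimal.
Cluster counts on weakly structured data should be read as descriptive
resolution, not as an estimated number of latent classes. Both the grid
size and the occupied-node count are reported, since "number of profiles"
can reasonably mean either.

Profile characterization reports per-profile membership, median
standardized concentration per chemical, and flags chemicals with profile
median ≥ 1.0 SD as "exceptional" (an explicit convention standing in for
verbal "high exposure" labels). Profiles under 10 members are listed as
rare and excluded from the covariate breakdown.

## Synthetic cohort

Concentrations follow a left-censored base-10 lognormal: log10 x = μ_c +
profile shift + batch shift + covariate effects + σ_c ε, censored to 0
below the chemical's quantitation limit. The default cohort emulates the
shape of a mid-sized pregnancy-cohort deployment: 255 participants, 40
chemicals (the 17 reference-panel chemicals with their reported detection
frequencies, medians and ICCs, plus 23 sporadically detected fillers), 3
analytical batches (additive shifts, SD 0.15 log10), five latent profiles
(a dominant ~58% low-exposure profile and several small high-exposure
profiles), covariate effects (nail polish → a plasticizer, summer → a
UV-blocker, winter → a musk, small whole-panel seasonal and education
shifts), ~28–30% missingness on education, marital status and smoke
exposure, and a 20-participant two-occasion subsample with a +0.2 log10
second-occasion shift and per-chemical (σ²_b, σ²_w) chosen to reproduce
the panel's ICC spread. Quantitation limits are calibrated against the
full mixture (mean shift plus variance inflation from profiles, batches
and covariates) so marginal detection frequencies hit their targets; with
a sampling SE of ~3% at n = 255 and several panel chemicals targeted
near the 60% screen, the retained-chemical count realistically varies by
one or two across seeds.

What the generator does **not** emulate: multiplicative or
heteroscedastic batch effects, correlated measurement error between
chemicals beyond the planted profile structure, informative (non-MCAR)
covariate missingness, uptake kinetics / wear-duration effects, and the
full 1,530-chemical long tail (23 fillers stand in for it, which is why
the default cohort's median of ~20 detects per wristband sits slightly
below the ~23 a full-width screen yields). Passing recovery tests on this
generator therefore demonstrates correctness of the estimators under the
stated model, not robustness to these unmodelled features.

All draws flow from one seeded generator; a fixed config + seed yields
byte-identical CSVs, and the ground truth (profile labels, true ICCs,
planted effects, expected detection fractions) is written alongside.

## Problem sizes in the tests and acceptance script

The test suite's recovery studies use sizes chosen to keep the default
run fast while leaving Monte-Carlo margins well clear of the thresholds:
the SOM benchmark runs 20 seeds at n = 200; ICC coverage uses 200
replicates of 50 pairs with 1000 bootstraps; the MI recovery check uses
20 cohort replicates at n = 255 with m = 5 imputations against an
empirical large-n (20,000) truth; the end-to-end determinism check runs a
reduced pipeline (3 imputations, 50 bootstraps, 3 SOM candidates) twice
and compares bytes. `scripts/acceptance.py` repeats the worked examples
and recovery studies (10 SOM seeds, 100 coverage replicates) and one full
default pipeline run.

## Known limitations

- Zeros-as-values censoring attenuates correlations and ICCs for heavily
  censored chemicals; a censored-likelihood treatment is out of scope.
- The ICC closed form assumes the balanced two-occasion design;
  three-plus occasions would need the iterative REML fit.
- The consensus map size is an interpretation of "most agreement" and is
  unstable on weakly structured data (see above).
- Imputation assumes missing-at-random given the analysis variables.
- The reference panel's printed values carry two significant digits;
  worked-example agreement is exact only at that precision.
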