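# Methods

This note documents the models, procedures and design choices behind
`helpchoice`, in the order a full analysis runs.

## Synthetic study generator (`helpchoice.synth`)

The generator emulates a two-survey design: a decision survey in which
participants rate willingness to help (WTH) on a 6-point scale for a subset
of short helping scenarios, and a rating survey in which an independent
rater pool scores each scenario on 15 five-point motivation dimensions.

**Scenario latents.** Each of `n_scenarios` (default 100) scenarios gets an
independent standard-normal true benefit and true cost, a uniform(0, 1)
urgency, a semantic cluster id (balanced assignment over
`n_semantic_clusters`, default 14) and an embedding vector drawn as its
cluster centroid plus isotropic noise (centroid spread 10x the noise SD, so
clusters are well separated).

**Motivation ratings.** Twelve of the 15 dimensions follow a planted
two-factor structure: rating = 3 + loading·(benefit, cost) + rater bias +
noise, discretized to 1..5. The default loading matrix puts eleven items
primarily on the benefit factor (loadings 0.70-0.90) and self cost on the
cost factor (0.90); the three not-helping-cost items (other cost, guilt,
negative self-concept) carry secondary cost loadings of 0.40-0.45 below
their benefit primaries. The secondary loadings matter: a second factor
indicated by a single standardized variable has a correlation-matrix
eigenvalue of exactly 1 and can never be retained by parallel analysis, so
a generator meant to emulate a detectable two-factor structure must spread
the cost factor over more than one item. Item assignment under the
max-loading & |loading| > 0.3 rule is still 11 vs 1. Urgency (q02) tracks
the latent urgency; the two summary questions (q11 of q07-q10, q15 of
q13-q14) are noisy copies of their constituents' means and are excluded
from factor analysis. The rating design is balanced and cyclic: every
scenario receives exactly `n_raters_per_scenario` raters (default 28), each
rater scoring `scenarios_per_rater` (default 20) distinct scenarios.
Defaults for noise: rating noise SD 0.5, rater bias SD 0.2 — large enough
that individual ratings are coarse, small enough that 28-rater consensus
means track the latents at r > 0.9.

**Agents and traits.** Each of `n_participants` (default 215) agents has
generative parameters for the configured utility model (defaults:
β ~ U(1, 4), w_cost ~ U(0.1, 0.9), b ~ truncated normal(0.2, 0.4) on
[-0.8, 1.2]). Questionnaire-like trait scores (empathic concern, social
value orientation, reward responsiveness, behavioural inhibition, Big-Five
subscales, plus sex and age) are drawn jointly with the parameters through
a Gaussian copula, so target trait-parameter correlations (defaults: +0.3
bias-agreeableness, +0.3 bias-empathy, +0.2 bias-SVO, +0.3 w_cost-BIS,
-0.2 w_cost-RR) are hit up to sampling error and mild marginal-transform
attenuation. An infeasible (non-PSD) correlation request is a
configuration error.

**Decisions.** Each agent rates `trials_per_participant` (default 50)
scenarios sampled without replacement. Cost/Benefit inputs are the min-max
normalized true latents (the same normalization the analysis applies to
factor scores); utility and P_help follow the agent's model; help is a
Bernoulli draw. The ordinal WTH level is derived from P_help by six
equal-probability bins with the help boundary at 0.5; when the Bernoulli
draw lands on the other side of 0.5 than the bin, the level is mirrored
(7 − level), so help = 1 ⇔ level ≥ 4 always holds. This generative link
between the ordinal and binary responses is a modelling convenience (the
binary decision is the quantity the choice models address); it is needed so
the continuous rating-model robustness check has ordinal data to fit. Each
participant also gets three repeated scenarios (identical re-ratings by
default — the generator's agents are perfectly reliable on immediate
repeats) and three attention-check slots (passed by default).

**Planted QC violations.** `inject_qc_violations` plants decisive
violations: attention failers (2 of 3 checks failed), inconsistent
repeaters (2 repeats flipped across the help boundary), straight-liners
(constant "somewhat likely"), can't-imagine flaggers (10 scenarios),
low-variability rater-question pairs (constant 3s) and outlier pairs
(alternating 4/5, mean 4.5). `truth.json` records both the planted list and
a rule-level ground truth computed by a deliberately plain per-participant
loop over the documented rules. The loop exists because the 3-SD outlier
rule is self-referential: on clean Gaussian data it flags roughly 0.3% of
rater-question pairs at any noise scale, so "exclusions == planted list"
cannot hold at every seed; "exclusions == independently evaluated rules"
can, and is what the tests assert (with the planted list verified to be a
subset).

**Determinism.** Every table draws from `default_rng([seed, offset])` (and
`[seed, 4, participant_id]` per agent for decisions), so tables regenerate
independently and identically; the test suite replays the decision stream
with an explicit loop and requires exact agreement.

## Quality control, consensus and reliability (`helpchoice.qc`)

Decision-survey exclusions, in precedence order (a participant is counted
once, under the first rule that fires): ≥2 failed attention checks, ≥2
inconsistent binarized decisions across the three repeats, straight-lining
(SD of the WTH codes below 0.5 — computed on the −5..5 code scale the
ratings are reported on), and ≥10 can't-imagine flags. Surviving
participants' flagged trials are dropped, and only the first rating of each
repeated scenario is kept. The 6-point level maps to codes
(1..6) → (−5, −3, −1, 1, 3, 5); help = 1 iff the code is positive.

Rating-survey exclusions: raters with ≥2 failed attention checks are
dropped; then, per rater-question pair (after dropping flagged scenarios),
low variability (SD < 0.1 across the rater's scenarios) takes precedence
over the outlier rule (rater mean more than 3 SD from the group mean of
rater means). Pairs with fewer than two ratings are skipped with a warning
(their SD is undefined). Consensus ratings are arithmetic means over
surviving raters, with counts, and a warning when a scenario falls below 25
raters.

**ICC(A,k)** (two-way random effects, absolute agreement, average
measures) is computed from the mean squares as
`(MS_scenario − MS_error) / (MS_scenario + (MS_rater − MS_error)/n)`.
On complete matrices this is exact and matches pingouin's ICC(A,k) to
machine precision (asserted in tests). With missing cells the mean squares
are estimated from all available cells via an unbalanced two-way OLS ANOVA
(each effect adjusted for the other); this expected-mean-squares route is
an approximation — full missing-data ICC estimation is out of scope — and
the complete-case path is preferred automatically whenever at least two
raters span all scenarios.

## Factor analysis (`helpchoice.factors`)

The 12 consensus motivation dimensions are reduced by exploratory factor
analysis. The factor count comes from parallel analysis: correlation-matrix
eigenvalues are compared rank-by-rank against the mean eigenvalue of
standard-normal data of identical shape (1000 simulations by default;
the mean criterion is the common default, the alternative 95th-percentile
criterion is stricter and was not needed). Retention stops at the first
rank that fails; the count is invariant to column order and affine
rescaling of columns.

Extraction is minimum-residual (ULS): uniquenesses are optimized by
L-BFGS-B so the off-diagonal residuals of `R − ΛΛ'` are minimized, starting
from squared multiple correlations. Rotation is varimax (Kaiser-normalized)
by default; promax (power 4) is available as the oblique robustness check
and also reports the factor correlation matrix. Each factor's sign is fixed
so its maximal-|loading| item loads positively. Factor scores use the
Thurstone regression method, `scores = Z R⁻¹ S` with S the structure
matrix. Total variance explained is the sum of squared rotated loadings
over the number of items. An item is assigned to the factor where its
|loading| is maximal, provided it exceeds 0.3; otherwise unassigned.

The factor holding the self-cost question becomes Cost, the other Benefit;
both are min-max normalized to [0, 1] (monotone, so ranks are preserved).
Scenarios are split into four quadrants at the per-factor medians (high =
strictly above) and urgency is binarized by a median split of its consensus
rating.

Per-motivation predictive value is quantified with a linear mixed model,
WTH ~ motivation with per-participant random intercepts and slopes
(statsmodels MixedLM, REML — a library estimator is appropriate here; the
reported quantity is the R² decomposition). Marginal R² is
`var_fixed / (var_fixed + var_random + var_resid)`; conditional R² adds
`var_random` to the numerator. With random slopes, `var_random` is the
observation-wise mean of `z'Gz` with `z = (1, x)` (Johnson's extension of
the Nakagawa decomposition). Singular random-effect fits are flagged, not
discarded.

## Choice models (`helpchoice.choice`)

Parameter boxes: β ∈ (0, 10] (lower bound implemented as 1e-6),
w_cost, w_benefit ∈ [0, 1], b ∈ [−10, 10] (wide enough that the softmax is
behaviourally saturated at the edges), α ∈ (0, 10], w_cb ∈ [−5, 5],
w_u ∈ [0, 5]. Nesting identities (2.1 at α=1, 2.3 at w_cb=0, 2.4 at w_u=0
all reduce to 2.0) hold exactly and are asserted on grids.

Fitting is maximum likelihood with probabilities clipped at 1e-12 (keeps
the NLL finite under separation), 10 Latin-hypercube starts within the
bounds, L-BFGS-B, best NLL kept with ties broken by the smaller parameter
norm. Diagnostics: pseudo-R² is McFadden-style against a chance null
(`n·ln ½` — chosen over the fitted bias-only null so model 1.0 itself has a
defined value), AIC = 2k − 2LL, BIC = k·ln n − 2LL. Leave-one-out accuracy
refits on each n−1 subset and predicts help iff P ≥ 0.5 (ties predict help,
configurable); refits can reuse the full-data optimum as a warm start.

**Parameter recovery** draws parameter sets from behaviourally plausible
ranges (β ∈ [1, 5], w_cost ∈ [0.1, 0.9], b ∈ [−1, 1] for model 2.0),
simulates one dataset per set, refits, and correlates true with recovered
values per parameter. Refits are bounded to the generative ranges by
default (`fit_bounds="sampling"`), the usual convention in recovery
studies: with the model's wide b box instead, occasionally separable
datasets (all-help or all-not-help) push the bias estimate to the box edge
and those few outliers dominate the Pearson correlation. A caveat worth
stating plainly: at 50 trials with uniform cost/benefit and β as low as 1,
w_cost is weakly identified — a Bayes posterior-mean oracle with the true
prior tops out near r ≈ 0.70, and the MLE sits near 0.59 — so w_cost
recovery at that scale should be read as moderate, not strong. It climbs
above 0.74 by 200 trials and 0.8 by 500.

The **rating model** is the robustness variant: it predicts the ordinal
WTH code as `scale · U` (β dropped, scale > 0 added) and minimizes MSE.
Across simulated participants its w_cost estimates correlate with both the
truth and the decision model's estimates (r > 0.7 in tests).

## Representational spaces (`helpchoice.spaces`)

The decision-space dissimilarity between scenarios x and y averages, over
the n raters who rated both (the same joint-rater set enters both terms),
half the mean absolute per-rater WTH difference plus half the absolute
summed difference. It equals a naive double loop to 1e-12 in tests. All
produced RDMs are validated for symmetry, zero diagonal, non-negativity and
finiteness. The motivation RDM is the 2-D Euclidean distance on (benefit,
cost), with per-axis absolute-difference component RDMs. The semantic space
is a cosine-metric UMAP (n_neighbors 15, min_dist 0.1, fixed seed) of the
scenario embeddings to 2-D; its RDM is Euclidean on those coordinates and
clusters are Ward agglomerative on the same coordinates (12 by default).
Running the clustering in the 2-D embedding rather than the raw embedding
space keeps the clusters aligned with the visualized map; on well-separated
synthetic clusters the labels recover ground truth (ARI ≥ 0.9). The MDS
embedding of a precomputed RDM is metric SMACOF (sklearn, random init,
fixed seed, stress reported).

RSA correlates upper-triangle vectors (Pearson); the null applies a single
random scenario permutation jointly to the rows and columns of one RDM
(preserving its internal structure and entry multiset), and p is the
proportion of null correlations strictly greater than the observed one — a
one-sided test by construction; a +1/(N+1)-smoothed variant avoids exact
zeros. Calibration is verified empirically (type-I rate ≈ 0.05).

The decision RDM is decomposed into a mean-WTH RDM (absolute differences of
scenario means) plus the OLS residual of regressing its entries on the
WTH-RDM entries, reassembled symmetrically; the residual is orthogonal to
the predictor by the normal equations. RDM regressions z-score both sides
so coefficients are standardized betas, report SEs and 95% CIs, and warn
when the predictor matrix is ill-conditioned (condition number > 1e8).
Quadrant comparisons use Welch's one-way ANOVA (Welch-Satterthwaite df,
partial η²) with Games-Howell post-hocs via pingouin; the two-group case
reduces to the squared Welch t, asserted numerically.

## Individual differences (`helpchoice.stats`)

Correlations are Pearson r with a two-sided permutation p (shuffle one
vector, compare |r|, +1/(N+1) correction) and a percentile bootstrap 95%
CI; Bonferroni adjustment multiplies by the declared family size (traits
and model-parameter hypotheses form separate families in the pipeline).
Group comparisons are Welch's t (two groups) or Welch's ANOVA (more), with
D'Agostino-Pearson normality, Levene and Bartlett diagnostics reported
alongside. Trait-by-category effect grids median-split each trait (high =
strictly above the median, ties to low), average each participant's WTH per
scenario category, and report Cohen's d (pooled SD; positive = high-trait
group helps more) with bootstrap CIs; cells with a degenerate split are
marked not applicable. Missing trait values are dropped pairwise.

## Pipeline (`helpchoice.pipeline`, CLI `helpchoice`)

Stages run in dependency order: simulate (or load CSVs) → QC → consensus +
reliability → factors (+ per-motivation mixed models) → choice-model fits
and comparison → spaces → trait statistics. Configuration is a JSON file
with per-stage settings; the global seed feeds fixed sub-streams per stage,
so a rerun with the same configuration is byte-identical (the timing log
aside). The spaces stage drops scenarios with zero rater overlap against
some other scenario (possible at small participant counts) before building
the decision RDM, logging each drop. A manifest records the configuration,
seeds, input hashes, per-stage outputs and package version.

## Problem sizes and limitations

The test suite and acceptance script run everything at desk scale, chosen
to exercise each procedure with comfortable statistical margins: recovery
at 100 parameter sets × 25/50/200 trials, model selection at 50 simulated
participants, calibration checks at 200-500 replicates of 500-2000
permutations, the end-to-end determinism check at 30 scenarios × 20
participants. The generator's defaults mirror the full study shape (100
scenarios, 215 participants × 50 trials, 28 raters per scenario).

What passing tests do and do not show: the synthetic data are well
specified by construction — ratings really are a linear two-factor model
plus noise, decisions really come from the softmax utilities, and traits
are Gaussian-copula coupled. Real data bring misspecification the generator
does not emulate: raters drift over time, ordinal scales are used
idiosyncratically, motivation dimensions can load on more than two factors,
and decisions may depend on scenario features outside cost/benefit/urgency.
Green tests certify the machinery (estimators, rules, statistics) against
known truth, not the substantive adequacy of the model for any human
dataset. Other known limitations: the incomplete-data ICC is an
expected-mean-squares approximation; LOO accuracy is computed by full
refitting and is the one expensive diagnostic (off by default in the
pipeline); β is weakly identified at typical per-participant trial counts
and its recovery correlations are accordingly modest; and the partial-η²
CI for Welch ANOVA is reported by bootstrap rather than a closed form.
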