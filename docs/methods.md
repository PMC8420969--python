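# Methods

## Feature extraction

Input is a tidy event table: one row per gated single cell with a sample id,
a stimulation condition (`unstim`, `LPS`, `IFNa`, `IL`), one of 34 disjoint
subset labels, and 11 non-negative marker intensities (ion counts).  All
events sit inside the singlet live leukocyte gate; every subset except
granulocytes additionally sits inside the mononuclear gate.

Three feature classes are computed per sample:

* **frequency** (percent): subset events over mononuclear events, except
  granulocytes, which are referenced to all leukocyte events;
* **basal** (arcsinh units): `asinh(median(x)/5)` of a protein's intensity
  over the subset's unstimulated events (cofactor 5, the mass-cytometry
  standard; the even-length median is the midpoint of the two central order
  statistics);
* **response** (arcsinh-difference units): stimulated minus unstimulated
  arcsinh-median, computed only for (subset, protein, stimulus) triples
  admitted by the penalization mask.

The **penalization mask** encodes receptor/pathway plausibility and is a
function of the panel alone: MAP-kinase/NFκB-axis readouts (pMAPKAPK2, pP38,
pERK1/2, pNFκB, pS6, pCREB, IκB) after LPS in the eight myeloid subsets;
STAT1/3/5/6 after IFNα in all subsets; STAT3/5/6 and pS6 after the
interleukin cocktail in all subsets.  With the default 34-subset panel this
yields 34 + 374 + 328 = 736 features.  The mask is fully overridable — the
composition of the original supplementary matrix is approximated, not
reproduced.

**Empty populations.** A subset with no events in a required condition
yields a missing value.  Features missing in more than 20% of samples are
dropped (recorded in `FeatureMatrix.dropped`); remaining missing values are
imputed with the feature median (`FeatureMatrix.imputed`).  This keeps the
matrix complete for the penalized regression while flagging sparse
populations.

## Pre-processing and univariate screening

Two sequential filters remove noisy or uninformative features: drop features
whose across-sample variance (n−1 denominator) is strictly below the 75th
percentile (linear-interpolation quantile) of all feature variances, then
drop features whose absolute across-sample median is strictly below the
median of those absolute medians.  Ties with a threshold are kept, so the
surviving set is never empty.  The filter order follows the stated
procedure; computing both filters on the unfiltered matrix is available via
`preprocess(..., sequential=False)`.  Note the second filter compares
percent-scale frequencies with arcsinh-scale signalling features on a common
absolute scale; this is deliberate and mirrors the source procedure.

Univariate screening computes per-feature Spearman ρ against GA with
tie-corrected ranks, two-sided p from the t approximation (appropriate for
n = 45 continuous features), and Benjamini–Hochberg step-up FDR across all
tested features.  Constant features have undefined rank correlation and are
excluded from the FDR family.

## The immune-age model

`ImmuneAgeModel` regresses GA (weeks) on the standardized feature matrix
with the glmnet-parameterized elastic net.  The search grid is
α ∈ {0.1, …, 1.0} by a 50-point log-spaced λ path per α running from
λ_max = max|Xᵀy|/(n·α) down three decades.  For every grid point, n = 45
leave-one-out folds each produce one blinded prediction; standardization
(feature centre/scale, response centre) is recomputed inside each training
fold, so no statistic of the held-out sample enters training.  The grid
point minimizing LOOCV mean squared error is selected, ties broken toward
larger λ then larger α (more regularization); reported predictions are the
blinded LOOCV predictions at that point, and coefficients come from a
full-data fit there.

Performance is the Spearman correlation between blinded predictions and true
GA.  Two caveats are built into the reporting:

* Because the same LOOCV errors select the hyperparameters and assess the
  model, the estimate is mildly optimistic.  `fit(nested=True)` runs an
  inner LOOCV per outer fold to remove the optimism at ~n-fold extra cost.
* When the selected model is **empty** (all coefficients zero), the LOOCV
  predictions are the training-fold means, which are anti-monotone in the
  held-out response *by construction* (Spearman −1 without any feature
  information).  Performance is then reported as NaN — "no model" — rather
  than a spurious negative correlation.

## Bootstrap stability selection

`results.bootstrap(B, seed)` refits the elastic net on B resamples of the
cohort drawn with replacement and tallies, per feature, the number of
resamples with a nonzero coefficient; resamples with constant GA are skipped
and excluded from the effective B.  The default resample fits use
*stability hyperparameters* rather than the prediction-optimal pair: the
mixing α is fixed at the smallest grid value, because the ridge-leaning
elastic net's grouping effect selects correlated feature blocks together
instead of an arbitrary single representative per block (at the sparse
MSE-optimal solution, block members split the selection "votes" and no
individual feature appears stable); the penalty is the one-standard-error
LOOCV λ at that mixing — the strongest penalty whose cross-validated error
is within one SE of the minimum, the standard parsimony rule.  The
prediction-optimal pair remains available (`hyperparams="selected"`), as
does per-resample re-tuning (`retune=True`).

The **informative set** is every feature selected in at least
`threshold_frac · B` resamples.  The default fraction is 0.6, inside the
conventional stability-selection range; the literal "selected at least once"
reading is recovered with `threshold=1`, but at n = 45 it marks nearly every
surviving feature informative and is not a meaningful selection rule.  Note
a genuine small-sample limit: a pure-noise feature whose chance correlation
with GA reaches |r| ≈ 0.45 is stably re-selected in roughly half of realized
datasets — stability selection cannot distinguish it from a weak true
feature at this n, so an occasional stray feature in the informative set is
expected behaviour, not a defect.

## Correlation network and communities

Nodes are features; an undirected edge joins pairs with |Pearson r| strictly
greater than 0.8 (computed across samples; zero-variance features excluded;
the signed r is stored).  Communities are Louvain modularity maximization on
the informative-subset-induced subgraph with |r| edge weights, deterministic
given a seed; isolated nodes form singletons.  Coverage at k is the fraction
of informative features inside the k largest communities.  The 2-D layout is
classical (Torgerson) MDS on distances 1 − |r|, with non-adjacent pairs at
distance 1 — an eigendecomposition, hence deterministic.

## Confounder analysis

For each of nine clinical covariates (fetal sex, steroid-to-birth interval,
rupture-of-membranes duration, labor duration, gestational diabetes,
first-trimester HbA1c, preeclampsia, severe preeclampsia, GBS status), GA is
regressed by OLS on an intercept, the blinded prediction, and that single
covariate.  Rows with a missing covariate value are excluded listwise — in
particular the steroid-interval regression uses only preterm samples, since
the interval is structurally undefined at term.  Each coefficient's p-value
is the partial F-test (identical to the squared-t for one coefficient): the
prediction p asks whether the model remains associated with GA given the
covariate; the confounder p asks whether the covariate itself is.  Binary
covariates are coded 0/1; unknown GBS status is missing.  A covariate
correlated with the predictions beyond |r| > 0.999 raises a collinearity
flag and suppresses both p-values.

## The synthetic cohort generator

The generator emulates the *statistical structure* of the study, not any
individual infant:

* **Cohort.** 45 samples: 25 term GA drawn stratified-uniform on [37, 41] w
  and 20 preterm on [25, 37) w (jittered evenly spaced positions — uniform
  marginals with guaranteed coverage of the early-preterm range).
  Covariates are drawn independently of the immune features, except the
  steroid-to-birth interval, which exists for every preterm and no term
  sample, and preeclampsia, which is more prevalent preterm.
* **Composition.** Per sample, a granulocyte share of leukocytes
  σ(logit) with logit linear in GA plus Gaussian noise, then a softmax over
  the 33 mononuclear subsets with log-weights linear in GA plus noise.
  Anchors: granulocytes 58% of leukocytes at the 39 w anchor and 24.5% at
  27.5 w; T-lymphocyte subsets ≈ 47% of leukocytes below 30 w; granulocyte
  logit noise (0.44 shared + 0.12 own) sized so the granulocyte-frequency /
  GA Spearman is ≈ 0.77.  Counts are multinomial with `events_per_condition`
  (default 5,000) trials, the same latent composition across all four
  conditions.
* **Signalling.** Event intensities are `5·sinh(z)`, `z ~ N(µ, 0.45)`
  truncated at zero ions, so the arcsinh-median of a population equals its
  location µ by construction.  µ is the basal location (plus the response
  amplitude under stimulation), each linear in GA per (subset, protein[,
  stimulus]) with per-sample noise.
* **Correlated blocks.** Five latent per-sample factors tie the
  GA-informative features into dense blocks: (0) innate frequencies rising
  (granulocytes, classical monocytes, CD16⁺ NK), (1) regulatory/invariant
  T-cell frequencies falling (Treg, CD161⁺CD4⁺, CD161⁺CD8⁺, NKT-like),
  (2) basal MAP-kinase/NFκB tone in the five APC subsets falling,
  (3) LPS-evoked MAP-kinase/NFκB responses in monocytic APCs rising
  (weakest in non-classical monocytes), (4) IFNα-evoked STAT3 (and weaker
  STAT1) responses in cytotoxic lymphocytes rising.  Within a block, GA
  slope and factor loading scale together per feature, so blocks are
  approximately one-factor structures with within-block |r| ≈ 0.85–0.95 —
  the regime in which the |r| > 0.8 network resolves them as communities.
  Uninformative basal pairs sit at low quiescent levels (arcsinh 0.3–1.2)
  with independent noise.
* **Ground truth.** `ground_truth_features(config)` returns exactly the
  features whose configured GA slope is nonzero (76 by default, spanning the
  five blocks), enabling recovery testing of the bootstrap.
* **Determinism.** The uninformative parameter tables are drawn once from a
  fixed internal RNG and are part of the default configuration; the
  simulation seed controls only the sampling stream.  Identical
  (config, seed) reproduces byte-identical tables.

**Calibration.** The generator's defaults were calibrated once against the
study-scale conditions — term/preterm composition anchors, the
granulocyte/GA correlation, an end-to-end blinded LOOCV ρ ≈ 0.85, recoverable
planted blocks — and then frozen; they are not tuned per run.

**What the generator does not emulate.** Instrument artifacts (bead drift,
doublets, barcode crosstalk, spillover), gating uncertainty, heavy-tailed
or zero-inflated marker distributions, covariate–immune confounding beyond
the steroid/preeclampsia structure, nonlinear GA trajectories, and the full
empirical covariance of a real immunome (features outside the five blocks
are conditionally independent).  Passing tests therefore demonstrate that
the pipeline recovers the encoded structure at the study's n — not that it
would perform identically on real cord-blood data.

## Numerical conventions and problem sizes

Coordinate descent (scikit-learn `enet_path`) with tolerance 1e-3 inside
LOOCV folds and 1e-4 for final fits; cyclic updates, hence fully
deterministic.  Correlations are clipped to [−1, 1] before thresholding.
Percentiles use linear interpolation.  Bootstrap RNG streams are spawned
per iteration from the given seed.

The test suite and the acceptance script run the full study scale (45
samples × 4 conditions × 5,000 events) for the calibrated checks, averaging
stochastic quantities over five generator seeds, and reduced event counts
(300–400 events per condition) for null-safety sweeps, where subset medians
are already stable.  Bootstrap checks use B = 200; production analyses
default to B = 1,000.

## Known limitations

* Single (non-nested) LOOCV both tunes and scores the model, exactly as in
  the emulated design; the optimism is documented and a nested mode exists.
* The informative set at n = 45 can contain isolated chance features (see
  above); community coverage and recovery rates are reported against that
  reality.
* The confounder regressions inherit OLS assumptions (linearity,
  homoscedasticity) and are one-at-a-time by design; no multivariable or
  causal adjustment is attempted.
* Percent-scale and arcsinh-scale features share one absolute-median filter
  threshold; a per-class filter would behave differently and is not offered
  because fidelity to the emulated procedure takes precedence.
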