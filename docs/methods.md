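# Methods

`polytrainsel` studies how the *composition* of a genomic-prediction
training set affects prediction accuracy in autotetraploids, using a
synthetic stand-in for a potato-style diversity panel. This note records
the models, the defaults and why, the numerical choices, and what the
synthetic benchmark can and cannot show.

## The synthetic panel

`simulate_panel` draws a dosage panel under the Balding–Nichols model.
Each biallelic marker j has an ancestral alternate-allele frequency
p_j ~ Uniform(0.05, 0.95); each of K subpopulations draws its own
frequency p_jk from a Beta distribution with mean p_j and variance
F·p_j(1−p_j); each individual's dosage is Binomial(q, p_jk) with q = 4.
F (`fst_target`) is the single differentiation knob.

Defaults reproduce the study conditions: 190 individuals, 3,262 markers,
3 subpopulations with proportions (0.5, 0.3, 0.2) — a dominant group and
two smaller ones, as after merging market classes — and F = 0.012, which
puts pairwise Fst estimates in the 0.01–0.02 range and the leading
principal component under 10% of the variance (the "weak structure"
regime). The marker map is 12 chromosomes (the potato karyotype) with
uniform random positions; the map feeds only QC and I/O, never the models.

Two deliberate simplifications, both visible in the results:

* **Markers are independent** (no linkage disequilibrium). The effective
  number of independent chromosome segments therefore equals the marker
  count, which caps GBLUP accuracy near √(nh²/(nh² + m)) — about 0.2 at
  n = 150 with m = 3,262. Real SNP-array panels have strong local LD and
  much lower effective dimensionality, hence their far higher accuracies.
  Passing benchmarks here demonstrate correct machinery and the *relative*
  behaviour of samplers and models, not the absolute accuracy levels of a
  real panel.
* **Individuals are unrelated within subpopulations.** The relationship
  matrix of the synthetic panel is therefore nearly constant-diagonal with
  off-diagonal entries that are almost pure estimation noise. A real
  diversity panel contains families and shared breeding ancestry, which is
  what relationship-based training-set optimisation exploits. This also
  explains why the among-group AMOVA fraction of the synthetic panel sits
  near F (≈ 1%) rather than the much larger among-group fractions reported
  for real panels at comparable pairwise Fst: in real data, within-group
  relatedness shrinks the within-group variance components.

`simulate_trait` builds additive genetic values g_i = Σ_j β_j d_ij over
`n_qtl` randomly placed QTL (Gaussian, Laplace or fixed effects;
optional pairwise multiplicative epistasis). Residuals are drawn Gaussian,
then centred, orthogonalised against g in-sample, and scaled so the
realized variance ratio var(g)/var(y) equals the target h² *exactly* in
every replicate — this makes heritability-recovery checks sharp instead of
Monte-Carlo-fuzzy. Default trait heritabilities are 0.91, 0.85 and 0.67
(high to intermediate broad-sense values typical of tuber morphology and
sugar-content traits), with 20 QTL each (a sparse architecture: sugar
traits in potato are thought to be controlled by few loci).

## Marker QC

`qc_filter` removes monomorphic markers, unmapped markers (chromosome "0"
or empty), markers with minor allele frequency strictly below 5%
(allele frequency = mean dosage / q over non-missing calls; a marker at
exactly 5% is kept), and markers missing in strictly more than 30
individuals (an absolute count tied to the 190-line panel;
`max_missing_frac` is the size-independent alternative). A marker can fail
several filters; the report attributes each removed marker to its first
failing filter in the order monomorphic → unmapped → MAF → missingness and
also records per-filter union counts, so both accountings are available.

## Distance measures

All four measures run on pairwise-complete markers; per-pair sums are
renormalised by the effective marker count so values stay comparable
across pairs with different missingness.

* **Nei**: allele proportions p = d/q and 1−p per locus; one global ratio
  across loci, D = −ln(Σ cross-products / √(Σ squares · Σ squares)).
  Orthogonal profiles give D = +∞ (kept as a sentinel; maps to similarity
  0). The per-locus-average variant was considered and rejected in favour
  of the single printed ratio.
* **Euclidean**: √Σ(X_j−Y_j)² on raw dosages, no centring or scaling;
  with missing data the sum is rescaled by r/r_eff to the all-marker scale.
* **Jaccard**: Σ min(X_j,Y_j) / Σ max(X_j,Y_j) — a ratio of sums. The
  formula is already a similarity in [0,1]; no further transform is applied
  (treating "conversion to a similarity matrix" as the identity).
* **Kosman–Leonard**: shared allele copies min(X_j,Y_j) + min(q−X_j,q−Y_j)
  out of q, averaged over markers. For biallelic dosages this equals
  1 − Manhattan/(q·r), a closed form used as a cross-check.

`to_similarity` maps Euclidean distances through 1 − D/max(D) and
unbounded measures (Nei) through clamp(1 − D, 0, 1); the clamp is needed
because 1 − D can be negative while the radial-exclusion sampler requires
entries in [0,1]. Matrices are compared by a Mantel test (Pearson r of
lower-triangle entries; permutation p-value counting the identity
permutation so p > 0).

## Kinship

See the module docstring for the centred VanRaden form
A = QQ′ / (2Σp_j(1−p_j)) with Q the column-centred recode
W = (d−q/2)/(q/2). Missing dosages are mean-imputed in W for kinship and
prediction only (distances use pairwise deletion); mean imputation keeps A
positive semidefinite. A 1e-6 ridge is added to A's diagonal before any
inversion inside the CD machinery.

## Population structure

AMOVA-style variance partitioning runs at the **allele-copy level** by
default: each individual contributes its q Bernoulli allele copies, so
under the generator the among-group variance fraction and the pairwise
two-group Phi statistic both estimate the Balding–Nichols F directly (the
pairwise recovery is tested at ±30% over 50 replicates). The
genotype-level coding (`unit="dosage"`, the squared-Euclidean AMOVA on
dosage vectors) is also available; because binomial within-individual
sampling then sits in the within-group component, it inflates the among
fraction to roughly qF/(qF+1−F) ≈ 4F for small F. A Hudson-style
frequency-based Fst estimator is available behind `method="hudson"`.
Subpopulation labels are taken as given (the market-class merging of a
real analysis is a judgment step, not an algorithm reproduced here).

## Samplers

* **SRS**: uniform without replacement.
* **Stratified**: proportional quotas n·N_S/N rounded by largest
  remainder (exact reconciliation to n), SRS within strata; a single
  stratum degenerates to SRS exactly.
* **Genetic distance (radial exclusion)**: on distance 1 − similarity,
  repeatedly pick a remaining candidate uniformly at random and discard
  all remaining candidates strictly within r of it. The radius is tuned by
  bisection (pick order frozen per evaluation) so that exhausting the pool
  yields the requested n; at a step discontinuity the tightest radius
  giving ≥ n is used and the surplus trimmed uniformly at random (both
  recorded). Exclusion is strict (< r), so r = 0 discards nothing and
  reduces to SRS; duplicate-profile clusters that make n unreachable raise
  an error naming the cluster. Every sample satisfies min pairwise
  distance ≥ the achieved radius, and the achieved radius shrinks as n
  grows.
* **CDmean**: maximises the mean generalized coefficient of determination
  CD(c) = diag[c′(A − λ(Z′MZ + λA⁻¹)⁻¹)c / c′Ac] of contrasts
  c_t = e_t − mean(candidates) between each unphenotyped individual and
  the candidate average, with λ = (1−h²)/h². The planning h² defaults to
  0.5 (λ = 1) — a deliberate trait-agnostic choice, since training sets
  are usually chosen before trait heritabilities are estimable and the
  selected sets are insensitive to it. The optimiser is a stall-bounded
  stochastic exchange: start from an SRS draw, propose uniform
  selected/non-selected swaps, accept only strict improvements, stop after
  `max_stall` consecutive rejections (default 2,000), keep the best of 3
  restarts. On enumerable instances (8 choose 3) it attains the global
  optimum. In the cross-validation mode the contrast set is the current
  complement and is recomputed after every accepted swap; with an
  explicit test set the contrasts are fixed on those targets. With
  intercept-only fixed effects, (X′X)⁻ is simply 1/n_train; an empty
  training set gives CD = 0 identically.

## Prediction models

All three models fit y = 1β + g + e on the training individuals.

* **GBLUP**: g ~ N(0, Aσ²_g). REML by spectral decomposition of the
  training submatrix (exact and fast at n ≤ 200): the variance ratio
  δ = σ²_e/σ²_g is profiled on log scale with bounded scalar
  minimisation in [e⁻¹², e¹²], σ²_g profiled out analytically.
  Predictions are the joint-normal conditional mean
  β + A_{pred,train}(A_{train} + δI)⁻¹(y − β), which equals both the
  mixed-model-equation solution and ridge regression on the centred
  marker matrix with matched penalty (both verified to 1e-8/1e-10).
* **RKHS**: the same machinery with K = exp(−D/θ). D is the squared
  Euclidean distance on recoded dosages divided by its off-diagonal mean,
  so the fixed θ grid — 20 points in (0.05, 1] — is well conditioned for
  any panel size; θ is chosen by maximal restricted log-likelihood.
  Plain (unsquared) distances and unnormalised D are available as flags.
* **BayesC-π**: y = 1β + Wb + e with b_j = 0 with probability π and
  b_j ~ N(0, σ²_b) otherwise; π ~ Beta(1,1) is estimated from the
  inclusion counts. Gibbs sampling (numba-compiled, deterministic per
  seed) with scaled-inverse-χ² priors on σ²_b and σ²_e: df 5, scales set
  so the prior modes split the phenotypic variance at R² = 0.5, the
  marker-variance scale assuming half the markers contribute a priori.
  These hyperpriors are conventional Bayesian-regression defaults, not a
  fitted choice. Defaults 5,000 iterations / 2,500 burn-in; the σ²_e
  chain's effective sample size exceeds 50 on test instances, and
  π fixed at 1 or 0 degenerates to the intercept-only and Bayesian-ridge
  limits respectively (both tested against independent samplers).

Accuracy is the Pearson correlation between predicted genotypic values
and observed phenotypes of the held-out individuals (≥ 3 overlapping ids,
nonzero variance required).

## Evaluation schemes and ANOVA

The **TV scheme** samples a training set of size n ∈ {50,…,150} from all
190 individuals and validates on the complement; the **TT scheme** first
holds out a common random test set (40 by default; 70 and 95 supported,
the latter with the reduced training-size menu {30,45,60,75}), then lets
every sampler draw from the remaining pool, so all methods predict
identical targets; a realization's accuracy is the mean over the sampling
repetitions. Replicates are seeded by a counter-based scheme
(SeedSequence over cell indices), so results are independent of execution
order. Inside scheme runs the CDmean search uses a desk-scale setting
(max_stall 300, single start) and BayesC-π runs at 1,000/500 draws; the
standalone functions keep their full defaults.

`anova_accuracy` takes the Fisher-z of the *cell mean* accuracy per
(method, size, model) — one response per cell, which is what makes the
residual degrees of freedom 36 on a 4×5×3 grid and 24 on 4×4×3 — with
size as a numeric covariate (1 df) and method/model as factors, Type-I
sums of squares in the order method, size, model, method:size,
method:model, size:model, three-way (Type-II behind a flag).

## What the synthetic benchmark shows — and does not

On the full-scale synthetic panel the evaluation reproduces the expected
qualitative pattern where the generator supports it: training-set size is
by far the dominant ANOVA term, stratified sampling is statistically
indistinguishable from simple random sampling under weak structure, the
sampler and the prediction model do not interact, and for sparse traits
the marker-selection model (BayesC-π) clearly outperforms GBLUP.

The *advantage of the analytical samplers* (CDmean, genetic-distance) over
random sampling, however, depends on genuine relatedness variation and LD
— exactly the two features the generator deliberately omits. With
independent markers and unrelated individuals, the off-diagonal of A is
estimation noise of order 1/√m; a CD-maximising search then overfits that
noise, and at the noise-floor accuracies of this regime the analytical
samplers do not beat SRS (CDmean can even fall below it). A second,
purely design-driven effect compounds this in the cross-validation (TV)
scheme: because training and validation sets are complements, an
analytical sampler implicitly *chooses* its validation set, and leaving
out the most "average" individuals restricts the genetic variance of the
validation set, deflating the accuracy correlation — most visibly at
large n, where only a small, strongly selected complement remains. Two
observations confirm this reading: in the TT scheme — where the test set
is fixed before sampling, removing the composition bias — CDmean and
genetic-distance sampling do lead SRS at the smallest training sizes on
this same panel (see `analysis/05_tt_scheme.py` and the acceptance
script's TT quantities); and in a small-dimension regime where prediction
works (e.g. 60 individuals × 300 markers) the same code shows CDmean and
GD ahead of SRS in the TV scheme as well. The benchmark
therefore validates the machinery and the size/model/structure patterns,
while the sampler ranking itself is a property of real panels that a
no-LD, no-family generator cannot — and should not be tuned to —
reproduce.

## Problem sizes used by the shipped runs

The analysis drivers and the acceptance script run the schemes at desk
scale — 10–20 replicates per cell, GBLUP + BayesC-π (1,000/500 draws) for
TV, GBLUP for TT with 10 test sets × 5 sampling repetitions — which keeps
a full pipeline pass in the tens of minutes on one CPU while leaving every
qualitative conclusion unchanged; the scheme functions accept the full
replication counts (100 TV reps, 50×50 TT) unchanged.
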