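# Methods

## Scope

`hiergst` detects loci whose differentiation between repeated environmental
contrasts (low vs high elevation population pairs, replicated across study
sites) departs from the genome-wide neutral background. It contains five
coupled components: a genotype data model with summary statistics
(`popdata`), Bayesian allele-frequency/GST inference (`gst`), the
hierarchical and single-site partitioning models (`models`), outlier
calling and power scoring (`outliers`), a genotype–environment association
test (`gea`), and a forward Wright–Fisher simulator plus orchestration
(`simulate`, `workflow`, `cli`).

## Step 1: allele frequencies and pairwise GST

Allele frequencies are inferred independently per population and locus
from allelic counts (n, N) under a Binomial likelihood with a β(1,1)
prior. Because the prior is conjugate, the posterior is exactly
Beta(n+1, N−n+1); the package draws i.i.d. samples from it rather than
running a Markov chain — the same distribution, with no autocorrelation
and exact seed control. For an unobserved locus (N = 0) the draws come
from the uniform prior.

Pairwise Nei GST is computed per posterior draw as
(H_T − H_S)/H_T with H_T = ½(p_i+p_j)(q_i+q_j) and
H_S = p_i q_i + p_j q_j, and each locus × pair cell is summarised by its
posterior median (default 2000 draws; the step-1 draw count is a free
choice since the original chain length is not documented). GST is
undefined only when both frequencies are exactly fixed for the same
allele, which has probability zero under the continuous posterior; the
degenerate case raises an error rather than being silently patched.

The per-cell median of GST has a positivity floor of order 1/N even for
identical true frequencies (sampling noise enters quadratically); this is
inherent to the estimator, affects all loci alike, and is absorbed by the
genome-wide intercept in step 2.

## Step 2: hierarchical partitioning (multi-site model)

The logit of each GST median is modelled as

    logit(GST_(i,j),m) ~ N(mu_G + kC(i,j) mu_Clus + kS(i,j) mu_SubClus
                           + kE(i,j) (mu_Elev + theta_m), tau_R)

with pair indicators kC (different clusters), kS (same cluster, different
sub-clusters) and kE (different elevations). Priors: mu_G ~ N(0, 1e-4
precision), mu_Clus/mu_SubClus/mu_Elev ~ N(0, tau) with
tau ~ Gamma(0.01, 0.01) each, theta_m ~ N(0, 1e-4 precision),
tau_R ~ Gamma(0.01, 0.01). Identifiability of the locus effects comes from
the sum-to-zero constraint Σ theta_m = 0, imposed by recentring theta at
every sweep and absorbing the offset into mu_Elev (the standard device in
graphical-model samplers; a corner constraint would shift the reported
mu_Elev by one theta but leave the calls unchanged).

Sampling is blocked Gibbs: the four genome-wide effects are drawn jointly
from their exact multivariate-normal conditional (their design columns
overlap strongly, so scalar updates mix an order of magnitude slower and
noticeably under-disperse short chains); theta is drawn as a vector; the
precisions follow gamma conditionals. All conditionals are conjugate, so
no tuning is needed and runs are deterministic given the seed. Chain
defaults follow the power-study settings (2000 iterations, 1000 burn-in,
thin 1); real-data analyses in the pipeline default to 10000/5000. A
split-chain potential-scale-reduction diagnostic is reported per
parameter; values above 1.1 warn but do not abort.

The logit transform clamps GST to [eps, 1−eps] with eps = 1e-6
(configurable); clamp events are counted so boundary-heavy inputs are
visible. Frequentist checks of the sampler: posterior means agree with an
ordinary-least-squares fit under sum-to-zero contrasts to < 0.01 on
synthetic data, and 95% credible intervals cover generating genome-wide
effects at 95–97% over 100 replicates.

## Single-site model

For one population pair the structure terms collapse (every observation
has kE = 1, so mu_Elev is confounded with the intercept), leaving
logit(GST_m) ~ N(mu_G + theta_m, tau_R) with the same priors and
constraint. This model is saturated — one observation per locus — so
tau_R is identified only weakly through the fixed theta prior, and its
chain performs a slow random walk. The posterior medians of theta, which
are all the outlier step consumes, remain stable (they track the centred
logit values to < 0.05 at the 10000/5000 chain length); posterior means
and the tau_R summary should not be over-interpreted. This behaviour is a
property of the model specification itself, not of the sampler.

## Outlier calling and scoring

A normal law is fitted by maximum likelihood (mean and ML standard
deviation, no trimming or robustification) to the per-locus posterior
medians of theta, and each locus receives a two-tailed probability.
Thresholds of 1% and 5% are both tabulated; the 1% set defines the calls.
`above` loci exceed the fitted mean (candidates for divergent selection
replicated across sites), `below` loci fall under it (homogenizing
selection or rare variants). With all loci entering the fit, a large
contingent of strong outliers inflates the fitted standard deviation and
partially masks weaker ones; this self-masking is faithful to the
published procedure and is visible in the power results below. Scoring
against simulation truth uses FDR = V/R (undefined when R = 0) and
FNR = T/(m−R).

## Forward simulator

Populations are arranged in nested levels — clusters, sub-clusters within
clusters, sites within sub-clusters, and a low/high elevation pair per
site; the default 2×2×2×2 design gives 16 populations of N = 200
diploids (the within-site design: one site, two populations of N = 1600).
Migration is a nested island model: each population draws a fraction m3
of its gene pool from the other populations of its sub-cluster, m2 from
the other sub-clusters of its cluster and m1 from the other clusters;
levels with no donors are dropped from the mix.

Because loci are unlinked and mating is random, the simulator tracks
per-locus allele frequencies with exact binomial Wright–Fisher resampling
of 2N gametes instead of individuals; this is distributionally equivalent
for every statistic the pipeline consumes and orders of magnitude faster.
Per generation: deterministic migration mixing, viability selection, then
binomial resampling. Selection is additive with fitnesses 1, 1−s/2, 1−s
(s = 1 − fitness of the disfavoured homozygote); under divergent
selection the favoured allele differs between elevations, under
homogenizing selection it is the same everywhere. Terminal genotypes are
materialised from within-population Hardy–Weinberg proportions.

Defaults (all configurable in `ScenarioConfig`):

| parameter | default | rationale |
| --- | --- | --- |
| N | 200 diploids (1600 within-site) | published power-study sizes |
| L | 100 loci | published power-study size |
| p0 | 0.5 | maximal initial diversity, no ascertainment model |
| m1, m2, m3 | 0.001, 0.002, 0.05 | see calibration below |
| generations | 800 | see calibration below |
| selection_onset | 100 | see below |

**Neutral calibration.** The migration rates and duration were chosen, on
neutral simulations only, so that the mean neutral GST hierarchy matches
the magnitudes reported for the real data: measured 0.061 (different
clusters) / 0.041 (different sub-clusters) / 0.011 (different elevations
within a sub-cluster) against the reported 0.063 / 0.056 / 0.013. The
ordering cluster > sub-cluster > elevation follows from m1 < m2 < m3.

**Selection onset.** Selection acts only during the final 100
generations. This mirrors the biological premise — lineage structure
(glacial refugia) long predates the recent altitudinal contrast — and is
also structurally necessary: directional homogenizing selection running
for the whole 800-generation history fixes the selected loci in every
population, after which they are discarded as monomorphic and no method
could flag them. One hundred generations is enough for
migration–selection balance to be reached at every strength simulated
(timescale ~1/s) while keeping homogenizing loci polymorphic.

**What the generator does not emulate.** No mutation, no linkage, no
demographic events, no genotyping error or missingness, no SNP
ascertainment (real candidate-gene panels are biased toward intermediate
frequencies), and a symmetric, time-constant migration matrix. Passing
power checks therefore demonstrate the statistical machinery under an
idealised island-model history, not performance guarantees on real data
with heterogeneous demography.

## Power study

The harness simulates each scenario, runs both steps blind to the truth
(truth labels are consumed only by the scoring step), calls outliers at
1% and 5% and aggregates detection counts, FDR and FNR over replicates
(default 10, reporting per-replicate rows and medians — single runs of a
stochastic pipeline are not a stable target). With 2000/1000 chains, one
16-population replicate costs a few seconds on one CPU; the full
eight-scenario acceptance run completes in minutes. Strong-selection
scenarios (s ≥ 0.5, and homogenizing/divergent mixtures at the
within-site scale) reproduce the published detection counts exactly.
Under weak selection (s ≈ 0.06–0.1) the measured power is lower than the
published single-run values: the long drifted history spreads the
neutral theta background, and the untrimmed normal fit self-masks when
many loci are selected. The per-replicate tables make this explicit
rather than hiding it behind a favourable seed.

## GEA test

For one site, the empirical F_IS distribution across polymorphic loci
(elevations pooled) feeds a simulated null: n1 F_IS values drawn with
replacement, one population of N_pop = 1000 diploids simulated per draw
from F_IS-corrected Hardy–Weinberg probabilities
(p² + pqF, 2pq(1−F), q² + pqF, clipped and renormalised when F < 0), and
n2 disjoint half-splits of 500+500 per population, giving a
10000-iteration null distribution of genotype frequencies per locus
(each locus uses its own pooled allele frequency; the F_IS pool is shared
across loci). Observed per-elevation genotype frequencies receive
p = min(F̂(obs), 1−F̂(obs)) under the empirical CDF, floored at one over
the iteration count, with a sign from the direction relative to the null
median. The default threshold is α = 0.05 (the original threshold is not
documented); "n1 values sorted in the empirical distribution" is read as
random draws with replacement. Note the null matches the sampling
variance of subpopulations of 500 diploids; sites much smaller than that
are tested anti-conservatively, which is inherent to the procedure.

## Numerical and interface choices

- Reference allele = first allele met in file order; every statistic
  (GST, F_IS, the models) is invariant to the labelling, so the
  convention is cosmetic. Missing genotypes are excluded locus-by-locus.
- Monomorphic filtering pools the requested scope; within-site analyses
  re-filter per site.
- Degenerate inputs raise: tri-allelic loci, n > N, H_T = 0, fewer than
  3 loci for the single-site model, zero-spread theta in the normal fit
  (detected with a relative tolerance against floating-point dust).
- All randomness flows through `numpy.random.Generator` seeded from
  user-supplied integers; replicate seeds are spawned via `SeedSequence`
  so scenarios are independent but reproducible. Pipeline reruns with the
  same seed produce byte-identical output tables.
- Tests and the acceptance script use the published problem sizes
  (16 × 200 diploids, 100 loci, 2000/1000 chains, 10 replicates) for the
  power checks and smaller synthetic designs for the unit-level oracles.

## Limitations

- The hierarchical model assumes a single shared elevation effect per
  locus across sites; site-specific (idiosyncratic) selection is
  invisible to it by design and is the single-site model's job.
- The partitioning model treats GST medians as exact observations;
  step-1 uncertainty propagates only through the median, not as
  measurement error in step 2.
- Weak-selection power depends strongly on the (undocumented) simulation
  history; see the power-study section.
- The GEA null ignores linkage between loci and uses a fixed
  subpopulation size.
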