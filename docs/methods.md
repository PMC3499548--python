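# Methods

`popcollapse` detects, quantifies and dates changes in effective population
size from diploid microsatellite genotypes, and probes whether population
structure alone could produce a spurious decline signal. This note records
the models, the numerical choices, and what the synthetic-data experiments do
and do not demonstrate.

## Model

### Demography

A single population of current diploid effective size N0 had ancestral size
N1 until the change began, ta generations before the present; between then
and now the size interpolates either linearly or exponentially in time.
Before ta (looking further into the past) the population is stationary at
N1. A pair of lineages coalesces at rate 1/(2N(t)) per generation, so the
genealogy prior is governed by the integrated intensity
Λ(t) = ∫₀ᵗ ds / (2N(s)), which has closed forms (and closed-form inverses,
used by the simulator through time rescaling) for all three trajectory
shapes. The structure scenario is a finite island model: d demes of size N0
with symmetric scaled migration M = 4·N0·m; it has genuine structure and no
size change.

### Mutation

Microsatellite alleles evolve under the strict stepwise mutation model
(SMM): mutations arrive as a Poisson process and each shifts the allele size
by ±1 repeat unit with equal probability. The transition probability across
a branch carrying on average λ mutations is the Bessel form
P(net displacement d) = e^{-λ} I_{|d|}(λ).

### Scaled parameterisation (simple engine)

Following the convention θ = 2·N0·μ, the simple engine measures genealogy
time in units of 2·N0 generations. In those units the identifiable
parameters are exactly the three ratios it samples: the magnitude of change
r = N0/N1, the scaled onset time tf = ta/N0 (the change completes at
τ = tf/2 on the 2N0 scale), and θ. All three get uniform priors on log10 in
[−5, 5], and chains start on the expansion side (log10 r > 0) so that a
decline is only reported when the data pull the chain across zero.

### Hierarchical engine

The hierarchical engine samples N0, N1, the onset time T in generations and
the mutation rate directly, under lognormal priors specified on the log10
scale: N0 and N1 centred at 4.0, T at 5.0 (default sd 2.0 for all three —
the plausible middle of the 1–5 range one would consider), and log10 μ
centred at −3.5 with sd 0.25, giving rates of 10⁻⁴–10⁻³ reasonable support.
Each locus gets its own rate: log10 μ_ℓ is normal around the population mean
with an among-locus scale given a half-normal hyperprior (scale 0.3,
matching the few-fold spread typical of microsatellite panels). The
trajectory is exponential. The time prior is stated in generations;
conversion to years happens only at reporting time, with the generation time
g an explicit required argument (8 y and 25 y are both defensible for
orang-utans and the dating conclusions should be checked under both).

## Likelihood

Internal allele states are integrated analytically rather than sampled: the
observed allele sizes at a locus are placed on a bounded integer ladder (the
observed range padded by K = 10 repeat units on each side) and the tip
configuration is pruned (Felsenstein) with the SMM kernel per branch. Root
states carry unit weight on every rung (summed out), so a single tip — or
two identical tips with a vanishing mutation rate — has log-likelihood
exactly zero, and the ladder constant cancels from every Metropolis ratio
because the ladder is fixed per locus. At initialisation the ladder widens
automatically until less than 10⁻⁶ of the root mass touches the boundary
rungs; the standalone `genealogy_loglik` does the same widen-and-retry on
every call.

The kernel rows e^{-λ} I_d(λ), d = 0..S−1, are computed by Miller's backward
recurrence normalised with e^{λ} = I₀ + 2·Σ I_k (machine precision against
`scipy.special.ive`), switching to the uniform asymptotic expansion beyond
λ = 2·10⁴ where the recurrence would be needlessly long. Pruning and the
coalescent log-density are numba-compiled; both have brute-force oracles in
the test suite (exhaustive state summation on small trees; quadrature of
1/(2N(s))).

## MCMC moves

Each iteration draws one elementary move:

* Gaussian random walks on each log10 parameter, occasionally replaced by
  independence draws from the prior (these keep prior-predictive runs nearly
  iid and let weakly identified parameters hop across their range);
* per-locus genealogy moves: single node-time shifts (uniform between the
  neighbouring node times; multiplicative above the root), whole-tree time
  scalings with the (n−1)·log c Jacobian, a *recent-scale* move that
  rescales only coalescences younger than the change onset (a bottleneck
  squeezes exactly that part of the tree), and symmetric subtree exchanges
  for topology;
* coupled, likelihood-invariant moves that rescale genealogy times together
  with parameters so that every branch's expected mutation count — hence the
  likelihood and all cached kernels — stays fixed: θ against times, tf with
  times (the change epoch rides along with tree depth), and a three-way
  r/tf/θ slide; the hierarchical engine has the analogous N0·N1·T·μ ridge
  move and a T·μ onset-time move, plus a block independence redraw of the
  whole rate hierarchy from its prior.

The coupled moves matter: the posterior has long ridges (N·μ and the
"instantaneous change" family) along which single-parameter walks are
painfully slow. Step scales adapt toward an acceptance window of 0.2–0.5
during burn-in only and are frozen afterwards, preserving detailed balance.
A joint check with the likelihood forced flat (the target then collapses to
the prior) reproduces uniform parameter marginals with the full genealogy
machinery running — the standard sanity test for Hastings/Jacobian errors.

### Metastable states and convergence control

The prior box admits a degenerate corner — essentially instantaneous change
with an extreme size ratio and a compensating mutation rate — in which every
genealogy is a near-star tree. Its posterior mass is negligible (its
log-likelihood trails the converged plateau by 50–150 units on the data
sizes used here) but chains that wander in during early burn-in take a very
long time to leave. Three mitigations are built in: chains start with tf
large (no bunching pressure during early adaptation); initial genealogies
keep coalescent-prior node times but hand similar alleles to tree-adjacent
tips, so the slow topology mixing starts from data-compatible clusterings;
and `drop_stuck_chains` excludes, before pooling, any chain whose
post-burn-in mean log-likelihood trails the best chain by more than 20 units
— the automated counterpart of inspecting independent runs and pooling only
those that agree. The pipeline itself only *flags* suspicious runs (Geweke
|z| > 3); exclusion is an explicit analysis step.

Desk-scale defaults (10⁵–10⁶ proposals, a few chains, minutes per dataset)
are far below the 10⁹–10¹⁰ iterations the original software needed at
publication scale; all calibration experiments here state their chain
lengths and were chosen to leave clear convergence margins at these data
sizes (12 loci, ~15 diploids), not to reproduce any site-specific posterior.

## Posterior analysis and dating

Burn-in removal takes the first ⌈fraction·n⌉ retained samples of each chain
(default 0.10; the calibration experiments discard 0.5 because their chains
are short). Convergence is monitored with the Geweke diagnostic (first 10%
vs last 50%, spectral variance at frequency zero via Bartlett-windowed
autocovariance). Independent runs are pooled after burn-in with provenance
kept per chain.

Interval summaries report both central quantile intervals and
highest-posterior-density intervals (shortest window of the sorted samples);
the pipeline locates intervals on the log10 scale and transforms back,
matching log-scale reporting conventions.

Epoch dating converts T to years with an explicit g and weighs interval
hypotheses by approximate Bayes factors — posterior odds over prior odds of
"T in the interval", with masses estimated by sample proportions floored at
1/(M+1) (a finite sample never yields an infinite BF; when the floor binds
the result is flagged as a bound) and analytic prior masses from the
lognormal T prior. The canonical epochs are H1 (0, 200] y (commercial
forest exploitation), H2 (200, 5000] (first farmers), H3 (5000, 40000]
(hunter-gatherers) and H4 (40000, 100000] (Pleistocene climate), each tested
against the other three pooled within the 100 ky horizon; H2 can be split
into (200, 2000] and (2000, 5000] sub-periods. Because the epochs differ in
width, a sliding profile of 500-year windows over the last 50,000 years
(100 windows) complements the four-way test. BF ≥ 10 counts as strong
support, 3–10 substantial, below 3 none; the mass-ratio estimator was chosen
over kernel-density ratios because the hypotheses are interval-valued and
proportions are stable.

## Synthetic data

The generator is the package's stand-in for unpublished field genotypes and
the engine of every recovery experiment. The study-shaped default
(`orangutan_like_config`) is 126 individuals across six sites (20, 26, 29,
26, 19, 6) typed at 12 loci. Its scenarios:

* **decline** — panmictic exponential collapse from N1 = 5000 to N0 = 50
  starting ta = 100 generations ago. At the default mutation rate
  μ = 7·10⁻⁴ (within the 10⁻⁴–10⁻³ range assumed for microsatellites) the
  ancestral equilibrium heterozygosity is ≈ 0.73 and the post-collapse
  samples land in the He ≈ 0.59–0.73 band with ~4–8 alleles per locus —
  the diversity regime the analysis is meant for. The onset maps to
  ~800 y (g = 8) or 2500 y (g = 25), inside the farmer epoch.
* **island** — six demes of 800 with M = 5, no size change, giving pairwise
  FST of roughly 0.05–0.2 (the confound experiments use ten demes of 500
  with M = 6, mean FST ≈ 0.12).
* **constant** — stationary at N0 = 2500 for null calibration.

Loci are independent, unlinked and error-free, exactly as the inference
model assumes — so the recovery experiments test the inference machinery,
not its robustness to genotyping error, linkage, null alleles, mutation-rate
misspecification or within-site relatedness, all of which real data contain.
Allele states are unbounded integers during simulation (no ladder); a locus
drifting non-positive is shifted up wholesale, which preserves every
pairwise difference and therefore the likelihood.

## What the calibration experiments show

* Prior recovery (likelihood off): both engines reproduce every marginal
  prior (KS < 0.05 at 10⁴ retained samples).
* Simulator calibration: mean TMRCA matches 2N (n = 2) and 4N(1 − 1/n)
  (n = 10) within Monte-Carlo error; SMM equilibrium homozygosity matches
  1/√(1 + 8Nμ).
* Decline recovery: on a simulated 100-fold collapse (12 loci, 15 diploids)
  the simple engine puts ≥ 90% of its posterior mass on decline and the
  hierarchical engine separates N0 and N1 by more than an order of
  magnitude.
* Null calibration: on stationary data the 90% central interval of log10 r
  covers zero in a clear majority of replicates.
* Structure confound: island-model data with no size change produce a
  spurious decline when sampled from one deme, and pooling individuals
  across demes pulls the posterior back toward stationarity — the pooled
  posterior median is strictly closer to zero. (A pooled "scattered" sample
  can even lean slightly positive: collecting lineages from many demes
  stretches recent coalescence, which mimics expansion.)

## Known limitations

* Single-event model: one monotone size change; multiple successive events
  are outside the model for both engines.
* The wide priors admit degenerate near-star configurations; convergence
  control (above) is required at desk scale, and posteriors from weakly
  informative data should always be compared across independent runs.
* BF dating inherits the generation-time and mutation-rate uncertainty;
  results are reported at g = 8 and g = 25 rather than averaged.
* The Genepop dialect is deliberately small (title, locus list, Pop blocks,
  2/3-digit alleles); exotic variants are out of scope.
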