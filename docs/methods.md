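# Methods

## The model family

All methods fit the mixed linear model

    y = X beta + Z u + e,        e_i ~ N(0, sigma_e^2)

where `y` holds `n` phenotypes, the only fixed effect is the population
mean (flat prior), `Z` is the centered `n x m` matrix of SNP genotype
scores (raw scores in {0,1,2}; centering so `Z'1 = 0` improves MCMC
mixing), and `u` is the vector of `m` SNP effects. The residual variance
has a scaled inverse chi-square prior `nu_e S_e^2 chi^-2_{nu_e}` with
`S_e^2 = V_E (nu_e - 2)/nu_e`, so its prior mean equals the assumed
residual variance `V_E` (by default half the phenotypic variance,
matching an h^2 ~ 0.5 prior belief; `nu_e = 4`).

The methods differ only in the prior on `u`:

* **BayesB** — `u_j = alpha_j delta_j`, `delta_j ~ Bernoulli(1 - pi)`,
  `alpha_j | sigma_j^2 ~ N(0, sigma_j^2)` with locus-specific
  `sigma_j^2 ~ nu_alpha S_alpha^2 chi^-2_{nu_alpha}`; marginally each
  effect is a fat-tailed t (`nu_alpha = 4`).
* **BayesC / BayesCpi** — one common slab variance `sigma_alpha^2` for
  all fitted SNPs; BayesCpi additionally samples `pi` under a uniform
  prior via Beta conjugacy.
* **BayesN** — the nested mixture. SNPs are grouped into non-overlapping
  fixed-width genomic windows (1 or 0.2 Mb). Effect of SNP j in window i
  is `u_ij = alpha_ij delta_ij Delta_i`: the window indicator
  `Delta_i ~ Bernoulli(1 - Pi)` switches the whole window in or out, the
  locus indicator `delta_ij ~ Bernoulli(1 - pi_i)` selects SNPs within
  an in-model window, and all effects of a window share one variance
  `sigma_i^2 ~ nu_alpha S_alpha^2 chi^-2_{nu_alpha}` (a multivariate-t
  window effect: uncorrelated but dependent). This is the package's
  core: dependence of effects of closely linked SNPs enters through the
  shared window indicator and the shared window variance, so markers
  flanking the same QTL are included or excluded jointly.
* **BayesNC** — BayesN with a single genome-wide slab variance
  `sigma_alpha^2` instead of window-specific variances; used when `Pi`
  is treated as unknown, because the common variance restores Bayesian
  learning of `Pi` (see "Posterior of Pi" below).
* **anteBayesB** — first-order antedependence: `alpha_j = t_j alpha_{j-1}
  + gamma_j` within a chromosome (`alpha_1 = gamma_1`), `u_j = alpha_j
  delta_j`. Both `gamma_j ~ t_{nu_gamma}(0, S_gamma^2)` and the
  antedependence coefficients `t_j ~ t_{nu_t}(0, S_t^2)` are fat-tailed;
  the induced conditional covariance of effects is nonstationary and
  decays with chromosomal distance. With `nu_t = 4`, `S_t^2 = 0.1` the
  expected prior variance of `t_j` is `nu_t S_t^2/(nu_t - 2) = 0.2`.

## Prior calibration

Interpretable inputs: assumed QTL count `s`, SNPs fitted per QTL `k`
(2 or 10), additive variance `V_A` and the mean allele-frequency product
`pq_bar` over SNPs.

* `pi = (m - s k)/m` — per-SNP exclusion for the flat models.
* `pi_i = (m_i - k)/m_i` per window, clamped at 0 when `k >= m_i`
  (a window cannot fit more SNPs than it contains).
* `Pi = (w - s)/w` over the `w` SNP-bearing windows (at most one QTL per
  window assumed).
* Slab scale `S_alpha^2 = V_A / (2 pq_bar (1 - pi) m) * (nu_alpha -
  2)/nu_alpha`, spreading `V_A` over the expected number of nonzero
  effects. For the nested models the equivalent `1 - pi` is
  `(1 - Pi) * weighted-mean(1 - pi_i)`.

When window sizes are constant the nested and flat priors place the same
prior mass on nonzero effects: `(1 - Pi)(1 - pi_i) = s k / m = 1 - pi`
(tested to machine precision). When `Pi` (or `pi`) is sampled, its
starting value still calibrates `S_alpha^2` once at setup; the scale is
not updated during the chain.

## Gibbs sampler

Systematic scan per sweep: mean -> windows in genome order (loci within
window) or loci in chromosome order -> variances -> sigma_e^2 -> pi/Pi.
All indicator draws integrate out the corresponding effects (single
locus for `delta_j`; the window's whole included set for `Delta_i`, a
closed-form multivariate normal marginal evaluated via a Cholesky
factorization) and all Bernoulli odds are computed in log space.
Effects with indicator 0 are refreshed from their priors so the
locus-specific and window-specific variance updates condition on a
full-length effect vector, keeping every conditional conjugate and the
dimension fixed. The common slab variance of BayesC/BayesCpi/BayesNC is
updated from the *included* effects only (df `nu_alpha + m_1`) — the
standard update for these models; excluded effects feed no other
conditional there, so this is the valid Gibbs step for the marginalized
parameterization and is what permits Bayesian learning of `pi`/`Pi`.

The BayesN window move is partially collapsed: `Delta_i` is drawn with
the included effects integrated out, those effects are immediately
redrawn jointly from their Gaussian full conditional (excluded ones from
the prior), and only then are the per-locus `(delta, alpha)` pairs
updated. t-priors (BayesB slab, anteBayesB `gamma` and `t`) are handled
through the normal / scaled-inverse-chi-square scale-mixture
representation. The anteBayesB locus update integrates `gamma_j` out and
carries the downstream term `alpha_{j+1} = t_{j+1} alpha_j +
gamma_{j+1}` — the correct full conditional under first-order
antedependence.

The residual-update bookkeeping vector `ycorr = y - X beta - Z u` is
maintained incrementally and re-checked against a full recomputation
every 1,000 sweeps (tolerance 1e-6); a NaN aborts with a diagnostic.

Correctness is anchored to an exact-enumeration oracle: for instances
with at most 12 indicators and fixed variances, the posterior over all
indicator configurations is computed in closed form, and the sampler's
marginal inclusion probabilities must agree within 0.02 (joint law
within total-variation 0.03) over 2e5 sweeps. Reduction identities are
tested the same way: BayesN with one genome-spanning window and `Pi = 0`
collapses to the common-variance (BayesC-like) model, and anteBayesB
with `t == 0` collapses to BayesB.

Chains default to 21,000 sweeps with 1,000 burn-in (101,000 available
for convergence checks); posterior summaries are streaming, so memory
stays flat at panel scale. Two implementations share the same
mathematics: numba-compiled sweep kernels (default) and plain NumPy
reference updates (`backend="python"`); both are tested against the
oracle. Chains are fully determined by their seed (one seeded generator
for Python-side draws, one seeded kernel stream).

## Forward simulator

The simulator emulates the structure of a real genotyped cattle
population without any real data.

* **Founders.** Each gamete carries a latent standard-normal AR(1) path
  along the chromosome with autocorrelation `rho_j =
  adjacent_corr^(gap_bp/ref)`; the allele is 1 when the latent value
  falls below the SNP's frequency quantile. Founder frequencies follow a
  Beta(0.6, 0.6) spectrum whose values are themselves spatially
  correlated (an AR(1) field on the quantile scale, `freq_corr`),
  because neighboring SNPs share genealogy. This yields exact marginal
  frequency spectra — including rare variants residing on common
  haplotype backgrounds (high D', low r2, as in real data) — and
  monotone LD decay. Two calibrated presets reproduce the adjacent-SNP
  LD of dense and sparse bovine panels: `HD_LD` (`adjacent_corr = 0.95`
  at 4.4 kb reference spacing, mean adjacent r2 ~ 0.57) and `MD_LD`
  (`0.56` at 50.5 kb, r2 ~ 0.24). A plain allele-copying Markov chain
  was rejected during design: copying forces neighboring allele
  frequencies together, which suppresses rare variants entirely and caps
  attainable adjacent r2 near 0.25.
* **Meiosis.** Crossover counts per chromosome follow a binomial map
  function, `X ~ Binomial(N, L/N)` with genetic length `L` Morgans
  (default 1 cM/Mb; chromosome length taken from the marker-map span)
  and `N = ceil(10 L)`, giving an expectation of one crossover per
  Morgan; crossover positions are uniform; strands alternate from a fair
  random start. No mutation, no interference.
* **Gene dropping.** Each offspring receives one recombinant gamete from
  each of two distinct founders drawn uniformly (random mating, no
  selfing, single generation — training and validation individuals are
  sibs/half-sibs by construction).
* **QTL and trait.** QTL are drawn uniformly among SNPs with MAF above
  (common) or below (rare) the 0.05 cutoff and masked from all marker
  panels. Raw effects are standard normal; effects and total genotypic
  values are divided by the realized SD of the total so Var(TBV) = 1
  exactly in the cohort (the 5,000-offspring cohort, not just the
  training split), and residuals are N(0, (1-h2)/h2); at the default
  h2 = 0.5 the residuals are standard normal.
* **Panels.** The dense panel holds all SNPs with founder MAF > 0.05;
  the sparse panel takes every 12th dense-panel SNP, restarting the
  count on each chromosome. Validation genotypes are centered with the
  *training* column means (anything else leaks validation information).

What the simulator does **not** emulate: multi-generation pedigree
structure, selection, mutation, genotyping error, ascertainment bias of
a real chip's manifest, and the very slow long-range LD decay of real
cattle (the latent AR(1) decays exponentially, so a sparse panel
subsetted from a dense simulation has less adjacent LD than a real 50k
panel; the sparse-panel preset compensates by generating at the sparse
spacing directly). Passing tests therefore demonstrate correctness of
the machinery and qualitative method behavior, not quantitative
transfer of accuracy levels to real populations.

## Evaluation

Accuracy is the Pearson correlation between GEBV (`Z_validate` times the
posterior-mean effects) and true breeding values in the validation set;
bias is the OLS slope of TBV on GEBV (1 = unbiased, > 1 = GEBV biased
downward). Per iteration, a window counts as "in" when `Delta_i = 1`
(BayesN/BayesNC) or when any of its SNPs carries a nonzero effect
(BayesB/anteBayesB); posterior means of windows-in estimate the number
of detected QTL. Method comparisons across replicates use two-sided
paired t-tests (degenerate zero-variance differences map to p = 1 when
the mean difference is 0, else to the p -> 0 limit, flagged).

## Study designs used by the test suite

Scaled-down versions of the full comparison (which at published scale —
609,870 SNPs, 2,649 windows, 4,000 training animals, 21,000-sweep
chains — is a cluster-sized computation) keep its structure:

* **Rare-QTL dense-panel comparison** (accuracy ordering and window
  counts): 4 chromosomes x 5 Mb at 4.4 kb SNP spacing (~3,500 panel
  SNPs after MAF filtering and masking), 500 founders, 1,200 offspring
  (800 train / 400 validate), 12 rare QTL, h2 = 0.5, 0.2 Mb windows,
  k = 2, chains 2,000/500, 8 replicates.
* **Posterior of Pi**: 8 chromosomes x 20 Mb at 50.5 kb spacing (~2,430
  SNPs), 1 Mb windows (~156 windows, ~16 SNPs each), 18 common QTL,
  1,600 training records, k = 10, chains 4,000/1,000, starting values
  of the with-QTL window fraction at 0.038 and 0.375.
* **Heritability moment**: 5,000 offspring, 300 common QTL on a 90 Mb
  three-chromosome genome.

## Numerical choices and degenerate inputs

* Bernoulli logits are capped at |35| before exponentiation; `pi` or
  `Pi` at exactly 0/1 force the corresponding indicator.
* Monomorphic SNP columns carry no information: they are skipped by the
  likelihood (indicator excluded, effect refreshed from the prior) and
  excluded from `pq_bar`; r2 against a monomorphic locus is reported as
  missing (NaN), never a 0/0 crash.
* Windows with zero SNPs are dropped from the partition; `w` counts
  SNP-bearing windows only (how real analyses bookkeep empty megabases
  is unknowable from published window counts alone; dropping is the
  consistent choice for the `Pi` calibration).
* Re-centering an already-centered matrix warns and no-ops; PLINK
  missing genotype codes are a hard error (simulated data has none).
* 0-based bp coordinates; windows are half-open `[kW, (k+1)W)` per
  chromosome; "every 12th SNP" restarts at chromosome boundaries.

## Known limitations

* anteBayesB is implemented in its modified form (mixture on the
  marginal effect, not on `gamma`), single chain, no parallel MCMC or
  EM/variational alternatives.
* Unequal-width / annotation-driven windows are not implemented.
* Missing genotypes and real-chip manifests are out of scope; phasing
  and imputation are assumed done upstream.
* Wall-clock benchmarking is not an output; the engine logs progress
  per 1,000 sweeps only.
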