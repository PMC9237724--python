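# Methods

## Problem and estimators

`sumdeconv` estimates the mixing proportions `alpha` (non-negative,
summing to one) that best explain a cohort's allele-frequency vector as a
convex combination of K reference populations. Two objectives are
implemented over the matched, harmonized variant set of size M:

* **frequency mode** — least squares directly on the M allele
  frequencies (the Summix-style baseline);
* **pc mode** — least squares on the L coordinates obtained by
  projecting the frequency vectors onto principal-component loadings
  derived from the reference genotype matrix, with a per-PC shrinkage
  correction applied to the cohort's projection only.

Both are convex quadratic programs on the probability simplex and share
one solver. The projection step is a plain matrix multiplication against
mean-centered frequencies; because the coefficients are constrained to
sum to one, any constant shift of the centering vector cancels between
cohort and references and cannot change the fit (this is asserted as a
property test). References are projected *without* correction: they are
the samples the PCA was computed from.

## Why PC space helps

Reference panel frequencies are sample means over a finite number of
reference individuals, so the frequency-space design matrix carries
per-variant sampling noise of variance `f(1-f)/(2N_k)`. Accumulated over
M variants this noise is comparable to the between-population signal for
closely related groups and biases the frequency-space fit toward
uniformity (classic errors-in-variables attenuation; on the default
synthetic scenario below it costs about two percentage points on the
closest pair). The PC projection compresses the population signal into L
coordinates. The residual scale mismatch between the in-sample reference
projections and the out-of-sample cohort projection is what the
multiplicative correction removes; with it, the PC-space fit recovers the
simulated proportions about an order of magnitude more accurately than
the frequency-space fit on the same data.

## Shrinkage correction

Projections of out-of-sample data onto PCs estimated from N reference
individuals are systematically shrunk toward the origin, because
finite-sample loadings partly chase sampling noise. The correction is
carried as one multiplicative factor `>= 1` per PC alongside the loadings
file, so a fit is exactly reproducible from distributed files.

For synthetic panels the factors are estimated by split-half
cross-validation (`estimate_correction`): repeatedly compute the PCA on a
random half of the reference individuals, project the held-out half, and
take the per-PC ratio of in-sample to held-out score standard deviations.
One adjustment is essential: the excess shrinkage of a PCA scales
inversely with the number of samples it was computed on, so the raw
half-sample ratio over-corrects the full-sample loadings by a factor of
two in its excess. The estimator therefore returns `1 + (ratio - 1) / 2`,
averaged over splits and floored at 1. Empirically (default scenario,
several seeds) the raw ratio leaves a residual bias of ~0.02 in the
fitted proportions while the rescaled factor reduces it to ~0.001-0.003.
Factors for PCs beyond the population structure (pure-noise directions)
are large, but those coordinates carry negligible weight in the fit.

## Variant matching

Variants are keyed by chromosome (normalized: no `chr` prefix, uppercase
X/Y/MT), 1-based position, and a single-nucleotide allele pair. A
summary-statistics variant matches a panel variant when chromosome and
position agree and the allele pair agrees under identity, allele swap
(frequency complemented), strand complement (frequency unchanged), or
both. Matching is one-to-one; when several transformations or panel rows
could apply, the lowest transformation (identity first) and the first
panel row win, deterministically. Strand-ambiguous A/T and C/G pairs are
removed by default because strand cannot be inferred from the alleles;
the flag is exposed for panels known to be strand-consistent. Indels and
multi-allelic rows are rejected at read time, which keeps the complement
transformation well defined.

## The solver

`solve_simplex_ls` is a primal active-set method on the QP
`min 1/2 a'A'Aa - b'Aa` with the equality constraint `sum(a) = 1` and
bounds `a >= 0`: starting from the uniform vector, the
equality-constrained subproblem on the current free set is solved through
its KKT system, a blocking bound is added when the full step would leave
the simplex, and the most negative multiplier (threshold `-1e-12`) is
released otherwise. Constraint violations up to `1e-10` are clipped and
the vector renormalized so the output sums to one exactly. Exactly
duplicated basis columns (twin populations) make the optimum a face; the
returned vertex moves all shared mass to the lowest group index,
documented as arbitrary-but-stable. Singular KKT systems fall back to a
least-squares solve; failure to converge within `100 K` iterations raises
with the condition number of `A'A`. `grid_oracle` exhaustively evaluates
the objective on a simplex lattice (refusing K > 5) and is the solver's
independent check in the tests.

## Synthetic data generator

The harness emulates the statistical structure the method assumes, with
known ground truth:

* **Divergence model.** Ancestral frequency `p_j ~ Uniform(0.05, 0.95)`;
  population frequency Beta-distributed around it with dispersion set by
  a per-population `F` (Balding–Nichols). Close population pairs are
  generated hierarchically: a shared intermediate frequency at
  `fst_shared`, then small per-member extra drift — emulating
  within-continent groups.
* **Reference panel.** `n_ref_per_pop` diploid genotypes
  `Binomial(2, f)`; the panel stores the frequencies *observed* in those
  individuals, as a real panel would.
* **Loadings.** Top-L right singular vectors of the column-centered
  genotype matrix, computed through the N x N Gram matrix in chunks so
  genotypes stay int8 (a one-million-variant panel fits comfortably in
  memory); correction factors from the split-half estimator; per-PC sign
  fixed by the largest-magnitude loading.
* **Cohort.** True frequency is the mixture of the supplied frequency
  matrix; observed frequency adds `Binomial(2n, f)/(2n)` noise; allele
  order is randomly swapped per variant (with complemented frequency) to
  exercise the matching step. Individuals are drawn as
  `Binomial(2, mixture)` dosages.

Default scenario (`SimConfig()`): M = 100,000 variants, K = 4 populations
with F = (0.02, 0.02, 0.05, 0.1), 200 reference individuals per
population, a cohort of 50,000 diploids, L = 8 PCs. These sizes give a
realistic ratio of reference noise to population signal while keeping a
full run around a minute; the subsampling-stability check uses
M = 1,000,000 with 100 reference individuals per population and 2
correction splits, which leaves the measured quantity unchanged while
halving the runtime.

What the generator does **not** emulate: linkage disequilibrium (variants
are exchangeable in both objectives, so LD affects standard errors of
real-data estimates, not the mechanics tested here), genotyping error,
imputation artifacts, assortative structure within populations, or any
uncertainty about how published cohort frequencies were computed
(pre/post quality control, meta-analysis weighting) — the pipeline takes
reported frequencies at face value and says so in its run report.
Passing tests therefore validate the estimator's mechanics and its
statistical behavior under the assumed sampling model, not robustness to
those real-data artifacts.

## Numerical and design choices

* All fitting arithmetic in double precision; genotype matrices int8 with
  chunked float64 accumulation.
* Loadings are used as distributed, with no per-variant standardization;
  whatever scaling they embed is shared by cohort and references and so
  cancels in the fit.
* The noiseless-exactness checks use unit correction factors: with the
  cohort inside the panel's span, recovery is an algebraic identity, and
  any factor > 1 on the cohort projection breaks the identity by
  construction.
* Run abort threshold: fewer than 50,000 matched variants (configurable);
  a warning between 50,000 and 100,000, reflecting that ~100,000
  overlapping variants are demonstrably sufficient (the subsampling
  experiment) while far fewer erodes the averaging the method relies on.
* Variant subsampling happens on the matched set, after ambiguity
  removal, seeded from the run configuration; reports are byte-identical
  across repeated runs with the same inputs and seed.
* Ties in matching and degenerate optima in the solver are resolved
  deterministically (first panel row; lowest group index).

## Known limitations

* Only biallelic SNPs; no indels, no VCF input, no liftover between
  genome builds.
* No standard errors or confidence intervals on the proportions.
* The correction estimator needs individual-level reference genotypes;
  for distributed loadings the factors must be supplied with the file.
* With reference groups far closer than the panel's noise floor, the
  fitted split between them is effectively unidentified; the intended
  remedy is the a-posteriori merge of such groups (`merge_proportions`),
  which is exact because the model is linear in `alpha`.
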