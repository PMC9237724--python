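# sumdeconv

Estimate the ancestry composition of a GWAS cohort from nothing but the
allele frequencies reported in its summary statistics.

Most published GWAS summary statistics include a per-variant allele
frequency for the analyzed cohort. Given a reference panel of allele
frequencies for K populations and principal-component loadings derived
from the reference individuals, the cohort's frequency vector can be
decomposed into a mixture of the reference populations. `sumdeconv`
implements that decomposition for cohort-level summary statistics and for
single individuals (genotype dosages divided by two), together with a
fully synthetic data generator so the whole pipeline can be exercised and
validated without downloading anything.

## The model

Let `f_j(0)` be the frequency of allele `a2` of variant `j` in the cohort
and `f_j(k)` its frequency in reference population `k`. The baseline
(Summix-style) estimator solves

    min_alpha  sum_j ( f_j(0) - sum_k alpha_k f_j(k) )^2
    s.t.       alpha_k >= 0,  sum_k alpha_k = 1

The preferred estimator instead works in the space of the top `L`
principal components of the reference genotype matrix. With loadings
`u_jl`, reference mean frequency `c_j` and per-PC shrinkage correction
factors `s_l >= 1`,

    p_l(0) = s_l * sum_j u_jl (f_j(0) - c_j)      (cohort, corrected)
    p_l(k) =       sum_j u_jl (f_j(k) - c_j)      (references, in-sample)

    min_alpha  sum_l ( p_l(0) - sum_k alpha_k p_l(k) )^2   s.t. alpha on the simplex

The correction compensates the systematic shrinkage toward the origin of
out-of-sample projections onto finite-sample PCs; without it the fitted
proportions are biased toward uniformity. Working in PC space concentrates
the population signal into a few coordinates and discards the dimensions
where reference sampling noise lives, which is what makes close
populations distinguishable.

Both problems are small convex quadratic programs on the probability
simplex, solved exactly by a dependency-free active-set method
(`solve_simplex_ls`), with a brute-force lattice oracle (`grid_oracle`)
used for verification.

Before any fitting, variants are matched between the summary statistics
and the panel on chromosome, position and allele pair, allowing allele
swaps (frequency complemented) and strand flips (frequency unchanged);
strand-ambiguous A/T and C/G variants are removed by default.

## Worked example

Everything below runs from scratch in a couple of minutes; the synthetic
generator plays the role of the reference distribution files.

```python
import sumdeconv as sd

# four populations, two of them weakly diverged; 100,000 SNPs;
# 200 reference individuals per population; cohort of 50,000 diploids
config = sd.SimConfig(seed=1)
sim = sd.simulate_panel(config)
loadings = sd.build_loadings(sim.genotypes, sim.panel, config.n_pcs, seed=1)

# a cohort mixing the populations 50/20/20/10, with binomial sampling noise
cohort = sd.simulate_cohort_sumstats(
    sim.panel, sim.true_freqs, config.alpha_true, config.n_cohort, seed=2
)

result, report = sd.deconvolve_tables(
    cohort, sim.panel, loadings, sd.RunConfig(mode="pc")
)
print(report.to_text())
```

prints

```
Ancestry proportions (pc mode), % of cohort:
  pop1   49.9
  pop2   20.1
  pop3   20.0
  pop4   10.0
objective (residual sum of squares): 0.0263252
matched variants: 100000
```

i.e. the known 50/20/20/10 mixture is recovered to about 0.1 percentage
points; the objective is the residual sum of squares of the PC-space fit.
The same run with `mode="frequency"` is noticeably less accurate (maximum
error around two percentage points) because reference-panel sampling noise
enters the frequency-space design matrix in full.

The same workflow runs from files through the CLI:

```
sumdeconv summary --sumstats s.tsv --panel panel.tsv --loadings l.tsv \
    --mode pc --merge merge.json --out report.json
sumdeconv individual --dosages d.tsv --panel panel.tsv --loadings l.tsv
```

File dialects (all delimited text, tab for `.tsv`, comma for `.csv`):

* summary statistics: columns `chr pos a1 a2 freq` (names remappable via
  `--chr-col` etc.), frequency refers to `a2`;
* panel: optional first line `##sizes<TAB>N1...NK`, then
  `chr pos a1 a2 <group1> ... <groupK>`;
* loadings: optional first line `##correction<TAB>c1...cL`, then
  `chr pos a1 a2 PC1 ... PCL [center]`;
* dosage file: `chr pos a1 a2 dosage` with dosages in {0, 1, 2}.

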