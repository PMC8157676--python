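# Methods

## The problem

Genomic-window association tests summarise whole-genome regression fits over
groups of neighbouring SNPs instead of single markers, which suits dense
panels where markers within a segment are strongly correlated.  When the SNP
density of the panel is *heterogeneous* — some 1-Mb windows carry several
hundred markers while the typical window carries under a hundred — windows at
the dense end of the distribution absorb a disproportionate share of the
fitted genetic variance even when the phenotype carries no signal at all.
Declaring windows significant because they explain a large share of genetic
variance then produces spurious associations concentrated on dense windows.
This package implements the windowed Bayesian GWAS machinery, demonstrates
the artefact, and implements the two corrections: fixed-SNP-count windows,
and window-specific variance thresholds proportional to SNP share.

## Bayesian whole-genome regression (BayesC-pi)

The single-trait model is

    y_i = mu + sum_j m_ij alpha_j + e_i,   e_i ~ N(0, sigma2_e),

with dosage codes m_ij in {0,1,2}, a flat prior on `mu`, and the spike-and-
slab mixture prior on each marker effect: `alpha_j = 0` with probability
`pi`, `alpha_j ~ N(0, sigma2_alpha)` with probability `1 - pi`.  Both
variances carry scaled inverse chi-square priors and `pi` is uniform on
(0,1).  Sampling is single-site Gibbs: the intercept, then each
`(delta_j, alpha_j)` pair jointly from the exact two-component conditional
(the inclusion odds marginalise `alpha_j`), then `pi` from its Beta
conjugate, then the two variances from their scaled inverse chi-square
conditionals.  Genotype columns are centered internally; the intercept
absorbs the shift and every window statistic downstream is shift-invariant.

Hyperparameter defaults follow the conventions of the animal-breeding
whole-genome regression packages: `nu_alpha = nu_e = 4`; `scale_e` set so
the prior mean of `sigma2_e` equals `Var(y) * (1 - v)`; `scale_alpha` set so
the prior mean of `sigma2_alpha` equals `v * Var(y) / ((1 - pi0) * sum_j
2 f_j (1 - f_j))` with `pi0 = 0.5`, where `v` (`genetic_variance_guess`,
default 0.5) is the assumed genetic fraction of phenotypic variance.  These
are weakly informative; the data dominate after a few hundred sweeps.
Chain defaults are 50,000/10,000/10 (iterations/burn-in/thinning) for
full-scale runs and 5,000/1,000/4 for desk-scale work; the stored-draw count
`(n_iter - burn_in)/thin >= 100` bounds WPPA resolution.  `pi` is clipped to
`[1e-8, 1 - 1e-8]` when sampled; pinning `pi` at exactly 0 or 1 switches the
inclusion step to its deterministic limit (used by the conjugate-oracle
tests).  The per-locus loop is numba-compiled; all random variates come from
a single numpy Generator in the driver, so chains are bit-reproducible from
the seed and independent of numba internals.

## Window statistics and WPPA

For stored draw `alpha`, the window genotypic value is `g_w = M_w alpha_w`
and its variance is the *population* variance `sum(g^2)/n - (sum(g)/n)^2`
(dividing by `n`, not `n-1` — the convention of the windowed-GWAS
literature).  The variance share is `q_w = sigma2_gw / sigma2_g`; on the
rare draw with zero total genetic variance all `q_w` are set to 0, keeping
the per-window sample counts equal.  WPPA is the fraction of draws with
`q_w > T`, strict inequality.  Threshold schemes:

* constant `T` (e.g. 0.1%),
* `T = 1/N` with `N` the number of non-empty windows,
* window-specific `T_w = p_w / p` (SNP share), which changes the null
  hypothesis from "every *window* explains an equal variance share" to
  "every *SNP* explains an equal share" and thereby removes the density
  artefact without touching `q_w` itself.

Physical windows bucket a marker at position `pos` into bin
`floor((pos-1)/size)` on 1-based coordinates; boundary markers belong to the
lower window and empty bins are not counted in `N` (thresholds built from
`1/N` should reflect testable windows only).  Count windows are consecutive
runs of `k` markers that never span chromosomes; a short trailing run is
kept and flagged.  Dense windows are those whose SNP count exceeds the Tukey
fence Q3 + 1.5 IQR of the per-window count distribution, with
linear-interpolation quantiles so the fence is reproducible exactly.

## The frequentist comparator

The EMMAX-style windowed test fits the polygenic null `y = mu 1 + u + eps`,
`u ~ N(0, sigma2_poly K)`, once by REML — a single spectral decomposition of
the VanRaden method-1 kinship `K = ZZ'/sum_j 2 f_j (1-f_j)` and a bounded
scalar search on the heritability ratio (tolerance 1e-8 after a boundary
check) — then tests every window by generalized least squares of `y` on
`[1, M_w]` with the components held fixed.  The Wald statistic
`alpha_hat' Var(alpha_hat)^{-1} alpha_hat` is referred to chi-square with df
equal to the rank of the intercept-projected window design (the window SNP
count when full rank; rank-deficient windows use an eigen pseudo-inverse
with relative threshold 1e-8).  Two deliberate approximations define the
comparator: components are not re-estimated per window, and the tested
window's SNPs stay inside `K`.  With the true components the test is
exactly calibrated (verified by a uniformity test in the suite); with
REML-estimated components at desk scale (n = 300) it is conservative,
most visibly on dense windows whose df approaches n — the same mechanism
that depresses dense-window evidence and keeps the density/evidence
correlation near zero for this test.

## Synthetic panels

The generator emulates a diversity-panel chip rather than a coalescent
population: marker positions follow a piecewise-constant intensity
(baseline SNPs/Mb, with hotspot segments multiplied by a fold factor placed
uniformly without overlap), and each of the `2n` haplotypes thresholds an
AR-style Gaussian process — `corr(Z_j, Z_{j+1}) = ld_rho *
exp(-dist/ld_decay_bp)` — at `Phi^{-1}(1 - f_j)`, `f_j ~ Uniform(maf
range)`.  This yields 0/1/2 dosages with tunable adjacent-marker LD decaying
with distance and a long right tail of per-window SNP counts, the two
structural features the method study needs.  It does not model population
structure, admixture, recombination hotspots in the LD (as opposed to
density) sense, or selection; passing tests therefore speak to the window
statistics under heterogeneous density and local LD, not to robustness
against confounding by structure.

Default desk-scale panel: n = 300 individuals, 4 chromosomes of 10 Mb,
baseline 75 SNPs/Mb, two 1-Mb hotspot stretches at 8-fold density, `ld_rho
= 0.9` with 100-kb decay, MAF in [0.05, 0.5] — about 4,000 SNPs in ~40
1-Mb windows whose count quartiles sit near 70/75/80 with dense windows of
200-380 SNPs.  The hotspot fold and panel shape were chosen so the
max/median window-count ratio matches the order observed on real diversity
panels (>= 5), and so a full desk-scale experiment (10 replicates at 5,000
sweeps) completes in minutes on one core.

Phenotypes: a configurable number of QTL drawn uniformly from the genotyped
SNPs (by default excluding dense windows, so any dense-window signal is a
false positive by construction), effects i.i.d. standard normal, residual
variance `Var_pop(g) (1 - h2)/h2` anchored to the *realized* genetic
variance; `realized_h2` is recorded so no test assumes exactness.  The
permutation diagnostic shuffles trait values against fixed genotypes.

## Power evaluation

Window scores (WPPA, or -log10 p for the comparator) are ranked against the
binary truth "window contains >= 1 QTL".  The figure of merit is the
partial area under the empirical ROC up to false-positive rate 5%, with
tied scores grouped into single ROC steps and linear interpolation at the
cut; the raw area is divided by 0.00125 (= 0.05^2/2, the chance-level
partial area) so a random classifier scores 1 and a perfect one 40.  The
experiment runner shares one MCMC chain per replicate across the three
Bayesian schemes (threshold choice never alters `q_w`), recomputes truth
labels on the count partition for the fixed-count method (different windows
are tested there), and derives all per-replicate seeds from one base seed.

## Numerical and design notes

* Missing dosages are imputed with the column mean rounded to the nearest
  integer dosage (numpy ties-to-even), keeping MCMC input integer-coded;
  counts are reported.  MAF ties at the threshold are retained.
* Allele frequency is always the dosage-sum frequency `f = sum/2n`.
* The PLINK bed/bim/fam codec counts dosage on the A1 allele.
* WPPA uses strict exceedance; a `q_w` sample exactly equal to `T` does not
  count.
* `reml_null` flags non-identifiable kinship (all eigenvalues equal) and
  reports the boundary rather than guessing.
* Degenerate inputs fail loudly: constant phenotypes, monomorphic columns
  reaching the GRM, empty windows, empty draw sets.

## Limitations

* The sampler supports a single fixed effect (the general mean); covariates
  and multi-trait models are out of scope.
* The generator's LD is local and stationary per chromosome; no population
  structure, so the mixed model's main confounder-control role is exercised
  only through the polygenic null.
* Desk-scale directional results (threshold-scheme power ordering, null
  correlation drop) are properties of the synthetic panel's density profile;
  magnitudes on real panels depend on their own density distributions.
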