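# Methods

## Model

A two-way admixture event places the admixed population on the segment
between its sources in allele-frequency space: `p_x = α p_a + (1−α) p_b`
coordinate-wise over the `s` retained SNPs.  Subsequent genetic drift is
treated as independent Brownian displacement of each population's
frequency vector, and finite sampling adds binomial noise on top.  The
estimator never models these noise sources explicitly; it relies on the
geometry: in high dimension, drift and sampling vectors are almost
orthogonal to any fixed direction, while directions built from
auxiliary-population differences retain the shared-ancestry component.

All f-statistics are per-SNP means of products of frequency differences
(`f2`, `f3`, `f4`), with `f4' = s·f4/f2(i,j)` normalising each
auxiliary-pair axis.  The mean-vs-sum convention is immaterial: the slope
and both angle cosines are ratios, invariant to any common rescaling of
the statistics.  No finite-sample bias correction (the `p(1−p)/(n−1)`
term familiar from other f-statistics software) is applied; the
formulation works with plain frequency vectors, and all quantities are
defined in those terms.

The admixture proportion is the closed-form through-origin least-squares
slope of `f4'(x,b;i,j)` on `f4'(a,b;i,j)` over all auxiliary pairs i < j.
Model quality is assessed by the vertex angle at the admixed population
computed twice: from raw proxy frequencies (ϕ, "pre-JL") and from the
projected coordinates (φ, "post-JL").  φ > ϕ indicates the projection
removed drift; φ < ϕ rejects the model; φ near 180° indicates the chosen
sources are close to the true ones.

## Why the auxiliary set must be phylogenetically informative

An auxiliary pair (i, j) contributes signal only if its difference
direction overlaps the source split, i.e. E[f4(a,b;i,j)] ≠ 0.  If every
auxiliary diverged independently from the common ancestor (a star
phylogeny), all f4 values are zero-mean noise products, the regression
cloud has no slope to estimate, and the projected estimate collapses to
the (biased) raw projection.  This is a property of the method, not of
the implementation, and it drives the design of the synthetic generator
below.  In real data the analogous requirement is that the reference
populations share ancestry asymmetrically with the two sources.

## Synthetic data generator

Per SNP: ancestral frequency `p0 ~ Uniform(0.05, 0.95)`; each source
drifts from `p0` by a clipped Gaussian step of SD `divergence_sd`
(default 0.02); the target is the exact `α/(1−α)` blend of the sources at
admixture time; target and sources then take one further independent step
of SD `drift_sd` (default 0.02, the post-admixture drift the estimator
must undo).  Each auxiliary branches off one source lineage at a uniform
random time `t`, its branch point drawn from the Brownian bridge between
ancestor and source (SD `divergence_sd·√(t(1−t))`), then takes one
private `drift_sd` step.  Frequencies are clipped to [0.01, 0.99] to
avoid fixation, which would create zero-length difference vectors in the
angle cosines.  Diploid genotypes are Binomial(2, p) per individual
(default 10 per population) and optionally masked at a missing rate.

Drift is modelled as Gaussian increments rather than Wright–Fisher
binomial resampling: the variance is controlled directly and the
straight-line-to-triangle geometry is reproduced without simulating
generations.  `divergence_sd` is separate from `drift_sd` because the
admixture-time triplet must survive the `drift_sd → 0` limit (in which
the dataset is exactly collinear up to genotype sampling); a single knob
for both would collapse every population onto the ancestor.

What the generator does **not** emulate: linkage disequilibrium between
SNPs (blocks of adjacent SNPs are exchangeable here, unlike real
chromosomes), ascertainment bias, non-uniform drift across populations,
and deep multi-furcating phylogenies.  Passing tests therefore
demonstrate correctness of the estimator under the model's own geometry,
not robustness to those real-data features.

The default scale (50 000 SNPs, 10 auxiliaries, 10 diploids, α = 0.2)
was chosen as a realistic desk-scale version of published simulated
admixture studies; at this scale the per-replicate estimate has an SD
near 0.09 and its mean over 20 replicates recovers α within 0.02.

The deliberately mis-specified model used in rejection tests replaces
both sources by the two auxiliaries most distant (by `min` of the two
`f2` values) from either true source — the analogue of proposing two
unrelated proxies — keeping the rest as the reference set.

## Uncertainty

* **Fit half-width (Δ1)** — a t-interval for the through-origin slope:
  `SE² = Σ(y−αx)² / ((n−1)·Σx²)` over the n pairs, Δ1 = t(n−1, 0.975)·SE.
* **Auxiliary bootstrap (Δ2)** — the m auxiliary labels are resampled
  with replacement; pairs are re-enumerated from the resampled multiset,
  skipping self-pairs and degenerate pairs (f2 = 0); the statistic (slope
  or φ) is recomputed per replicate and Δ2 is the half-width of the
  percentile interval.  Percentile rather than BCa: it is the plainest
  reading of a bootstrap CI and the replicate distributions here are
  near-symmetric.  Defaults: 1000 replicates, level 0.95, at least 8
  auxiliaries so resamples retain enough distinct labels; replicates with
  fewer than two distinct usable labels are redrawn (bounded retries).
  ϕ carries no error bar — it does not depend on the auxiliaries.
  The pair-level f2/f4 values are precomputed once (O(s·m)), making each
  replicate O(m²); resampling is driven by one explicit seed.
  Simulation at s = 3000 puts the interval's coverage of the true α near
  80 % — bootstrap over a handful of outgroups is not an exact pivot, so
  Δ2 should be read as a stability indicator, not an exact CI.
* **Block analysis** — for each block size L, α, ϕ and φ are recomputed
  on random-origin blocks of L adjacent retained SNPs (origins uniform on
  [0, s−L], drawn with replacement, no wrap-around; default 20 blocks per
  size) and summarised by mean and one population-convention SD, showing
  how the estimates stabilise as the frequency-space dimension grows.

## Numerical choices and degenerate inputs

* Angle cosines are clamped to [−1, 1]; by Cauchy–Schwarz the overshoot
  can only be rounding-level (~1e−16).  Angles are reported in degrees,
  displayed at 0.1° precision.
* The model-validity rule `φ > ϕ` is applied with a 1e−6-degree
  tolerance so the exactly collinear case (ϕ = φ = 180°) counts as valid.
* A pair with `f2(i,j) = 0` (identical auxiliary columns) defines no
  axis and raises a degenerate-pair error naming the pair; per-pair
  f4-ratios with zero denominator are reported as undefined, never
  silently dropped, and excluded from the in-range ([0, 1]) mean.
* All-zero `f4'(a,b;·)` (auxiliaries blind to the source split) raises an
  undefined-slope error rather than returning 0/0.
* Genotype value counts the first `.snp` allele; every downstream
  statistic is invariant under per-SNP allele flips, so the choice of
  reference allele is irrelevant.
* A SNP is dropped iff some selected population has no genotyped
  individual there; partially missing SNPs keep reduced denominators.
  `max_snps` truncation happens before this filter.
* PCA treats populations (not individuals) as observations, centres each
  SNP across the selected populations and applies no `√(p(1−p))`
  scaling; component signs are fixed by making the largest-magnitude
  loading positive, so repeated runs are bit-identical.
* Summation is plain numpy over SNP-ascending order in a single process;
  the `--procs` CLI flag is accepted for batch-script compatibility but
  never alters any output value.

## Open design points resolved here

* The "pre-JL proportion" diagnostic is defined as the through-origin
  projection of `x − b` on `a − b` in raw frequency space — the natural
  no-projection analogue of the slope formula.  Note that under heavy
  drift/sampling noise it is biased toward 0.5 (shared noise of source b
  enters numerator and denominator), so it can over- rather than
  under-estimate a small α; its role is purely diagnostic.
* "In range" for f4-ratios means the closed interval [0, 1], the domain
  where a proportion is meaningful.
* The bootstrap resamples population labels, not pairs or SNPs.

## Known limitations

Two-way models only; no qpAdm-style rank testing; no SNP-block jackknife
standard errors for individual f-statistics; no VCF/PLINK input; datasets
are held in memory (fine up to millions of SNPs × dozens of populations).
With only ~10 auxiliaries the bootstrap error bar is wide and the
per-replicate α estimate is noisy — conclusions should rest on the angle
pair (ϕ, φ) as much as on the point estimate, mirroring how the method is
meant to be used.
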