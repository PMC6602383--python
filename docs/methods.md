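# Methods

This note documents the statistical procedures implemented in
`methcortex`, the assumptions behind them, the defaults and why they
were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would want to know.

## Quality control

Probes are removed for (i) failed detection — a probe is dropped when
its detection p-value exceeds 0.05 in at least `max(1, ceil(0.01 * n_samples))`
samples; the `max(1, …)` makes the 1%-of-samples rule behave like the
practical p-filter for cohorts of up to 100 samples, where any single
failure removes the probe; (ii) SNP genotyping probes; (iii) known
cross-reactive probes; and (iv) probes with a common SNP within 10 bp
of the single-base-extension position. Flags (ii)-(iv) come from the
manifest. The retained set is order-independent; removal counts are
attributed sequentially so they sum to the total dropped.

Sample sex is verified by classical (Torgerson) multidimensional
scaling of Euclidean distances over sex-chromosome probes: the first
coordinate is split by an exact 1-D 2-means, each cluster labelled by
its majority reported sex, and discordant samples flagged. Sample
identity across regions of a donor is verified by Pearson correlation
of SNP-probe betas, which behave like genotypes (same-donor pairs
correlate near 1, cross-donor pairs far lower; the default concordance
threshold is 0.9).

## Normalisation and batch adjustment

Methylated and unmethylated intensities are quantile-normalised
separately within each probe design type (the two Infinium chemistries
have different beta distributions, so pooling them distorts both), and
betas are recomputed as `M / (M + U + 100)`. This is a stratified
between-array quantile normalisation; the background-drift spline some
implementations add is deliberately omitted — with synthetic data that
has no scanner drift it would be untestable, and the stratified
normalisation is the component that matters for the downstream models.
Ties are broken by row order (ordinal ranks).

Batch (brain bank) adjustment is the parametric empirical-Bayes
location/scale model: per probe, data are standardised on the residuals
of a model containing batch indicators plus protected covariates
(diagnosis, age and sex by default — the covariates whose effects must
survive correction); per-batch means are shrunk through a normal prior
and per-batch variances through an inverse-gamma prior, both with
method-of-moments hyperparameters estimated across probes; the adjusted
data are rescaled and the protected effects restored. `shrink=False`
gives the raw location/scale correction (exact per-batch mean
equalisation), useful for testing. Single-batch input is returned
unchanged; a batch with fewer than two samples is an error. Final
values are clipped to [0, 1].

## Cell composition and the epigenetic clock

Neuronal proportion is a two-component least-squares deconvolution
against neuron/glia reference profiles at marker CpGs; the minimiser is
the closed-form projection of `x - g` onto `n - g`, clipped to [0, 1],
which equals a dense grid search to numerical precision in the
two-component case. At least 10 markers must be present; missing
markers are dropped. Cerebellum is skipped and the covariate dropped
from cerebellar models, because most cerebellar neurons are
NeuN-negative and cortical references do not transfer; this is
implemented as a per-region covariate mask.

Methylation age applies a linear clock and inverts the log-linear age
transform used to train such clocks: `age = (1 + A) exp(raw) - 1` for
`raw < 0`, else `A + raw (1 + A)`, with adult-age knot `A = 20`. The
inverse is continuous and strictly increasing. Clock weights are
supplied as a CSV; the package ships no trained clock — the synthetic
generator builds a 30-CpG clock whose CpGs move linearly with
transformed age, which suffices to validate the computation but says
nothing about any published clock's accuracy. Up to 20% missing clock
CpGs are mean-imputed from the cohort with a warning; more is an error.
Age acceleration is the residual of an OLS of methylation age on
chronological age fit per region on all samples, compared between
groups with Welch's t-test; identically zero residuals give p = 1 by
convention.

## Per-probe differential methylation

Effects are estimated and reported on the beta scale (delta-beta,
case minus control), not M-values, so they read directly as
percentage-point methylation differences. Within a region the model is
OLS with the diagnosis indicator and covariates; missing beta values
are handled by listwise deletion per probe; a singular design (e.g.
bank perfectly confounded with diagnosis) yields flagged rows with
missing p-values rather than a crash. Zero-variance probes with zero
effect get p = 1 rather than being dropped, keeping the tested set
stable.

The cross-cortex model adds a donor random intercept. It is fitted by
REML profiled over the variance ratio `lambda = sigma_donor^2 /
sigma_e^2`: the marginal covariance `I + lambda Z Z'` is diagonalised
once (the eigenbasis is shared by all probes because the design is),
the criterion is evaluated on a log-spaced lambda grid for all probes
simultaneously, and each probe's optimum is refined by golden-section
search; lambda = 0 is always a candidate, and at that boundary the fit
reduces exactly to pooled OLS. Inference on the diagnosis effect is a
Wald z-test — no Satterthwaite or Kenward-Roger degrees-of-freedom
correction — which is mildly anticonservative at small donor counts;
at the 30-donors-per-group scale the package targets, the null
calibration checks show the approximation is adequate.

Significance tiers: discovery at p < 5e-5 (strict inequality) and
experiment-wide at the Bonferroni threshold 0.05 / n_probes; the
experiment-wide tier is a subset of the discovery tier by construction.

Supporting analyses: hierarchical clustering of samples at called DMPs
(average linkage on 1 − Pearson over DMP betas, two clusters, per-
cluster case fraction); effect-size concordance between patient groups
(Pearson r over a probe set, optionally stratified inside/outside a
genomic interval such as the duplicated locus); Fisher's z-test for
comparing two independent correlations; and expression integration,
where every gene annotated to a DMP contributes a probe-gene pair and
the correlation between delta-beta and log-fold-change is computed over
pairs whose transcript passes the FDR cut.

## DMR calling

The spatial combination follows the comb-p recipe. P-values are
converted one-sidedly (`z = Phi^{-1}(1 - p)`); the autocorrelation of z
by genomic distance is estimated in 50-bp bins up to 300 bp from the
same p-value set being corrected (as the original procedure does);
empty bins inherit the nearest smaller-lag value, starting from 1 at
lag zero. Each probe's p is replaced by the Stouffer-Liptak combination
of its window (unit weights; combined variance `1' Sigma 1` from the
binned ACF); isolated probes are unchanged. Seeds are probes with
adjusted p below 1e-3; consecutive seeds join a region while gaps are
at most 300 bp (the boundary is inclusive — the reference
implementation is ambiguous there, and ≤ was chosen and documented);
regions need at least two probes. Each region is scored by the
Stouffer-Liptak combination of its raw p-values with the ACF-derived
correlation matrix; if that matrix is not positive definite its
eigenvalues are floored at 1e-8 before the combined variance is formed.
The Sidak correction `1 - (1 - p)^{T/L}` uses territory T = bp spanned
by tested probes plus 300 bp on each flank summed over chromosomes, and
region length L = `end - start + 1` floored at the median inter-probe
spacing (so a single-position region cannot have zero length); it is
evaluated in log space (`-expm1(k log1p(-p))`) so small p-values
survive.

## CNV detection

Total intensity (M + U) scales with DNA copy number. Totals are
quantile-normalised across the test sample and its control panel
(removing array-brightness differences), per-probe log2 ratios are
taken against the control median, probes with zero control median are
masked, and the ratio track is median-centred so a genome-wide scaling
cannot mimic a gain — the documented consequence is that a
whole-genome duplication would be invisible, which is the correct
behaviour for a relative-intensity method. Segmentation is a bespoke
recursive binary splitter: the split maximising the reduction in
residual sum of squares is accepted when the reduction exceeds
`penalty * sigma^2` (default penalty 30, with sigma estimated robustly
from the MAD of first differences) and both sides keep `min_seg`
probes (default 10). The defaults were chosen so that a 3-copy gain
(log2 1.5 ≈ 0.585) over tens of probes is detected against noise of SD
0.1 while a flat track stays one segment; both are configurable.
Segments with mean ratio above 0.3 across at least 20 probes are called
gains; a sample is duplication-positive when a gain overlaps the
configured 15q11-13 interval. Quantile normalisation slightly
attenuates the measured gain when the aberrant locus is a large
fraction of all probes; at realistic locus fractions (a few percent)
the attenuation is within a few percent of log2(1.5).

## Co-methylation network

The network stage follows the weighted-correlation recipe on the
cross-cortex samples: probes with a central methylation range above 5%
(0.9 minus 0.1 quantile, strict inequality) are kept; the effects of
age and cell composition are regressed out per probe from a model that
also contains diagnosis, sex, region and bank, subtracting only the
nuisance contribution so disease signal correlated with the protected
covariates survives; a signed adjacency `((1 + bicor)/2)^7` is built
from biweight midcorrelations (Tukey weights `(1-u^2)^2`, `u = (x -
median)/(9 MAD)`, Pearson fallback when MAD = 0); and similarity is
re-weighted by topological overlap.

Module extraction deviates deliberately from the dynamic-hybrid tree
cut, whose published description does not specify its internals at the
level needed for a faithful reimplementation. Instead a static
relative-height rule is applied to the average-linkage dendrogram of
`1 - TOM`: a subtree of at least `minModuleSize` probes becomes a
module when its top merge height is below `cut_fraction` (default
0.995) of the height at which it joins the rest of the tree — a branch
that hangs clearly below its attachment point. Chained noise, whose
merge heights are nearly equal, shatters into unassigned probes. A
qualifying branch is further split while both halves are large enough
and complete below 0.9 of its height (so two distinct modules that
happen to merge with each other before joining the background are
separated). The root, which has no attachment point, qualifies when its
height is below an absolute dissimilarity of 0.9, covering the case
where the whole input is one co-methylated block. Modules whose
eigengenes correlate above `1 - mergeCutHeight` (default 0.1) are
merged iteratively, and labels are renumbered by decreasing size with 0
meaning unassigned. This rule recovers planted block structure exactly
and names no modules on pure noise across the sizes tested, but it is
not the dynamic-hybrid algorithm: module counts and boundaries on real
data will differ from WGCNA's, and nested sub-modules that the deepSplit
heuristics would separate may stay together.

Above `maxBlockSize` probes (default 15,000) the probes are first split
into blocks by k-means on a principal-component embedding, modules are
detected per block, and block-wise modules are merged across blocks by
the same eigengene rule. Probe order never matters (input is
canonically sorted).

The module eigengene is the first right singular vector of the
probe-standardised module matrix, scaled to unit variance and
sign-anchored to correlate positively with the module's mean
methylation. Module-trait association fits, per module and contrast
(iASD vs control, dup15q vs control, combined ASD vs control), the same
donor-random-intercept model as the probe-level analysis with the
eigengene as outcome, then applies Benjamini-Hochberg correction across
modules within each contrast.

## Pathway enrichment

Genes are assigned to probes from the manifest annotation; a listed
gene counts when the probe overlaps it or lies within 1500 bp upstream
of its transcription start site (the signed `tss_distance` convention:
negative = upstream). Intergenic probes contribute nothing;
multi-annotated probes contribute every gene. The universe is all genes
with at least one QC-passing probe and at least one pathway; pathways
are tested only at 10-2000 universe genes. The test is a logistic
regression of pathway membership on test-list membership plus
`log(probe count + 1)` — the log taming the right-skewed count
distribution (a raw-count mode exists) — with a two-sided Wald test on
the test-list coefficient; direction is read from the coefficient sign.
When maximum likelihood separates or fails to converge, a Firth-
penalised fit (Jeffreys-prior score correction) is used instead.
Grouping iteratively pops the most significant remaining pathway as a
group head (p ties broken by pathway id, making the output
deterministic) and retests the others with head membership as an extra
covariate; a pathway whose coefficient p rises above 0.05 joins the head's group
(the grouping threshold reuses the 0.05 significance level; no separate
threshold is established for "no longer predicts"). The algorithm terminates in at most as many iterations as there
are significant pathways. Parent-term propagation is assumed already
applied in the input GMT.

## The synthetic-data generator

`synthdata` emulates the structure each stage assumes: a probe grid
with strictly increasing coordinates, gene annotations assigned in runs
(so per-gene probe counts vary as on the real array) and ~2% flagged
probes; donors in three diagnostic groups (defaults 38 controls, 36
idiopathic ASD, 7 duplication carriers — the scale of a three-bank,
three-region brain cohort) with banks cycled within groups (cohorts are
randomised with respect to bank, so diagnosis and bank are never
confounded); per-sample betas as baseline + diagnosis effects + bank
shift + cell mixture + module factors + donor intercept + Gaussian
noise, clipped to [0, 1]; SNP probes carrying per-donor genotypes
shared across that donor's samples; X-chromosome probes shifted by sex;
clock CpGs moving linearly with transformed (optionally group-shifted)
age; and M/U intensities with log-normal per-probe brightness (long
upper tail, as on real arrays) satisfying `M/(M+U+100) ≈ beta`, with
total intensity multiplied by CN/2 inside the duplication locus for
carriers and log-normal noise (SD 0.1 total, 0.02 per channel).

Defaults the literature does not pin down were fixed once: within-group
beta noise SD 0.03 (chosen from the 0.02-0.05 range for adequate power
at the planted effect sizes, not fitted to any dataset), donor
intercept SD 0.02, cortical neuronal proportions uniform on
[0.25, 0.55], donor ages uniform on [2, 60].

What it does **not** emulate — and therefore what passing tests do not
show about real data: beta-distributed (heteroscedastic, boundary-
inflated) noise — noise is Gaussian with clipping, so boundary probes
behave more symmetrically than real ones; probe-type-specific dye
chemistry and background; scanner drift; linkage between SNP probes;
cell-composition effects outside the marker probes; and any real CpG-
island or gene structure. Recovery rates measured here are therefore
statements about the implemented estimators under their assumed models,
not about performance on any particular cohort.

Module latent factors are drawn per sample (not per donor), with an
optional mean shift in affected groups; a factor's realised
case-control difference therefore varies around the planted shift by
±2/sqrt(n_samples).

## Numerical conventions

1-based inclusive genomic coordinates internally (array-manifest
convention); BED export converts to 0-based half-open. Missing betas
read as empty cells or `NA`. P-values are clipped to [1e-300, 1-1e-16]
before normal inversion. All generator randomness flows from one seed
through named `SeedSequence` streams, so identical designs give
bit-identical cohorts and every pipeline re-run with the same
configuration and seed reproduces its CSV outputs exactly.

## Problem sizes used in validation

The validation suite exercises the stages at the scale they are
designed for while remaining quick to run: the differential-methylation
and calibration checks use 20,000-probe cohorts with 30 donors per
group and two cortical regions; DMR detection uses 20 planted and 20
null replicates at the same scale (the standalone acceptance script
uses 10 + 10); CNV breakpoint recovery uses 100 simulated chromosomes
of 1000 probes; network recovery uses 900-probe inputs with two
150-probe planted modules; enrichment calibration uses 500 confounded-
null replicates over 500-gene universes and 100 planted-pathway
replicates over 800-gene universes.
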