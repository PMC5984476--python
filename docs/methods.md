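# Methods

This note records the statistical machinery implemented in `gsabench`, the
defaults it ships with and why, the numerical choices that would otherwise
be invisible, and the limits of what the synthetic study conditions can
demonstrate.

## Semi-synthetic simulation model

**Baseline and preprocessing.** A baseline dataset is any genes × samples
matrix with binary labels.  The canonical preprocessing is quantile
normalization (every sample mapped onto the across-sample mean order
statistics, with tied values receiving the mean of the reference values at
their tied ranks) followed by per-gene centering.  Centering guarantees a
mean case-minus-control difference of exactly zero for every gene while
leaving pairwise gene correlations and per-gene spread untouched; the
pipeline therefore hands the injector a dataset with *known* (null) signal
and *realistic* dependence.  Note the composed pipeline is not idempotent —
centering rows breaks the common column distribution that normalization
established — so it is applied exactly once; each step individually is a
fixed point of itself.

**Signal injection.** For a target set of size `m`, an altered-proportion
`π ∈ (0, 1]` and an effect size `τ ≥ 0`, `round(π·m)` genes (at least one
when `π > 0`) are drawn uniformly without replacement, and every *case*
sample of a drawn gene is shifted by `±τ·sd_g`, where `sd_g` is the gene's
across-all-sample standard deviation (sample SD, `ddof=1`) computed before
injection.  The shift is upward by default and applied with the same sign to
all altered genes.  The altered list is returned so truth is trackable
downstream.  Within the power harness the altered subsets are *nested* in
π: one master shuffle of the target set is drawn per study and each π-cell
alters its prefix.  Each prefix is still a uniform draw, and nesting removes
subset-choice noise from power comparisons across π.

**Bootstrap replicates.** Replicates resample samples with replacement
within each class, preserving the design's class sizes exactly (each column
position is refilled by a random member of its own class); sample ids are
suffixed to stay unique.  Power for a cell is the fraction of replicates in
which the target set is significant at `α = 0.05` — on BH q-values by
default for methods whose pipeline includes an FDR step, on raw p-values
behind a per-method flag (both proportions are always reported).

**Null constructions.** Three, mirroring the power definition:
label permutation (expression untouched), iid standard-normal expression
with randomly assigned labels (correlation structure destroyed), and τ = 0
injection (bootstrap replicates of the centered baseline).  The false
positive rate of a method is the per-set rejection proportion at raw
p < 0.05, summarised across sets by the median and quartiles.

**Synthetic baseline generator.** Real microarray baselines show blocks of
co-regulated, positively correlated genes against a mostly uncorrelated
background.  The generator emulates this with compound-symmetric blocks:
within a block of size `b`, `x = √ρ·z_block + √(1−ρ)·ε` gives exchangeable
pairwise correlation ρ and standard-normal marginals; blocks are mutually
independent, remaining genes fully independent.  Defaults: 1,000 genes,
40 samples (20 cases + 20 controls), twenty blocks of 25 genes at ρ = 0.3 —
a deliberately desk-scale stand-in with a correlation density in the range
reported for summarized expression arrays.  What it does **not** emulate:
heavy-tailed and heteroskedastic expression distributions, negative and
long-range correlation, batch structure, or any alignment between
correlation blocks and the gene sets under test (random sets straddle
blocks, so their within-set correlation is near zero).  Consequently,
passing null-calibration tests here does not certify competitive methods on
real data where knowledge-base sets *are* co-expression modules — that
regime is exercised separately by the correlated-set contrast (below).

## Gene-level statistics

All statistics are signed case minus control.  Pooled-variance Student t
(default local statistic), Welch t with Satterthwaite df, signal-to-noise
`(x̄₁−x̄₀)/(s₁+s₀)` with each class SD floored at `max(0.2·|x̄|, 0.2)`
(the convention of the reference ranking metric; the floor is configurable
and can be disabled), and an empirical-Bayes moderated t.  The moderated-t
prior `(d₀, s₀²)` is estimated by moment matching on log variances:
`e_g = log s²_g − ψ(d_g/2) + log(d_g/2)` has variance `ψ′(d₀/2)` in excess
of the sampling term, and the trigamma equation is inverted by Newton
iteration; the posterior variance `(d₀s₀² + d_g s²_g)/(d₀+d_g)` replaces
`s²_g`.  When the observed excess is non-positive the prior df is infinite
(full shrinkage).  Degenerate genes (zero variance in both classes) score 0
when means agree and ±1e6 with a warning otherwise — rank-based machinery
downstream only needs a consistent extreme.

## Set-level methods

**Enrichment-score testing (GSEA).** Genes are ranked descending by the
metric with ties broken by gene id (so permutation distributions are
reproducible).  ES is the maximal signed deviation of the weighted running
sum (hit step `|r_i|^p / Σ_hits |r_j|^p`, miss step `−1/(N−m)`, default
`p = 1`; `p = 0` recovers the classic Kolmogorov–Smirnov form).  The
implementation evaluates the walk only at hit positions (its extremes can
occur nowhere else), which is what makes desk-scale permutation grids cheap;
a brute-force full running sum is kept in the test suite as the oracle.  If
the maximal positive and negative deviations tie in magnitude (within 1e-12)
the positive one is returned.  Phenotype mode re-ranks under permuted labels
(self-contained); gene mode resamples m-gene subsets of the fixed ranked
list (competitive).  P-values are two-sided on |ES| with add-one smoothing,
`(1 + #{|ES_perm| ≥ |ES_obs|})/(B+1)`; when the number of distinct label
assignments does not exceed B the null is enumerated exactly (identity
included, so the plain proportion is already bounded away from zero).
A normalized ES is deliberately not computed — power is scored on p/q-values
throughout.

**Two-stage testing (SAFE).** Local Student t, then one of four globals:
Wilcoxon rank sum of the set's local statistics among all N (mid-ranks),
average-difference pooled t (set vs complement), Pearson chi-squared
(no continuity correction) of the 2×2 table of set membership against a
"flagged" indicator, and the Fisher-exact hypergeometric tail of the same
table.  The flagging threshold — nowhere pinned down by the method's usual
descriptions — is the top 5 % of |local| (`fet_quantile = 0.95`,
configurable), with at least one gene flagged.  Permutation inference
recomputes local and global statistics under B label permutations; the
location-type globals use two-sided min-tail doubling
`min(1, 2·min(F̂_lo, F̂_hi))`, the chi-squared global its upper tail.
Bootstrap inference resamples samples within class and scores
`p = 2·min(F̂(θ₀), 1−F̂(θ₀))` where F̂ is the bootstrap CDF of the global
statistic and θ₀ its analytic null mean (Wilcoxon `m(N+1)/2`, avediff 0,
chi-squared 1) — a bootstrap-z style criterion with much finer resolution
than B permutations, which is exactly why it rescues power at strong
signal.

*The Fisher-exact global is deliberately miscalibrated.*  An exact
hypergeometric test with the inclusive tail `P(X ≥ x)` cannot exceed its
nominal level under an exchangeable null, yet inflated false positive rates
are the known signature of this variant.  The package reproduces that
signature by scoring FET with the analytic *strict* tail `P(X > x)` used
directly as the p-value; on a discrete overlap count the strict tail is
anti-conservative (median per-set FPR ≈ 0.08 at α = 0.05 under the iid
null, versus ≈ 0.05 for every other method).  This is documented as an
emulation of anomalous tool behaviour, not a recommendation: the statistic
column still reports the inclusive tail, and `fet_inclusive=True` switches
to the calibrated convention.

**Normalized mean statistic (sigPathway-style).** The set statistic is the
equal-weight mean of the member genes' t statistics, normalized to
`z = √m (T̄ − μ̂)/σ̂` with μ̂, σ̂ the moments of all gene statistics.  The
competitive null resamples m-gene subsets (one shared pool of index
permutations serves all sets); a rank-sum set statistic and a
phenotype-permutation (self-contained) mode sit behind flags.  Gene
resampling deliberately ignores inter-gene correlation — that is faithful
to the method being benchmarked, and the correlation-adjusted test below is
the contrast.

**Correlation-adjusted competitive testing (CAMERA-style).** Each gene's
data is projected onto the orthogonal complement of the two-group design
(intercept + case indicator, via full QR), giving n−2 independent residual
effects per gene; ρ̄ is the mean pairwise correlation of those residual
vectors (cosine form — residuals are already orthogonal to the intercept,
so no re-centering), and `VIF = 1 + (m−1)ρ̄`, floored at 0.01 to avoid
negative-variance pathologies for small sets with negative ρ̄.  Rank mode
(default, softer assumptions): Wilcoxon rank-sum z with its variance
multiplied by the VIF.  Parametric mode: two-sample t of gene statistics
with the set-mean variance inflated, `se = s_p·√(VIF/m + 1/m₂)`, df N−2.
Gene metric defaults to moderated t.  Inference is asymptotic — no
resampling — which is why this method is orders of magnitude faster than
the permutation-based ones.  `adjust=False` exposes the unadjusted test:
on a 50-gene set with within-set ρ = 0.2 and no signal the unadjusted
rank-sum rejects more than half the time while the adjusted test stays at
the nominal 5 %.

## Multiplicity

BH step-up q-values (`q_i = min_{p_j ≥ p_i} m·p_j/rank_j`, capped at 1) are
the standard route, verified against a literal step-up oracle.  The
*median-anchored* q-value emulates the pathological alternative in which
the q-value is driven by the median of a p-value distribution rather than
each set's own extreme observation.  The exact formula, fixed here and by
regression tests: the pseudo-p of set s is the add-one tail fraction of
s's own permutation distribution evaluated at the **median of the observed
statistics across sets**, followed by BH.  When every set shares one
distribution and one observation this reduces exactly to the ordinary
tail p; when one set's observation is far beyond all its permutations the
pseudo-p stays at the null level — so power under the median-anchored
q-value stalls as the injected effect grows, while BH on the raw
permutation p-values keeps responding.  This is a behavioural emulation of
a described pathology, not a numerical reimplementation of any particular
tool's internals.

## Study conditions and problem sizes

The shipped desk-scale conditions are: 1,000 genes, 40 samples (20/20),
50 random gene sets of sizes 10–100, B = 200 resamples, 50 replicates per
cell, α = 0.05 — the package's own choice of a grid that exercises every
code path while a full suite completes in minutes; the classic large-scale
grid (τ ∈ {0.25, 0.5, 1, 2, 10}, π ∈ {0.05, 0.1, 0.25, 0.5, 1}, 100
replicates, B = 1000) is the `SimulationSpec`/CLI default for real studies.
Two resolution effects matter at desk scale and are accounted for in the
shipped analyses rather than hidden:

* with B permutations the smallest achievable p is `1/(B+1)`, so a BH
  q-value over 50 sets cannot fall below `50/(B+1)`; power on q-values is
  therefore measured at B = 1999 (floor 0.025 < α), while null FPR uses
  raw p at B = 200 as the calibration target is the p-value itself;
* the SAFE bootstrap criterion reaches `2/(B+1)` and so retains power where
  the equally sized permutation run cannot — the point of that comparison.

Determinism: every stochastic component draws from streams spawned off one
master `SeedSequence` per (cell, replicate, method), so full-grid results
are bit-reproducible and independent of execution order; replicates are
embarrassingly parallel units by construction.

## Known limitations

Injected genes are shifted independently — the simulator does not add
correlation *among the altered genes themselves* (a documented future hook);
real enriched pathways are often co-expressed, which is known to reduce
power across methods.  The baseline generator's limitations are listed
above.  SAFE's paired/ANOVA local statistics, per-gene resampling, NES
normalization and leading-edge reporting, and covariate designs beyond
two groups are out of scope.  The moderated-t prior uses closed-form moment
matching rather than full marginal maximum likelihood; for the designs here
the two agree to well within the shrinkage noise.
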