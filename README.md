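# gsabench

Semi-synthetic simulation and statistical benchmarking of **gene set
analysis (GSA)** methods for case/control expression studies.

## The problem

GSA asks whether a predefined group of genes (a pathway from a knowledge
base such as MSigDB) is associated with a phenotype, rather than testing
genes one at a time.  Methods differ in their null hypothesis — a
*self-contained* null says the set's genes show no association at all, a
*competitive* null says they are no more associated than the rest of the
genome — and in how they aggregate gene-level evidence.  Benchmarking them
on real data alone is impossible (the truly enriched sets are unknown), and
purely synthetic data misses the correlation structure that drives
competitive tests.  `gsabench` takes the semi-synthetic middle road: start
from a real (or realistically correlated synthetic) baseline, erase its
signal, and *inject* a known amount of differential expression into a chosen
target set.

The simulation recipe:

1. **Preprocess** the baseline: quantile-normalize samples, then center every
   gene at mean zero — signal becomes exactly zero while the gene–gene
   correlation structure survives.
2. **Inject signal** into a target set of size *m*: choose `round(π·m)` of
   its genes at random and shift every *case* sample of each chosen gene by
   `τ·sd_g`, where `sd_g` is the gene's pre-injection standard deviation.
   π is the altered proportion, τ the effect size in per-gene SD units.
3. **Bootstrap** the injected dataset, resampling samples with replacement
   *within* each class, so every replicate keeps the original case/control
   balance.
4. **Power** = the fraction of replicates in which a method declares the
   target set significant at α = 0.05.  False positive rates come from three
   null constructions: permuted labels, iid standard-normal expression, and
   τ = 0 injection.

## The methods benchmarked

All four are implemented here as statsmodels-style models — construct from
`(ExpressionDataset, GeneSetCollection)`, call `fit(seed)`, get a results
object with a per-set table and `summary()`:

* **`GSEA`** — genes are ranked by a metric (signal-to-noise by default); a
  weighted running sum rises by `|r_i|^p / Σ_hits |r_j|^p` at set members and
  falls by `1/(N−m)` between them; the enrichment score ES is the maximal
  signed deviation of the walk.  Phenotype permutation gives the
  self-contained test, gene permutation the competitive one.
* **`SAFE`** — two-stage: a local statistic per gene (Student t), then a
  global set statistic (Wilcoxon rank sum, average-difference t,
  Pearson chi-squared of a top-|t| contingency table, or Fisher's exact
  tail), calibrated by label permutation or within-class bootstrap.
* **`SigPathway`** — competitive normalized mean statistic
  `z = √m · (T̄_set − μ̂)/σ̂` against a gene-resampling null.
* **`Camera`** — competitive test corrected for inter-gene correlation: the
  variance inflation factor `VIF = 1 + (m−1)ρ̄` is estimated from QR
  residual effects and scales the variance of the set-level z (rank or
  parametric mode).

`PowerStudy` and `NullSuite` orchestrate the (π, τ) grid and the three null
suites over any roster of methods; `bh_fdr` and the median-anchored
`gsea_median_q` emulation handle multiplicity.

## Worked example

```python
import numpy as np
from gsabench import (BaselineSpec, Camera, GSEA, GeneSet, GeneSetCollection,
                      MethodRunner, PowerStudy, SigPathway, generate_baseline,
                      random_collection)

baseline = generate_baseline(BaselineSpec(seed=23))   # 1000 genes, 20+20 samples
rng = np.random.default_rng(101)
target = GeneSet("TARGET", "na",
                 tuple(rng.choice(baseline.gene_ids, 50, replace=False)))
rest = random_collection(baseline.gene_ids, 49, (10, 100), rng=rng)
collection = GeneSetCollection([target] + rest.sets)

runners = [
    MethodRunner("gsea_bh", GSEA, {"permutation": "gene", "B": 1999}),
    MethodRunner("sigpathway", SigPathway, {"B": 1999}),
    MethodRunner("camera", Camera, {}),
]
study = PowerStudy(baseline, collection, "TARGET", runners,
                   pis=[1.0], taus=[0.25, 1.0, 2.0], n_replicates=50)
results = study.fit(seed=31)
print(results.summary())
```

prints

```
Power grid for target 'TARGET' (50 bootstrap replicates, alpha=0.05):
tau             0.25  1.00  2.00
method     pi                   
camera     1.0 0.040 1.000 1.000
gsea_bh    1.0 0.080 1.000 1.000
sigpathway 1.0 0.140 1.000 1.000
```

Each entry is the fraction of 50 bootstrap replicates in which the injected
50-gene target set reached BH q < 0.05.  At τ = 1 and 2 (one to two SDs of
shift in every target gene) all three methods always find the set; at
τ = 0.25 power collapses, with the correlation-adjusted test the most
conservative — the signal is simply small relative to 20-vs-20 sampling
noise once multiplicity is paid for.

A single fit looks like an ordinary model result:

```python
from gsabench import inject_signal, preprocess
ds = preprocess(baseline)
injected, altered = inject_signal(ds, target, pi=0.5, tau=1.0, rng=7)
print(Camera(injected, collection).fit().summary(top=5))
```

```
Camera results: 50 gene sets on 1000 genes x 40 samples
   set  size    rho_bar    vif  statistic   p_value  q_value
TARGET    50   0.005104   1.25      4.006 6.185e-05 0.003092
SET013    51 -0.0005821 0.9709      2.277    0.0228   0.5107
SET031    92  -0.005034 0.5419      2.106   0.03518   0.5107
SET004    71  -0.001963 0.8626      1.885   0.05937   0.5107
SET016    80  -0.002003 0.8418      1.776   0.07569   0.5107
```

Only the target survives FDR correction; `rho_bar`/`vif` show the estimated
inter-gene correlation adjustment per set.

A thin CLI wraps the same models for shell use
(`gsabench simulate|gsea|safe|sigpathway|camera|benchmark|nullsuite`);
it ingests TSV/GCT matrices, CLS labels and GMT/GMX gene sets.  Note that
probe-level background correction (RMA) is out of scope — inputs are
already-summarized matrices.

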