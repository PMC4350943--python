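# Methods

## Problem setting

Compound potency data sets pair a binary molecular fingerprint (a set of
on-bit indices over a fixed universe) with a pKi value, the negative decadic
logarithm of the equilibrium inhibition constant in molar units. Structural
similarity between two compounds is their Tanimoto coefficient
`Tc = |u∩v| / |u∪v|`; pairs above a scheme-dependent threshold *t* count as
structural analogs. On binary vectors the Tanimoto *kernel*
`K(u,v) = ⟨u,v⟩ / (⟨u,u⟩ + ⟨v,v⟩ − ⟨u,v⟩)` is identical to the coefficient,
so the package computes it once (`similarity`) and uses it both for SAR
scoring and as the SVR kernel. Matrices are dense; the intended data scale
(hundreds to a few thousand compounds) keeps O(n²) memory trivial, and the
vectorized matrix is forced exactly symmetric with an exactly unit diagonal
so downstream consumers can rely on those properties bitwise.

## K_i curation

Raw data sets may carry several K_i measurements per compound. Curation
keeps only measurements below a cutoff (default 100 µM), then combines a
compound's surviving values if they agree within one order of magnitude
(max/min ≤ 10) and discards the compound otherwise. Averaging happens on
the pKi scale — the geometric mean of K_i — which is the standard convention
for log-normally distributed potencies and keeps all downstream arithmetic
on one scale; arithmetic K_i averaging is available as an option. Data sets
additionally enforce a configurable potency floor (default pKi ≥ 5.0, i.e.
K_i ≤ 10 µM): curated potency collections in this field are typically
reported with that floor even when the stated assay cutoff is weaker, and
the floor is a parameter precisely because the two conventions coexist.

## SAR continuity and discontinuity

For potencies `pot(i)` and similarities `Tc(i,j)` over pairs i > j:

* `cont_raw = 1 − Σ w_ij Tc(i,j) / Σ w_ij` with
  `w_ij = pot(i)pot(j) / (1 + |pot(i) − pot(j)|)`. The weight is large for
  pairs of potent compounds with similar potency, so the score reads as one
  minus a potency-weighted mean similarity: high values mean potency varies
  smoothly regardless of structural diversity. Since Tc ∈ [0,1], cont_raw
  ∈ [0,1].
* `disc_raw` = mean of `|pot(i) − pot(j)| · Tc(i,j)` over qualifying pairs
  (Tc ≥ t). It is in pKi units and unbounded above; activity cliffs (similar
  pairs with multi-log potency gaps) dominate it.

A data set with *no* qualifying pair has no defined discontinuity; the
package raises an explicit `UndefinedScoreError` rather than returning 0,
because a silent zero would be indistinguishable from the genuine score
collapse the analysis is designed to detect.

Raw scores are standardized against a reference panel of independent data
sets (sample mean and n−1 standard deviation — the panel is a sample of
data sets, not a population) and mapped to [0,1] with the standard normal
CDF. Thresholds default to 0.85 (MACCS-like) and 0.56 (ECFP4-like/synthetic)
and ride on the data set's fingerprint scheme, overridable per call.

## ε-SVR and the regularization sweep

The regression is standard ε-insensitive SVR: minimize
`½‖w‖² + C Σ(ξᵢ + ξᵢ*)` subject to the ε-tube constraints, predicting via
the kernel expansion `f(x) = Σ(αᵢ − αᵢ*) K(xᵢ, x) + b`. ε is fixed at 0.1
pKi and never tuned: smaller tolerances are below experimental detection
limits, and tolerating larger deviations would excuse biologically
meaningful errors. The quadratic program is delegated to scikit-learn's
libsvm backend with a *precomputed* kernel matrix (solver tolerance 1e-6,
iteration cap 200 000, non-convergence raised as an error carrying C);
kernel construction and prediction are implemented in the package, and
every reported prediction is reproduced from the stored dual coefficients,
support indices and intercept alone.

The sweep protocol fits, for each C in an ordered grid (default {1…50, 100,
250, 500, 1000}), one model per random 50/50 train/test split (default 10
trials; train side ⌊n/2⌋). The *same* split partitions are reused for every
C so that per-trial comparisons isolate the regularization effect. Errors
use the objective's own slack sum `Σ max(0, |y − f(x)| − ε)` (not plain L1),
its per-compound mean, and R² = 1 − SS_res/SS_tot; the preferred C minimizes
mean test error, ties breaking toward the smaller C (weaker regularization
is never preferred without evidence). This deliberately selects C on the
test data — a positive bias toward the model — because the point of the
analysis is that the artifact persists even under favorable selection, not
to benchmark SVR.

## Recomputing SAR scores from predictions

After the sweep, each compound's predictions are averaged over the trials
in which it sat in the training sets (fit quality) and, separately, the test
sets (generalization). Compounds absent from a context across all trials
fall back to their observed potency, flagged. SAR scores recomputed from
these means — same structures, same similarity matrix, same threshold —
quantify how much SAR information the model preserves; feeding back the
observed potencies reproduces the observed scores exactly, which the tests
assert bit-for-bit. Per-C discontinuity profiles expose how regularization
shifts the recovered discontinuity in both contexts; summary scores are
computed at the selected best C. Across data sets, observed discontinuity
is correlated with mean test error by the Pearson product-moment
coefficient with a two-tailed p from the t-transform with n − 2 degrees of
freedom. Normalized scores are what users see; internal comparisons and
test assertions use raw scores so they cannot be skewed by panel choice.

## Activity landscapes

The landscape is a metric stress-majorization (SMACOF) MDS embedding of the
dissimilarities 1 − Tc into 2D (seeded random initialization, 4 restarts,
stress tolerance 1e-12, up to 2000 iterations), plus an
inverse-distance-weighted (Shepard, power 2, no cutoff) potency surface on
a regular grid over the embedding's bounding box (default 100×100; the
study pipeline uses 60×60). IDW is parameter-free, exact at compound
locations, linear in the potency vector, and bounded by the observed
potency range. Observed and predicted surfaces share one embedding, so they
are compared cell-wise: peak height loss (difference of surface maxima),
surface range ratio, discontinuity delta, and the count of lost peaks —
8-neighborhood local maxima above mean(observed surface) + 1 pKi with no
predicted local maximum within 2 grid cells (both constants configurable).
On a flat observed surface the range ratio is defined as 1 when the
predicted surface is also flat and +∞ otherwise, so identical inputs always
produce the identity report.

## Synthetic data generator

The generator emulates the features the analysis relies on, and only those:

* **Analog clusters.** Each cluster has `core_bits` (default 40) shared
  on-bits, disjoint across clusters when the universe (default 1024)
  allows; each member adds `private_bits` (default 8) random bits. Within-
  cluster Tc is therefore ≈ 40/56 ≈ 0.71 (above the 0.56 qualifying
  threshold) and between-cluster Tc near 0.
* **Smooth potency.** Cluster base potencies are uniform in [5, 10] pKi;
  members add a linear gradient spanning ±`within_cluster_spread` (default
  0.3 pKi) plus Gaussian noise with that sd. Tying the gradient amplitude
  to the spread makes the continuous limit exact: spread → 0 with no cliffs
  gives discontinuity → 0.
* **Planted cliffs.** `⌈cliff_fraction · n⌉` members of multi-member
  clusters receive +`cliff_magnitude` (default 3 pKi, clamped to the range
  top + 2) — an activity cliff of three orders of magnitude against their
  untouched analogs, the canonical cliff scale. Cliff compounds are chosen
  in a cluster-interleaved seeded order and boosted incrementally, so
  discontinuity is monotone in `cliff_fraction` at fixed seed and
  configurations differing only in cliff fraction share their underlying
  compounds.
* **Reference panel.** 120 sets of ≥ 100 compounds by default (the study
  pipeline's panel), with per-set size, cliff fraction (0–0.15) and spread
  (0.15–0.45) sampled so panel raw scores have genuine spread for
  Z-normalization.

All sampling flows through one numpy Generator in a fixed order, so every
artifact is bit-reproducible from its seed. What the generator does *not*
model: real chemistry (no SMILES, no matched pairs, no correlated bit
patterns within fingerprint families), assay noise structure, or the
long-tailed size and similarity distributions of real screening data.
Passing tests therefore demonstrate that the pipeline's mathematics and the
under-prediction mechanism behave as designed on data with controlled SAR
structure — not that any particular real target family will show effects of
a given magnitude.

## Study scale and determinism

The headline study runs 12 synthetic sets of 150 compounds with cliff
fractions evenly spanning 0–0.2, grid {1…10, 25, 50}, 10 trials, ε = 0.1,
and 60×60 landscape grids — large enough for the artifact's signatures
(test-context discontinuity collapse, discontinuity–error correlation,
conserved continuity, peak loss) to be unambiguous, small enough to run in
minutes on one CPU. The orchestration layer fans a single global seed out
to per-stage seeds by hashing the stage label (SHA-256, reduced below
2³¹), so re-running one stage in isolation reproduces its in-study result;
report bundles contain no timestamps and rerunning a study writes
byte-identical files.

## Known limitations

* The Tanimoto kernel is used as-is; other kernels (RBF on fingerprints,
  count-vector variants) are out of scope, as is the explicit linear-case
  weight vector.
* Best-C selection on the test error is intentional positive bias (above);
  results should not be read as SVR benchmarks.
* Local-peak matching on the surface grid is resolution-dependent; the
  defaults are declared constants, not fitted quantities.
* With very few trials a compound can miss a context entirely; the observed
  -potency fallback then slightly biases predicted scores toward the
  observed ones. At the default 10 trials of 50/50 splits this is rare
  (probability 2⁻¹⁰ per compound per context).
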