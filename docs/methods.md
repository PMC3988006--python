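# Methods notes

## The evidence-factor model

Each gene is assumed to belong to one of two classes, clock (`Cgene`) or
nonclock (`NCgene`). For a feature metric M and an observed value m, the
event "a randomly drawn gene of this class has M ≥ m" has probability
S_class(m), estimated with the empirical survival function of the class
sample: the exemplar clock genes for `Cgene`, every other gene in the
feature table for `NCgene`. Using a tail event instead of a point value
regularises estimation from a very small positive class (an exemplar set
of ~17 genes). The evidence factor EF(m) = S_clock(m′)/S_nonclock(m′) is a
Bayes-factor analogue built on cumulative rather than density estimates;
under conditional independence of the features given class, the joint tail
probability factorises and the combined evidence factor is the product of
per-feature factors. Multiplying by the prior odds of clock membership
yields posterior odds; the prior only rescales reported odds, so the
ranking itself is prior-free.

Numerical conventions, all applied identically in the engine and in the
brute-force test oracles:

* **Tail convention** is closed (≥), one-sided high: every metric is
  constructed so larger = more clock-like.
* **Capping**: m′ = min(m, exemplar maximum). Values beyond the largest
  exemplar value get the same evidence as that maximum, which keeps the
  numerator nonzero and prevents extreme candidates from being judged on
  an empty clock tail.
* **Denominator floor**: if no nonclock value reaches m′, S_nonclock is
  replaced by 1/(n_nonclock + 1), the smallest resolvable nonzero tail.
* **Missing data**: a missing feature contributes EF = 1 exactly. M_Cyc is
  missing only when all three tissue p-values are missing; a present
  subset contributes the product of the present p-values.
* **Boolean features** (ubiquity flag, homology flag) use the standard
  Bayes-factor frequency ratio with Laplace (+1/+2) smoothing of the class
  fractions, so a flag never produces an infinite or zero factor from a
  small exemplar set.
* **Log-space accumulation** of EF products avoids underflow/overflow at
  genome scale; ties in the combined factor break on ascending gene
  identifier so output is deterministic.

Because the construction is rank-based, any strictly increasing transform
of a continuous metric column leaves every EF and the whole ordering
unchanged; the base of the logarithm in M_Cyc (base 10 here, chosen for
readability) is therefore immaterial to the ranking.

### Known property: exemplar self-training bias

Exemplar genes are ranked with ECDFs that contain their own values, so an
exemplar's clock-tail probability is never below 1/n_exemplar at its own
value. Even with no planted signal, exemplars therefore rank better than
uniform (measured mean rank quantile ≈ 0.30 under a pure-noise universe).
This is inherent to ranking the training class with itself and is why all
calibration claims in the test suite are made on held-out genes: under
zero effect sizes the ranks of genes *outside* the training exemplar set
are uniform (KS test), and cross-validation always scores withheld genes
that did not contribute to the ECDFs.

## Feature-metric decisions

* **Cosinor stand-in for rhythm detection.** Per-tissue cycling p-values
  come from an F-test of a fixed-24-h cosine+sine fit against a constant
  model. This is a deliberately simple, exactly calibrated stand-in for
  nonparametric detectors such as JTK_cycle (an external published tool):
  its null distribution is exactly uniform under Gaussian noise, which the
  suite verifies, and downstream stages only consume p-values. Constant
  series give p = 1 (no evidence) rather than an error; p-values are
  floored at 1e-300 so −log products stay finite.
* **Pool selection** in M_Dist uses the L1 norm |Δperiod| + |Δamp| so that
  exactly one siRNA pool represents each gene; per-parameter selection
  was the alternative reading and would mix two pools per gene.
* **Z-scores** use the population SD (denominator n) over genes' selected
  values; at screen scale the ddof choice is negligible but it is fixed
  for reproducibility. A zero-SD parameter contributes 0 with a warning.
* **Nonself interaction counting**: duplicate and reversed edges count
  once; a gene absent from the network scores 0 when the gene universe is
  known (the pipeline passes it) and missing otherwise.
* **Ubiquity cutoff**: all observed counts are swept as thresholds
  (ubiquitous ⇔ count ≥ t) and t maximising Youden's J = sensitivity −
  FPR is chosen — equivalent to the ROC point farthest from the identity
  line; ties break toward the smallest t, and ≥ (not >) defines the flag.

## The synthetic generator

The generator emulates the shape, not the biology, of the five real data
sources: three-tissue time courses (24 samples, 48 h at 2-h spacing;
clock genes are 24-h cosines with uniform random phase per gene and
tissue plus i.i.d. Gaussian noise), a two-pool RNAi screen (clock genes'
period/amplitude log-ratios shifted by a configurable number of noise-SD
units with random sign, since knockdowns may lengthen or shorten period),
a Bernoulli interaction network with an elevated clock–clock edge rate,
class-specific Poisson tissue counts, and class-specific Bernoulli
homology flags. Missingness is i.i.d. Bernoulli per gene and feature,
independent of class, which isolates the EF = 1 missing-data rule from
confounding. Every generator is a pure function of (config, seed) via
per-generator seed streams, so outputs are bit-identical across runs and
independent of call order.

Default study conditions: 1,000 genes with 17 planted clock genes
(matching a realistic exemplar-set size), cosine amplitude 2 at noise SD
1, screen shift 2.5 SD, clock–clock edge probability 0.4 versus 0.01
background, Poisson tissue-count means 20 (clock) versus 3 (nonclock),
homology probabilities 0.5 versus 0.25, and 5% missingness per feature.
These are strong, clearly detectable effects by design: the synthetic
benchmark demonstrates the machinery (recovery well above the permutation
null, near-total top-50 sensitivity), not the marginal detectability of
real clock genes. What passing tests on this generator do **not** show:
robustness to microarray normalisation artefacts, heavy-tailed or
correlated expression noise, realistic network degree distributions, or
class-dependent missingness — none of which the generator models.

An instructive consequence of the pool-selection step: taking the more
extreme of two pools inflates the spread of the selected-value population,
so a clock gene shifted by 3 SD has mean |Z_period| ≈ 2.6–2.7, not 3; the
tests freeze the Monte-Carlo value.

## Cross-validation and FDR

Leave-pair-out CV withholds each of the C(n,2) exemplar pairs, retrains
the class-conditional models (ECDFs, NB fits, Boolean fractions) on the
remaining n−2 exemplars, and ranks the withheld pair among all
non-training genes. The feature columns themselves (including M_int and
the ubiquity cutoff, which reference the exemplar set) are computed once
from the full exemplar list and held fixed across folds; only the
probabilistic models are retrained. Sensitivity aggregates over withheld
gene-instances (two per fold). Under label permutation a withheld gene's
rank is uniform over the candidate pool, so E[sens(k)] = k/n_candidates —
the analytic null used both as a calibration check and as the reference
when testing that planted-effect recovery beats chance (instances are
treated as independent in that binomial tail bound, a mild approximation
since folds share data).

The screening FDR estimator assumes N_true genuine clock components
genome-wide, takes expected true positives at cutoff k as
sens(k)·N_true, and reports clip((k − TP)/k, 0, 1). N_true ∈ {25, 50, 75}
is the standard assumption grid.

## Baseline classifiers

Both naive-Bayes baselines are implemented in-package (an external
implementation is used only as an independent cross-check in the test
suite). The Gaussian variant floors per-class variances at 1e-9 × the
overall feature variance; the kernel variant uses Gaussian kernels with
bandwidth 1.06·min(SD, IQR/1.34)·n^(−1/5) (a documented Silverman-type
heuristic; a single-sample class falls back to the overall feature SD).
Missing values are skipped in fitting and in scoring, mirroring the EF
neutrality rule; class priors are empirical label frequencies. On
Gaussian synthetic data the kernel model closely reproduces the Gaussian
model's ranking (Spearman ρ > 0.95 in the suite); in the infinite-
bandwidth limit its densities flatten and the ranking degenerates to the
tie-break order, so "large bandwidth" is not the right limit in which the
two coincide.

## Problem sizes

The test suite and the acceptance script run the full method at 1,000
genes / 17 exemplars (136 CV folds), with auxiliary Monte-Carlo checks at
up to 20,000 genes for moment/frequency recovery and 10,000 genes for
test calibration; counting-oracle equivalence uses 100 random universes
of up to 200 genes. These sizes give stable statistics for every property
asserted while keeping the default run fast on a laptop.
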