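# Methods

## Model and procedure

`funcforest` grows un-pruned CART-style regression trees on bootstrap
resamples. At every node a fresh subset of `m` features is drawn uniformly
without replacement; every midpoint between consecutive distinct sorted
values of each candidate feature is scored by the reward
C = D(parent) − D(left) − D(right), and the reward-maximising split is taken.
Ties are broken deterministically (lowest feature index, then lowest
threshold); splits whose reward is not strictly positive are rejected, which
also guarantees termination on constant targets. A node with at most
`n_size` samples becomes a leaf. Defaults are T = 150 trees, m = 10,
n_size = 10.

The six node deviances fall into two families.

**Quadratic (SSD) family.** Scalar SSD, region-wise SSD, PCA, basis, and
Mahalanobis costs are all quadratic forms around the node mean, so each
equals the plain per-column SSD of a linearly transformed target matrix
Z = Y·A (identity, leading principal axes, Cholesky factor of the basis Gram
matrix applied to spline coefficients, or covariance whitening). The split
reward then reduces to prefix sums of Z in feature-sorted order,
Σ_c [S_L²/n_L + S_R²/n_R − S_P²/n_P], which the numba-compiled kernel
evaluates in O(n·k) per candidate feature. Design choices in this family:

* The PCA basis and the B-spline coefficients are computed once at the
  forest root from all training responses — the projected coordinates are
  otherwise not comparable across nodes.
* The Mahalanobis covariance is estimated once per tree from that tree's
  bootstrap responses, with ridge ε·I, ε = 10⁻⁶·trace(Σ)/m; per-node
  estimation is ill-posed at small leaves. `covariance="identity"` reduces
  the cost exactly to the region-wise SSD (used by the equivalence tests).
* Default regioning is one region per dose; the cost is invariant to how
  doses are grouped into regions (the SSDs are additive), so regioning
  matters only for the divergence costs, where the mixture is formed per
  region.

**Divergence family.** Each sample contributes a per-dose Gaussian
(replicate mean, SD). Densities are discretised on a fixed support grid Ω —
256 equally spaced points spanning the pooled means ± 4·max SD, fixed at the
forest root so parent and child costs are comparable. The node's reference
distribution is the equal-weight mixture of member densities (the mean of
the discretised mass vectors), and the node cost sums KL(Φᵢ ‖ Φ̂) or the
squared Hellinger distance over members and regions. Both divergences also
reduce to prefix-sum statistics (Σ S ln(S/n) for KL; Σ √(S/n)·R with R the
summed root-masses for Hellinger), so the same exhaustive threshold search
applies; this path is pure numpy since it is only used at small scale.
Numerical safeguards: SDs are floored at half the grid step (a point mass is
not representable on a finite grid) and probabilities at ε = 10⁻¹² before
logs/ratios. The divergence cost is not guaranteed to decrease under
splitting; the search simply maximises the reward and rejects non-positive
ones.

**Prediction.** Tree weights follow the bootstrap-multiplicity/leaf-size
rule; forest weights average over trees and always sum to one. Curve
prediction fits, per dose, a Gaussian to the forest-weighted training
responses and predicts its mode — identical to the weighted mean, which the
tests assert as the dose-wise application of the scalar prediction rule.
The per-dose variance uses the weighted (1/n-style) estimator; the
prediction is insensitive to this choice and the variance is only reported
for uncertainty bands. The FRFL hybrid grows the same trees as the FRF
(identical seeds give identical node structure) but stores a scalar summary
metric per training sample and predicts its weighted mean.

## Curve fitting and summary metrics

All fitting and integration use the log10-dose axis. AUC is the trapezoidal
area between a reference (untreated) level and the curve, clamped at the
reference and normalised by the log-dose width, so values are in response
units and comparable across grids. IC_p is defined on the fitted curve's
range as p percent of *decline from the fitted maximum*
(level_p = max − (p/100)(max − min)), scanning for the first in-span
crossing from low dose; a decreasing curve therefore yields
IC25 < IC50 < IC75 in dose, matching the pharmacological convention, and an
increasing curve still yields crossings (counted from its minimum). Metrics
whose crossing does not occur inside the dose span return a NOT_REACHED
sentinel (NaN); no extrapolation is ever performed. EC50 and Amax come from
a bounded multistart least-squares fit of the four-parameter sigmoid
y(d) = A0 + (Amax − A0)/(1 + (IC50/d)^θ) (asymptotes within 1.5× the data
range, θ ∈ (0, 10], IC50 within a decade of the dose span, starts at
θ ∈ {0.5, 2, 8}); when it converges it also supplies the IC50 crossing,
otherwise an interpolating-spline crossing is used. B-spline fits use a
clamped knot vector whose interior knots follow the data quantiles; with as
many basis functions as dose points the fit interpolates.

Curve ranking for function-to-function features: slope ranking uses the
least-squares slope against log10-dose (rank 1 = steepest decline);
dominance ranking counts pairwise wins (strictly more than half the dose
points higher), ranks by the number of curves that beat each curve, and
breaks ties by mean value then input order. Both are deterministic.

## Synthetic benchmark

The generator emulates a clustered pharmacogenomic screen: 5 clusters × 15
samples; 10 relevant features per sample drawn from N(k·Δ, (Δ/4)²) for
cluster k (adjacent means 4 SDs apart, ~5% overlapping mass), 10 standard
Gaussian noise features, columns shuffled with a recorded mask. Targets are
four-parameter sigmoids on 101 log-spaced doses over 0.0025–8 µM with
A0 = 1, Amax = 0, θ = 2; cluster IC50 centres are log-spaced over
0.01–4 µM and each sample's IC50 jitters by ±10% uniformly within its
cluster. Additive Gaussian noise has SD = noise_level × (global noiseless
response range), so "5% noise" has a fixed meaning. These constants are the
package's calibration of a qualitative recipe (decreasing viability curves
whose IC50s sit inside the measured dose range, clusters that are separable
but not trivially so); they are configurable but the defaults are the study
conditions used by the tests and the evaluation driver.

What the generator does *not* emulate: genome-scale feature dimensionality
(tens of thousands of correlated features), dose-dependent or heteroscedastic
measurement noise, curve shapes beyond the sigmoid family, and missing
values. Passing tests therefore demonstrate correctness of the machinery and
the qualitative functional-vs-scalar comparison, not performance on real
screens.

A second, smaller generator produces function-to-function inputs:
per-sample dose-expression curves for 21 proteins over 7 doses with mixed
trends (a third decreasing, a third exactly flat at the vehicle-control
level, a third increasing), plus viability curves whose IC50 is tied to the
same latent sensitivity that shifts the decreasing proteins — so AUC/IC_p
features extracted from those curves are predictive by construction.

## Evaluation

NMAE = pooled mean absolute error divided by the range of the reference
responses. On the synthetic benchmark, models are trained on the noisy
targets but scored against the generator's noiseless curves: the quantity of
interest is recovery of the true dose-response profile, and scoring against
the noisy draws would bound every model's error from below by the noise's
mean absolute deviation regardless of model quality, washing out the
functional-vs-scalar comparison at higher noise. `cross_validate` itself
keeps the generic contract (scores against the targets it is given) and
takes the noiseless reference through an explicit argument.

The benchmark driver runs the per-dose RF baseline (one scalar forest per
dose — the conventional way to emulate curve prediction with univariate
forests) against the FRF across noise levels, tree counts and fold counts,
and reports per-noise mean NMAEs plus the relative improvement
100·(NMAE_RF − NMAE_FRF)/NMAE_RF averaged over settings. The bootstrap
comparison fits both models on each with-replacement resample (shared
per-replicate seed) and evaluates MAE on the out-of-resample samples;
identical configurations therefore produce exactly zero differences, a
property the tests use.

## Known limitations

* Axis-aligned splits at the default ~5% per-feature cluster overlap leak a
  few percent of forest weight across cluster boundaries: with 10
  independent relevant features, roughly a third of samples have at least
  one feature beyond the midpoint toward a neighbouring cluster, so
  noiseless jitter-free CV error plateaus near NMAE ≈ 0.013 rather than
  reaching zero, and per-sample IC50 recovery from predicted curves is
  near-perfect for most but not all samples. This is a property of
  single-feature threshold routing, not of the cost functions.
* The divergence-cost grower is O(n²·|Ω|·q) per node and intended for
  screen-sized data (tens to hundreds of samples), not genome-scale use.
* Missing feature values are rejected, not imputed; there are no surrogate
  splits and no pruning.
* Out-of-bag error machinery is not built; evaluation is by k-fold CV and
  bootstrap out-of-resample sets.
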