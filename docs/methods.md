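# Methods

This note records the models, conventions and design choices behind the
package, in the order data flows through it.

## PLS1 core

`fit_pls1` implements single-response partial least squares by the
classical NIPALS/deflation scheme. Conventions:

- **Centering.** X and y are mean-centered before decomposition and the
  means are restored at prediction; the coefficient vector β therefore
  lives on the centered scale and `pls_predict` computes
  `(X − x̄)β + ȳ`. Wavelength channels are *not* autoscaled — NIR
  absorbance channels share units and comparable variance, and scaling
  would change which spectral regions dominate the weights.
- **Weights.** Each weight vector is `X'y/‖X'y‖` of the current deflated
  X — equivalently the dominant eigenvector of `X'yy'X`. The sign is fixed
  so the largest-magnitude element is positive: signs are arbitrary in
  exact arithmetic (they cancel between the two instruments, which share
  the master's W), but fixing them makes serialized models reproducible.
- **Deflation.** X is deflated per component (`X ← X − t p'`); y is not
  deflated (PLS1 convention); `q_a = t'y/t't`. Successive training scores
  are mutually orthogonal by construction and β = W(P'W)⁻¹q'.
- **Early termination.** If the deflated covariance `X'y` underflows below
  1e-12 of its initial norm, the fit is already exact and the component
  count is truncated there rather than extracting noise directions. This
  matters for the PDS sub-regressions, where the target channel lies
  inside the regressor window and the fit becomes exact after a few
  components.
- **Latent-variable selection.** `select_lv` searches A ∈ [1, 15] by
  default with 10-fold cross-validation: a seeded shuffle, contiguous
  fold blocks, pooled held-out squared errors, and ties broken toward the
  smaller A (parsimony). Held-out predictions for all truncation levels
  are computed from one maximal fit per fold, which is exact for PLS1
  because P'W is unit upper triangular, so the first a columns of
  W(P'W)⁻¹ depend only on the first a components.

## Transfer by affine invariance

The fitting stage computes, per latent variable, the OLS line between the
min–max-normalized score column and the min–max-normalized prediction
vector, separately on the master calibration spectra (true scores and
predictions) and on the slave calibration spectra (pseudo-scores and
pseudo-predictions through the *master* model). The angle of each line is
`θ = arctan(slope)` ∈ (−π/2, π/2), so Δθ ∈ (−π, π) with no wrapping. The
correction rotates each test sample's normalized (score, prediction) point
by Δθᵢ after removing the slave intercept and restores the master
intercept:

    y′ = t_n sin Δθᵢ + (y_n − b̃ᵢˢ) cos Δθᵢ + bᵢᵐ.

Choices that the formulation leaves genuinely open, and what we do:

- **Scaling factors.** The printed form of the rotation mixes raw and
  normalized units in its scaling factors; no constant matrix realizes it
  literally. We perform the rotation entirely in normalized coordinates
  and treat the scaling as the denormalization step. A switch
  `denorm_reference ∈ {master, slave}` selects whose calibration
  prediction bounds map y′ back to property units. The default is
  `master`: it is the only reading under which (a) the identity case
  (slave ≡ master) reproduces the master model exactly and (b) a pure
  prediction offset between the instruments is corrected exactly — both
  are pinned by tests.
- **Test-set normalization.** Test scores and predictions are normalized
  with the *calibration* bounds of the slave instrument, not with
  test-set statistics. This makes single-sample prediction well-defined
  and keeps the correction a fixed function once fitted. Test points may
  therefore fall slightly outside [0, 1]; the affine map extends to them
  naturally.
- **Aggregation.** The final prediction is the arithmetic mean of the A
  per-component corrected predictions (exposed as the `per_component`
  matrix for diagnosis).
- **Degeneracies.** Normalization ranges below 1e-12 raise an error naming
  the component; components with |cos Δθ| < 1e-9 trigger a runtime
  warning (near-vertical rotation) but no special-casing of the formula.

`slave_coefficients` provides the equivalent-coefficient diagnostic view:
the corrected predictions are projected back onto the (batch-centered)
slave spectra by least squares, minimum-norm when the batch is
rank-deficient (flagged). Because the correction is nonlinear in X
(normalization bounds enter), the projection residual is reported rather
than hidden.

## Baselines

- **SBC** fits one OLS line from slave-instrument predictions of the
  standards to the master's predictions of the same samples.
- **MSC** regresses each spectrum on the mean master calibration spectrum
  and removes the fitted additive and multiplicative terms; it is
  idempotent, which is the self-transfer identity exercised in tests.
- **PDS** regresses every master channel on the slave window centered at
  that channel with a PLS1 sub-model, assembling a banded transfer matrix
  (entries outside the band are exactly zero) plus per-channel
  intercepts. Edge windows are truncated symmetrically, so the output
  keeps all p channels. `inner_lv` is capped by window width and standard
  count.
- **Hyperparameter searches.** The PDS window grid is the odd values
  {3, 5, …, 15} (centered windows must be odd), chosen by 5-fold CV on
  the standards: the held-out standards are mapped to master space and
  predicted with the master model against their reference values. The SBC
  standard count is searched over [5, 30] by the smallest RMSE of the
  corrected standards against their reference values — the only error
  computable without a test set. Standards are always the first k samples
  in Kennard–Stone selection order.

## Kennard–Stone splitting

Seeded with the maximally distant sample pair (Euclidean distance on raw
absorbance), then greedily adding the sample with the largest minimum
distance to the selected set. Ties break toward the lowest index, making
the split bitwise reproducible; selection order is preserved so "first k
standards" is well-defined.

## Evaluation statistics

RMSE is the plain root-mean-square error; bias is the mean signed error;
SE is the bias-corrected standard error of prediction
`sqrt(Σ(eᵢ−ē)²/(n−1))`, which satisfies
`rmse² = bias² + se²(n−1)/n` (property-tested). The improvement rate is
`h = (1 − RMSEP/RMSEP_other)·100%`. The Pearson test uses the t
transformation with n−2 degrees of freedom; the one-sample t-test reports
the two-sided critical value at α (2.131 at df 15, 2.01 at df 49). The
Wilcoxon signed-rank test drops zero differences, uses W⁺ (rank sum of
positive differences) and is two-sided; the exact mode builds the
tie-free null by the generating-polynomial recursion (identical to full
2ⁿ enumeration, verified against it), the normal mode uses tie-corrected
variance without continuity correction, and `auto` picks exact for n ≤ 25
without ties. In `evaluate_transfer`, the Wilcoxon test pairs the
*absolute residuals* of the reference method with each competitor's — a
deliberate interpretation, since "significant difference between methods"
does not by itself fix the paired quantity.

## Synthetic scenarios

The generator emulates two spectrometers measuring the same chemical
system. Master physics is a Beer–Lambert linear mixture: k pure-component
spectra, each a sum of Gaussian absorption bands (seeded centers, widths
5–20% of the wavelength span, band amplitudes 0.005–0.02 AU per unit
concentration), concentrations drawn uniformly from a shared range
(default 5–15, arbitrary property units), a quadratic baseline and iid
noise. The slave instrument applies a smooth multiplicative gain curve
(±10% by default), a smooth additive offset (±0.05 AU), optional
fractional wavelength shift by linear interpolation, per-sample scatter
(sd 1%) and higher noise (2e-3 vs 1e-3 AU). Both slave datasets share one
pair of gain/offset curves — they are one instrument — with independent
noise; `measure_on_slave` re-measures arbitrary samples on that same
virtual instrument, which is how paired transfer standards are created
for the baselines. All randomness flows through `numpy`'s PCG64
generator, so scenarios are bit-reproducible per seed across platforms.

Defaults (60 calibration, 20 test samples, 200 channels, 3 components)
were fixed once as a realistic mid-size NIR experiment and define the
standard conditions used by the tests and the acceptance script.

What the generator does *not* emulate: nonlinear detector response,
wavelength-dependent noise, stray light, temperature drift, or real
instrument line-shape differences. Passing tests on these scenarios show
the algorithms are implemented correctly and behave as designed under the
affine-difference model they target; they do not certify performance on
any particular real instrument pair.

Known property: when a seed happens to draw distortion curves that barely
perturb the master model's predictions, there is little to correct and
the estimated correction can add variance — the corrected error then
roughly matches, and occasionally exceeds, the uncorrected one. Across
seed blocks the correction wins in roughly 85–95% of replicates and cuts
the median test RMSEP by about a factor of 3.

## Problem sizes

Unit and property tests run on 8–100-sample, 3–200-channel problems; the
transfer-efficacy checks and the acceptance script use the default
60/20-sample, 200-channel scenario with 20 replicate seeds and
cross-validated latent-variable selection, which completes in seconds.

## Limitations

- The method corrects *predictions*, not spectra; it cannot repair
  distortions that move slave spectra outside the span where the master
  model's pseudo-scores remain informative (e.g. large wavelength
  shifts).
- Min–max normalization bounds come from calibration extremes and are
  sensitive to outliers; robust quantile bounds are not implemented.
- The wheat-style multi-instrument layout is supported through generic
  loader keys; no instrument-specific file formats (JCAMP-DX, SPC) are
  parsed, and spectra on different wavelength grids are not resampled.
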