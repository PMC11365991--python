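# Methods

## Model and procedure

A measured FTIR absorbance trace is a pair (wavenumber grid, intensities).
All spectra are piecewise-linearly resampled onto one uniform grid (default
650–3999.5 cm⁻¹ at 0.5 cm⁻¹, N = 6700; a reduced 650–1650 cm⁻¹, 2 cm⁻¹ grid
with 501 points serves simulations and tests) and min-max normalized to
[0, 1]. Resampling refuses to extrapolate — grid points outside a spectrum's
support are an error, since zero-filling would fabricate signal — and
normalization rejects constant spectra, on which the downstream gradient
correlation is undefined.

A contaminated measurement of polymer class *b* is modeled as
s⁽ᵇ⁾ = y⁽ᵇ⁾ + β·z with the membrane amplitude β related to the commanded
signal-to-noise ratio by SNR = −20·log₁₀β; the mixture is re-normalized
after summation. The learning matrix X stacks J normalized membrane spectra
and then L normalized clean spectra per class, classes in sorted-name order.
Dictionary learning alternates:

1. **Sparse coding.** Each column is coded by orthogonal matching pursuit
   over the unit-norm atoms, stopping at the per-spectrum non-zero budget,
   or when the residual drops below 10⁻⁶ of the signal norm, or when the
   best remaining atom would explain less than `gain_tol²` of the residual
   energy (|⟨d, r⟩| ≤ gain_tol·‖r‖, default gain_tol = 0.1, i.e. 1% of the
   remaining energy). The last rule is scale-free; without it the greedy
   pursuit pads supports with unrelated atoms at correlations near machine
   precision, which destroys the interpretability of "which atoms does this
   spectrum use". A Lasso coder (via scikit-learn, α = λ/N to match the
   ½‖·‖² + λ‖·‖₁ convention) is available for the literal L1 formulation.
2. **Atom update.** Each used atom is refreshed by a rank-one SVD of its
   restricted residual (K-SVD style), with a deterministic sign convention
   (the atom's largest-magnitude element is positive); unused atoms are
   re-seeded from the worst-reconstructed training column.

The dictionary is initialized from K seeded distinct columns of X and is
undercomplete by construction (K < N is enforced; K ≤ M is required so the
initializer is well-posed). An iterate is accepted only if the data-fit term
½‖X − DC‖² does not increase; the first non-improving iterate stops the loop
with the previous model kept, and convergence is declared when the relative
fit change falls below 10⁻⁶. The penalized objective ½‖X − DC‖² + λ‖C‖₁ is
evaluated and stored for every accepted iterate alongside the fit. Descent
is monitored on the fit rather than the penalized objective because the
budgeted greedy coder optimizes the fit: in practice the λ‖C‖₁ term drifts
while the fit decreases, so gating on the penalized objective would stop the
optimization before the atoms specialize. Both trajectories are reported in
the model so the trade-off stays visible.

**Membrane atom membership.** Atoms carrying a *significant* coefficient on
any membrane training column form the index set I; significance means
exceeding 5% of the largest coefficient magnitude in the membrane block (and
always the numeric zero threshold 10⁻¹⁰, which is all that matters on the
Lasso path). The same rule defines each class's atom support. The relative
threshold replaces a strict any-non-zero rule after measurement showed the
learned coefficient blocks to be strongly bimodal: structural contributions
sit within a factor ~1.06 of the block maximum while greedy polish terms sit
two orders below, with nothing in between, so any fraction inside that gap
selects the same set — but the strict rule lets a single polish coefficient
on one of J columns flip an informative polymer atom into I, after which
removal deletes genuine polymer signal. An explicit `tol` argument restores
the strict behaviour where wanted.

**Removal and identification.** A new spectrum is coded by the same coder,
coefficients at I are set exactly to zero, and ŝ = D·ŵ is reconstructed —
by construction ŝ lies in the span of the non-membrane atoms. The
reconstruction is re-normalized before comparison (gradient correlation is
affine-invariant, so this is cosmetic for classification but keeps plotted
reconstructions on the reference scale); a degenerate all-constant
reconstruction is returned as-is. Identification computes the Pearson
correlation between first-difference gradients of the query and every
labeled reference, keeps each class's best ρ, and predicts the argmax class,
breaking exact ties toward the lexicographically smallest name. ρ is a
Pearson correlation and may be negative; it is never clamped — a negative
match simply loses the argmax. The baseline applies the same classifier to
the raw spectrum.

## Synthetic data

The generator emulates three things about bench data: per-class clean
spectra as sums of Gaussian or Lorentzian bands with replicate-to-replicate
jitter (1-sigma relative perturbations of band center/width/height, defaults
0.2% / 5% / 10%), membrane spectra from their own band model, and noisy
mixtures at commanded SNR via pair mixing — each synthetic clean spectrum is
a uniformly weighted sum of two distinct same-class seeds, re-normalized,
and likewise for membrane spectra. Seed selection runs over content-sorted
seed lists, so outputs depend only on the seed value, not file order.
Train/evaluation splits are per-class random halves (odd counts favor the
first half).

The *separable five-class toy* places 10 cm⁻¹-wide Gaussian bands on slots
50 cm⁻¹ apart in 690–1590 cm⁻¹: three strong membrane bands on slots of
their own, three bands per polymer class on disjoint slots, plus one weak
membrane *satellite* band 22 cm⁻¹ beside each class's main band (heights
0.35·0.8ᵇ). The satellites encode the spectral-coincidence mechanism by
which a real cellulose filter defeats naive matching: a membrane exactly
orthogonal to every reference could never change the baseline's class
ranking, because Pearson gradient correlation is scale-invariant in each
argument and the ranking over classes would be independent of β. With the
satellites, the baseline degrades from perfect accuracy toward chance as the
filter grows dominant, while the membrane atoms absorb satellite structure
and coefficient zeroing removes it. Membrane jitter is set lower than the
class default (0.1% / 3% / 4%) — a manufactured filter is far more
reproducible than cryogenically ground polymer particles — which also keeps
the membrane subspace well covered by few training spectra.

What the toy does *not* emulate: detector noise, atmospheric CO₂/H₂O lines,
ATR penetration-depth effects, baseline drift, and the dense many-band
structure of real polymers. Passing results on it demonstrate the
correctness and the qualitative robustness mechanism of the pipeline — exact
removal semantics, atom-support separation, baseline collapse versus
dictionary stability — not instrument-grade accuracy figures for measured
spectra, which depend on data available only from the original laboratory.

## Evaluation protocol

The SNR sweep synthesizes `n_per_class` mixtures per class per level from
held-out seeds (training and evaluation seeds never mix), classifies each by
both methods against references synthesized from the same held-out pool
(default 10 per class), and reports per-(method, level) accuracy and two
reconstruction-quality summaries: `rho_truth`, the mean gradient correlation
against each mixture's paired clean truth, and `rho_bestref`, the mean of
the winning per-spectrum correlation over the reference library. Both are
reported because "mean of maximum gradient correlations" is ambiguous
between the two readings; they move together. Per-spectrum records are kept
in the report so every aggregate can be recomputed. Confusion matrices use
scikit-learn with an explicit class order. The default study conditions are
J = 100, L = 10, K = 50, λ = 1.0, budget 10, 50 iterations, levels
0/−10/−20/−30 dB with 100 mixtures per class per level; the packaged tests
and the acceptance script run the same protocol on the reduced grid with
J = 20, K = 30 and 12 replicates per class, which one CPU completes in
seconds without changing any qualitative behaviour.

## Numerical choices and edge cases

- Coefficient zero threshold 10⁻¹⁰ (OMP emits exact zeros off-support; the
  threshold guards the Lasso path). Membership significance fraction 5%, as
  above. Removal writes exact zeros, never "small" values.
- OMP refits by `numpy.linalg.lstsq`; an independent cross-check against
  scikit-learn's `orthogonal_mp` and against exhaustive least squares over
  all supports (at mutual coherence < 1/3, where greedy selection is exact
  for 2-sparse signals) is part of the test suite.
- Ties in the classification argmax break toward the smaller class name;
  ties in atom-profile ordering break toward the smaller atom index.
- One global seed fans out to per-stage seeds by fixed offsets, so a config
  reruns byte-identically (`report.json` embeds the config and contains no
  timestamps) and stages can be reproduced in isolation.
- Atom indices are 0-based in the API; printed artifacts (profiles, heatmap
  rows) use 1-based labels to match figure conventions.
- Known limitations: a single designated interferent class (swap in another
  filter's spectra, but no multi-interferent modeling); no overcomplete or
  online dictionary variants; no instrument-native file formats (delimited
  text only); plotting is a thin optional layer over emitted data.
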