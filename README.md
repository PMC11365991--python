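# specsieve

Membrane-filter interference removal and polymer identification for FTIR
spectra of microplastics, via sparse dictionary learning.

## The problem

Microplastic particles collected from water are concentrated on a cellulose
membrane filter and measured by ATR-FTIR directly on the filter. The filter
has strong infrared bands of its own, and for micrometer-scale particles the
measured absorbance spectrum **s** is dominated by the filter rather than the
polymer. Identification then fails exactly where it matters most — and
black-box denoisers offer no way for a chemist to check *what* was removed.

`specsieve` implements an explainable alternative. Let **z** be a membrane
filter spectrum and **y**⁽ᵇ⁾ a clean spectrum of polymer class *b*, all
min-max normalized on a common wavenumber grid. A contaminated measurement is
modeled as

    s⁽ᵇ⁾ = y⁽ᵇ⁾ + β·z,      SNR(dB) = −20·log₁₀ β.

From J membrane spectra and L clean spectra per class (stacked as the N×M
learning matrix **X**) an undercomplete dictionary **D** (N×K, K < N) and
sparse coefficients **C** are learned by alternating orthogonal matching
pursuit (OMP) with K-SVD-style atom updates, targeting

    min½‖X − DC‖² + λ‖C‖₁.

Atoms carrying significant coefficients on any membrane column form the
membrane index set **I**. A new spectrum is cleaned by sparse-coding it
(w\* = argmin ½‖s − Dw‖² + λ‖w‖₁ via the same coder), zeroing ŵₖ = 0 for
k ∈ I, and reconstructing ŝ = D·ŵ. Identification assigns

    b̂ = argmax_b ρ⁽ᵇ⁾,

where ρ⁽ᵇ⁾ is the Pearson correlation between the first-difference
*spectral gradients* of ŝ and each labeled reference spectrum — a
shape-sensitive, offset- and scale-invariant similarity. Classifying the raw
spectrum the same way, without removal, is the no-preprocessing baseline.

Because every reconstruction is a short sum of atom profiles wₖ·dₖ, the
decomposition itself is the explanation: one can see which atoms carried the
filter, which carried the polymer, and what removal changed.

## Worked example

No measured spectra are required: the `synthesis` module simulates seed
libraries from parametric band models, including a separable five-polymer
toy whose membrane model carries weak satellite bands beside the polymer
bands — the spectral-coincidence mechanism that defeats naive matching on
real filters. Running `examples/02_learn_dictionary.py` and
`examples/04_snr_sweep.py`:

```text
learning matrix: N=501 points, M=70 columns (J=20 membrane + 5 classes x L=10)
K=30 atoms; data-fit 1.114 -> 0.454 over 14 accepted iterations
membrane atom index set I (1-based): [7, 8, 13, 18, 29]
  polymer_A    uses atoms [2, 16, 24, 28]
  ...
membrane/class atom overlap: none

accuracy
     SNR  baseline  dictionary
     0dB     1.000       1.000
   -10dB     1.000       1.000
   -20dB     0.800       1.000
   -30dB     0.313       1.000

mean gradient correlation vs clean truth
     SNR  baseline  dictionary
     0dB     0.633       0.983
   -30dB    -0.064       0.913
```

At −30 dB the membrane enters ~31.6× stronger than the polymer: raw-spectrum
matching collapses toward chance while the dictionary method keeps both its
accuracy and the fidelity of its reconstructions, and the membrane atoms stay
disjoint from every polymer's atom support. `examples/03_denoise_and_classify.py`
and `examples/05_atom_profiles.py` walk one spectrum through removal and its
atom-profile explanation.

## Library, examples, CLI

The importable API is the main interface (`import specsieve as sv`); each
capability has a short narrative script under `examples/`. A thin `specsieve`
command wraps the same functions for shell use:

```bash
specsieve simulate --replicates 12 --seed 0 --out seeds.csv
specsieve learn --clean clean.csv --membrane mf.csv -J 20 -L 10 -K 30 --seed 4 --out model.npz
specsieve denoise --model model.npz --in noisy.csv --out clean_est.csv
specsieve classify --model model.npz --refs refs.csv --in noisy.csv --out predictions.csv
specsieve evaluate --model model.npz --seeds heldout.csv --snr 0,-10,-20,-30 -n 100 --seed 7 --out report.json
specsieve explain --model model.npz --in spectrum.csv --out profiles.csv
specsieve run --config config.yaml --out-dir out/
```

Configuration defaults reproduce the reference study conditions: grid
650–3999.5 cm⁻¹ at step 0.5 (N = 6700), J = 100, L = 10, K = 50, λ = 1.0,
SNR levels 0/−10/−20/−30 dB, 100 test mixtures per class per level.

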