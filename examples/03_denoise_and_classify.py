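"""Remove the membrane contribution from a contaminated spectrum and
identify the polymer.

Synthesizes a noisy mixture s = y + beta*z at -20 dB SNR (the membrane 10x
stronger than the polymer), denoises it by coefficient zeroing, and
classifies both the raw and the reconstructed spectrum by maximum
spectral-gradient correlation.
"""

import specsieve as sv

seeds = sv.simulate_seed_library(
    sv.toy_band_library(), replicates_per_class=12, rng_seed=0,
    grid=sv.reduced_grid(),
)
train, heldout = sv.split_halves(seeds, rng_seed=1)
clean = sv.synthesize_clean_set(train, n_per_class=10, rng_seed=2)
membrane = sv.synthesize_membrane_set(train, n=20, rng_seed=3)
model = sv.learn_dictionary(
    sv.build_learning_matrix(membrane, clean, J=20, L=10), K=30, rng_seed=4
)
references = sv.synthesize_clean_set(heldout, n_per_class=10, rng_seed=5)

mix = sv.synthesize_dataset(heldout, n_per_class=1, snr_db=-20.0, rng_seed=6)[0]
print(f"mixture: true class {mix.label}, beta={mix.beta:.1f} "
      f"(membrane {mix.beta:.0f}x the polymer amplitude)")

estimate, pre, post = sv.denoise(mix.noisy, model)
print(f"code support before removal: {sorted(int(k) + 1 for k in pre.support)}")
print(f"code support after removal : {sorted(int(k) + 1 for k in post.support)}")

raw = sv.classify_baseline(mix.noisy, references)
cleaned = sv.classify(estimate, references)
rho_raw = sv.gradient_correlation(mix.noisy, mix.clean_truth)
rho_est = sv.gradient_correlation(estimate, mix.clean_truth)
print(f"baseline on raw spectrum : predicted {raw.predicted!r} "
      f"(rho vs truth {rho_raw:.3f})")
print(f"after membrane removal   : predicted {cleaned.predicted!r} "
      f"(rho vs truth {rho_est:.3f})")
print("the reconstruction tracks the clean polymer spectrum even though the "
      "raw measurement is dominated by the filter")
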