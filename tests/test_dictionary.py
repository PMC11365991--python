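import itertools

import numpy as np
import pytest

import specsieve as sv
from specsieve.dictionary import (
    COEFF_TOL,
    DictionaryError,
    SparseCode,
    membrane_atom_indices,
    omp,
)
from specsieve.synthesis import MEMBRANE_LABEL


def _random_set(rng, n_points, labels):
    grid = np.linspace(650.0, 650.0 + 2.0 * (n_points - 1), n_points)
    spectra = []
    for lab in labels:
        v = rng.random(n_points)
        v = (v - v.min()) / (v.max() - v.min())
        spectra.append(sv.Spectrum(grid, v, lab))
    return sv.SpectrumSet(spectra)


def exhaustive_best_residual(D, s, budget):
    """Least-squares over every support of size ≤ budget (oracle for OMP)."""
    best = float(np.linalg.norm(s))
    K = D.shape[1]
    for size in range(1, budget + 1):
        for supp in itertools.combinations(range(K), size):
            coef, *_ = np.linalg.lstsq(D[:, supp], s, rcond=None)
            best = min(best, float(np.linalg.norm(s - D[:, supp] @ coef)))
    return best


def incoherent_dictionary(rng, n, k, max_coherence):
    while True:
        D = rng.standard_normal((n, k))
        D /= np.linalg.norm(D, axis=0)
        G = np.abs(D.T @ D - np.eye(k))
        if G.max() < max_coherence:
            return D


class TestBuildLearningMatrix:
    def test_small_counting_case(self):
        rng = np.random.default_rng(0)
        membrane = _random_set(rng, 12, [MEMBRANE_LABEL] * 2)
        clean = _random_set(rng, 12, ["b", "a", "c"])
        lm = sv.build_learning_matrix(membrane, clean, J=2, L=1)
        assert lm.M == 5 and lm.B == 3
        assert lm.column_labels[:2] == (MEMBRANE_LABEL, MEMBRANE_LABEL)
        assert lm.column_labels[2:] == ("a", "b", "c")  # sorted class order

    def test_study_scale_counting(self):
        # J membrane columns plus L columns for each of 22 polymer classes
        rng = np.random.default_rng(1)
        classes = [f"poly_{i:02d}" for i in range(22)]
        membrane = _random_set(rng, 8, [MEMBRANE_LABEL] * 100)
        clean = _random_set(rng, 8, [c for c in classes for _ in range(10)])
        lm = sv.build_learning_matrix(membrane, clean, J=100, L=10)
        assert lm.M == 100 + 22 * 10 == 320
        assert all(abs(col.min()) < 1e-9 and abs(col.max() - 1) < 1e-9
                   for col in lm.X.T)

    def test_shortfall_error_names_class(self):
        rng = np.random.default_rng(2)
        membrane = _random_set(rng, 8, [MEMBRANE_LABEL] * 3)
        clean = _random_set(rng, 8, ["a", "a", "b"])
        with pytest.raises(DictionaryError, match="'b'"):
            sv.build_learning_matrix(membrane, clean, J=3, L=2)

    def test_unnormalized_column_rejected(self):
        grid = np.arange(8.0)
        membrane = sv.SpectrumSet(
            [sv.Spectrum(grid, np.linspace(0, 1, 8), MEMBRANE_LABEL)]
        )
        clean = sv.SpectrumSet([sv.Spectrum(grid, np.linspace(0.2, 0.8, 8), "a")])
        with pytest.raises(DictionaryError, match="normalized"):
            sv.build_learning_matrix(membrane, clean, J=1, L=1)


class TestOmp:
    def test_orthonormal_identity_pick(self):
        D = np.eye(5)
        w = omp(D, D[:, 2].copy(), budget=1)
        assert np.flatnonzero(w).tolist() == [2]
        assert w[2] == pytest.approx(1.0)

    def test_two_component_recovery(self):
        rng = np.random.default_rng(0)
        D = incoherent_dictionary(rng, 8, 5, 0.5)
        s = 0.7 * D[:, 1] + 0.3 * D[:, 3]
        w = omp(D, s, budget=2)
        assert set(np.flatnonzero(np.abs(w) > 1e-12)) == {1, 3}
        assert w[1] == pytest.approx(0.7, abs=1e-9)
        assert w[3] == pytest.approx(0.3, abs=1e-9)

    def test_budget_one_takes_dominant_component(self):
        D = np.eye(5)
        s = 0.7 * D[:, 1] + 0.3 * D[:, 3]
        w = omp(D, s, budget=1)
        assert np.flatnonzero(w).tolist() == [1]

    def test_matches_exhaustive_search_on_incoherent_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(5, 9))
            k = int(rng.integers(3, 6))
            budget = int(rng.integers(1, 3))
            D = incoherent_dictionary(rng, n, k, 1 / 3)
            supp = rng.choice(k, size=budget, replace=False)
            coefs = rng.uniform(0.5, 1.5, budget) * rng.choice([-1, 1], budget)
            s = D[:, supp] @ coefs
            got = float(np.linalg.norm(s - D @ omp(D, s, budget)))
            want = exhaustive_best_residual(D, s, budget)
            assert abs(got - want) < 1e-9

    def test_agrees_with_reference_omp_implementation(self):
        from sklearn.linear_model import orthogonal_mp

        rng = np.random.default_rng(7)
        D = incoherent_dictionary(rng, 16, 6, 0.4)
        s = D[:, 0] * 1.2 - 0.8 * D[:, 4]
        ours = omp(D, s, budget=2)
        ref = orthogonal_mp(D, s, n_nonzero_coefs=2)
        assert np.allclose(ours, ref, atol=1e-9)

    def test_zero_signal_gives_zero_code(self):
        assert not omp(np.eye(4), np.zeros(4), budget=2).any()


class TestLearnDictionary:
    def test_exact_recovery_of_repeated_orthonormal_columns(self):
        rng = np.random.default_rng(5)
        Q, _ = np.linalg.qr(rng.standard_normal((20, 3)))
        cols, labels = [], []
        for i, lab in enumerate(["a", "b", MEMBRANE_LABEL]):
            v = Q[:, i]
            v = (v - v.min()) / (v.max() - v.min())
            for _ in range(4):
                cols.append(v)
                labels.append(lab)
        grid = np.arange(20.0)
        membrane = sv.SpectrumSet(
            [sv.Spectrum(grid, c, MEMBRANE_LABEL) for c, l in zip(cols, labels) if l == MEMBRANE_LABEL]
        )
        clean = sv.SpectrumSet(
            [sv.Spectrum(grid, c, l) for c, l in zip(cols, labels) if l != MEMBRANE_LABEL]
        )
        lm = sv.build_learning_matrix(membrane, clean, J=4, L=4)
        model = sv.learn_dictionary(lm, K=3, rng_seed=0, n_iter=30)
        assert np.linalg.norm(lm.X - model.D @ model.C) < 1e-6

    def test_rank_one_case_recovers_single_atom(self):
        rng = np.random.default_rng(6)
        v = rng.random(15)
        v = (v - v.min()) / (v.max() - v.min())
        grid = np.arange(15.0)
        membrane = sv.SpectrumSet([sv.Spectrum(grid, v, MEMBRANE_LABEL)] * 3)
        clean = sv.SpectrumSet([sv.Spectrum(grid, v, "a")] * 3)
        lm = sv.build_learning_matrix(membrane, clean, J=3, L=3)
        model = sv.learn_dictionary(lm, K=1, rng_seed=1)
        cosine = abs(model.D[:, 0] @ v) / np.linalg.norm(v)
        assert cosine >= 0.999

    def test_same_seed_reproduces_model(self, toy_split):
        train, _ = toy_split
        clean = sv.synthesize_clean_set(train, 4, rng_seed=2)
        membrane = sv.synthesize_membrane_set(train, 8, rng_seed=3)
        lm = sv.build_learning_matrix(membrane, clean, J=8, L=4)
        m1 = sv.learn_dictionary(lm, K=10, rng_seed=99, n_iter=10)
        m2 = sv.learn_dictionary(lm, K=10, rng_seed=99, n_iter=10)
        assert np.array_equal(m1.D, m2.D)
        assert np.array_equal(m1.C, m2.C)
        assert m1.membrane_atoms == m2.membrane_atoms

    def test_fit_trajectory_non_increasing(self, toy_model):
        fits = np.asarray(toy_model.fit_trajectory)
        assert len(fits) >= 2
        assert np.all(np.diff(fits) <= 1e-8)

    def test_undercompleteness_enforced(self):
        rng = np.random.default_rng(8)
        membrane = _random_set(rng, 6, [MEMBRANE_LABEL] * 4)
        clean = _random_set(rng, 6, ["a"] * 4)
        lm = sv.build_learning_matrix(membrane, clean, J=4, L=4)
        with pytest.raises(DictionaryError, match="undercomplete"):
            sv.learn_dictionary(lm, K=6, rng_seed=0)

    def test_k_larger_than_m_rejected(self):
        rng = np.random.default_rng(9)
        membrane = _random_set(rng, 30, [MEMBRANE_LABEL] * 2)
        clean = _random_set(rng, 30, ["a"] * 2)
        lm = sv.build_learning_matrix(membrane, clean, J=2, L=2)
        with pytest.raises(DictionaryError, match="exceeds"):
            sv.learn_dictionary(lm, K=10, rng_seed=0)


class TestMembraneAtomIndices:
    BLOCK = np.array([[0.0, 0.0], [1.2, 0.0], [0.0, -0.4]])

    def test_reads_nonzero_rows(self):
        assert membrane_atom_indices(self.BLOCK) == (1, 2)

    def test_explicit_threshold(self):
        assert membrane_atom_indices(self.BLOCK, tol=0.5) == (1,)

    def test_strict_numeric_zero_threshold(self):
        assert membrane_atom_indices(self.BLOCK, tol=COEFF_TOL) == (1, 2)

    def test_all_zero_block_empty(self):
        assert membrane_atom_indices(np.zeros((4, 3))) == ()


class TestRemoveReconstruct:
    def test_zeroing_listed_indices(self):
        code = SparseCode(np.array([0.5, 0.2, -0.1]))
        out = sv.remove_membrane(code, [1])
        assert np.array_equal(out.w, [0.5, 0.0, -0.1])

    def test_empty_index_set_is_identity(self):
        code = SparseCode(np.array([0.5, 0.2, -0.1]))
        assert np.array_equal(sv.remove_membrane(code, []).w, code.w)

    def test_full_removal_gives_zero_vector(self):
        code = SparseCode(np.array([0.5, 0.2, -0.1]))
        assert not sv.remove_membrane(code, [0, 1, 2]).w.any()

    def test_out_of_range_index_rejected(self):
        with pytest.raises(DictionaryError, match="out of range"):
            sv.remove_membrane(SparseCode(np.zeros(3)), [3])

    def test_reconstruct_identity_dictionary(self, toy_model):
        D = np.eye(3)
        model = sv.DictionaryModel(
            D=D, C=np.zeros((3, 1)), membrane_atoms=(), lam=1.0,
            grid=np.arange(3.0), column_labels=("a",), J=0, budget=2,
            coder="omp", rng_seed=0,
        )
        out = sv.reconstruct(model, SparseCode(np.array([0.5, 0.0, -0.1])))
        assert np.allclose(out.intensities, [0.5, 0.0, -0.1])
        assert np.allclose(
            sv.reconstruct(model, SparseCode(np.zeros(3))).intensities, 0.0
        )
        e1 = np.zeros(3); e1[1] = 1.0
        assert np.allclose(sv.reconstruct(model, SparseCode(e1)).intensities, D[:, 1])


class TestDenoise:
    def test_membrane_only_input_reconstructs_to_near_zero(self, toy_model, toy_heldout):
        z = sv.synthesize_membrane_set(toy_heldout, 1, rng_seed=21)[0]
        code = sv.sparse_code(z, toy_model)
        removed = sv.remove_membrane(code, toy_model.membrane_atoms)
        recon = sv.reconstruct(toy_model, removed)
        residual = float(
            np.linalg.norm(z.intensities - toy_model.D @ code.w)
        )
        # whatever OMP could not explain bounds what survives removal
        assert np.linalg.norm(recon.intensities) <= residual + 1e-9

    def test_clean_spectrum_without_membrane_atoms_passes_through(
        self, toy_model, toy_heldout
    ):
        # removal is the identity off I: pick a clean spectrum whose code
        # happens to use no membrane atoms (most do; some polish a satellite)
        y = next(
            s
            for s in sv.synthesize_clean_set(toy_heldout, 4, rng_seed=22)
            if set(sv.sparse_code(s, toy_model).support).isdisjoint(
                toy_model.membrane_atoms
            )
        )
        est, pre, post = sv.denoise(y, toy_model)
        assert np.array_equal(pre.w, post.w)
        plain = sv.reconstruct(toy_model, pre).intensities
        rescaled = (plain - plain.min()) / (plain.max() - plain.min())
        assert np.allclose(est.intensities, rescaled, atol=1e-12)

    def test_denoising_raises_gradient_correlation_with_truth(
        self, toy_model, toy_heldout
    ):
        mixtures = sv.synthesize_dataset(toy_heldout, 2, snr_db=0.0, rng_seed=23)
        for mix in mixtures:
            est, _, _ = sv.denoise(mix.noisy, toy_model)
            rho_denoised = sv.gradient_correlation(est, mix.clean_truth)
            rho_raw = sv.gradient_correlation(mix.noisy, mix.clean_truth)
            assert rho_denoised > rho_raw

    def test_post_removal_support_in_nonmembrane_span(self, toy_model, toy_heldout):
        mix = sv.synthesize_dataset(toy_heldout, 1, snr_db=-20.0, rng_seed=24)[0]
        _, _, post = sv.denoise(mix.noisy, toy_model)
        assert set(post.support).isdisjoint(toy_model.membrane_atoms)


class TestPersistence:
    def test_round_trip(self, toy_model, tmp_path):
        path = tmp_path / "model.npz"
        sv.save_model(toy_model, path)
        back = sv.load_model(path)
        assert np.array_equal(back.D, toy_model.D)
        assert np.array_equal(back.C, toy_model.C)
        assert back.membrane_atoms == toy_model.membrane_atoms
        assert back.column_labels == toy_model.column_labels
        assert back.class_atom_map == toy_model.class_atom_map
        assert back.lam == toy_model.lam
        assert back.gain_tol == toy_model.gain_tol
        assert back.objective_trajectory == toy_model.objective_trajectory
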