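"""Crossnobis engine tests: noise model, pair LDC, averaging, subspaces."""

import itertools

import numpy as np
import pytest

from seqobs import mvpa, synth


def brute_force_crossnobis(pj, pk, sigma=None):
    """Independent fold-by-fold enumeration of the LDC estimator."""
    d = np.asarray(pj, dtype=float) - np.asarray(pk, dtype=float)
    if sigma is not None:
        vals, vecs = np.linalg.eigh(sigma)
        d = d @ (vecs @ np.diag(vals**-0.5) @ vecs.T)
    R, P = d.shape
    folds = []
    for m in range(R):
        train = np.mean([d[r] for r in range(R) if r != m], axis=0)
        folds.append(float(np.dot(train, d[m]) / P))
    return float(np.mean(folds)), np.array(folds)


class TestNoiseModel:
    def test_iid_residuals_give_near_identity(self, rng):
        res = [rng.standard_normal((3000, 8)) for _ in range(3)]
        nm = mvpa.estimate_noise_cov(res)
        off = nm.sigma - np.diag(np.diag(nm.sigma))
        assert np.abs(off).max() < 0.1
        assert np.allclose(np.diag(nm.sigma), 1.0, atol=0.15)

    def test_full_shrinkage_is_diagonal(self, rng):
        res = [rng.standard_normal((50, 6)) for _ in range(2)]
        nm = mvpa.estimate_noise_cov(res, shrinkage_weight=1.0)
        assert np.allclose(nm.sigma, np.diag(np.diag(nm.sigma)))

    def test_positive_definite_even_when_t_below_p(self, rng):
        # more voxels than time points: raw covariance is singular
        res = [rng.standard_normal((12, 30)) for _ in range(4)]
        nm = mvpa.estimate_noise_cov(res)
        assert np.linalg.eigvalsh(nm.sigma).min() > 0

    def test_zero_residuals_rejected(self):
        with pytest.raises(ValueError):
            mvpa.estimate_noise_cov([np.zeros((10, 4))])

    def test_whitener_inverts_covariance(self, rng):
        res = [rng.standard_normal((200, 5)) for _ in range(2)]
        nm = mvpa.estimate_noise_cov(res, shrinkage_weight=0.2)
        W = nm.whitener()
        assert np.allclose(W @ nm.sigma @ W, np.eye(5), atol=1e-10)


class TestCrossnobisPair:
    def test_identical_patterns_give_exact_zero(self, rng):
        p = rng.standard_normal((10, 6))
        ldc, folds = mvpa.crossnobis_pair(p, p.copy())
        assert ldc == 0.0
        assert np.all(folds == 0.0)

    def test_matches_brute_force_oracle(self, rng):
        """Hand-sized inputs equal independent fold enumeration to 1e-10."""
        for R, P in itertools.product((2, 3, 4), (2, 4, 6)):
            pj = rng.standard_normal((R, P))
            pk = rng.standard_normal((R, P))
            A = rng.standard_normal((P, P))
            sigma = A @ A.T + P * np.eye(P)
            nm = mvpa.NoiseModel(sigma, 0.0)
            got, got_folds = mvpa.crossnobis_pair(pj, pk, nm)
            want, want_folds = brute_force_crossnobis(pj, pk, sigma)
            assert got == pytest.approx(want, abs=1e-10)
            assert np.allclose(got_folds, want_folds, atol=1e-10)

    def test_null_distribution_is_centered_at_zero(self, rng):
        """Unbiasedness: pure-noise patterns give mean LDC ~ 0."""
        n_sims, vals = 1000, []
        for _ in range(n_sims):
            ldc, _ = mvpa.crossnobis_pair(
                rng.standard_normal((6, 12)), rng.standard_normal((6, 12))
            )
            vals.append(ldc)
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(n_sims)
        assert abs(vals.mean()) < 3 * se

    def test_run_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            mvpa.crossnobis_pair(rng.standard_normal((4, 3)), rng.standard_normal((5, 3)))

    def test_whitening_equivalence(self, rng):
        """LDC with noise sigma equals plain LDC on sigma^(-1/2)-rotated data."""
        pj, pk = rng.standard_normal((5, 7)), rng.standard_normal((5, 7))
        A = rng.standard_normal((7, 7))
        nm = mvpa.NoiseModel(A @ A.T + 7 * np.eye(7), 0.0)
        W = nm.whitener()
        direct, _ = mvpa.crossnobis_pair(pj, pk, nm)
        rotated, _ = mvpa.crossnobis_pair(pj @ W, pk @ W)
        assert direct == pytest.approx(rotated, abs=1e-10)


class TestAverageDissimilarity:
    def test_six_pairs(self, rng):
        est = mvpa.average_dissimilarity(rng.standard_normal((4, 5, 8)))
        assert est.pairwise.shape == (6,)
        assert est.fold_values.shape == (6, 5)
        assert est.average == pytest.approx(est.pairwise.mean())

    def test_sequence_order_invariance(self, rng):
        pats = rng.standard_normal((4, 6, 10))
        a = mvpa.average_dissimilarity(pats).average
        b = mvpa.average_dissimilarity(pats[[2, 0, 3, 1]]).average
        assert a == pytest.approx(b, abs=1e-12)

    def test_average_matches_pairwise_oracle(self, rng):
        pats = rng.standard_normal((4, 2, 3))
        est = mvpa.average_dissimilarity(pats)
        oracle = np.mean(
            [
                brute_force_crossnobis(pats[j], pats[k])[0]
                for j, k in itertools.combinations(range(4), 2)
            ]
        )
        assert est.average == pytest.approx(oracle, abs=1e-12)

    def test_wrong_sequence_count_rejected(self, rng):
        with pytest.raises(ValueError):
            mvpa.average_dissimilarity(rng.standard_normal((3, 5, 8)))

    def test_monotone_in_signal_amplitude(self, small_truth):
        """Expected LDC grows with the injected pattern-difference scale."""
        means = []
        for i, amp in enumerate([0.0, 0.3, 0.6, 1.2]):
            truth = synth.with_amplitude(small_truth, amp)
            nm = mvpa.NoiseModel(small_truth.noise_cov, 0.0)
            vals = [
                mvpa.average_dissimilarity(
                    synth.simulate_run_patterns(truth, "pre", "trained", 10, 1.0, 1000 * i + r),
                    nm,
                ).average
                for r in range(200)
            ]
            means.append(np.mean(vals))
        assert all(b >= a for a, b in zip(means, means[1:]))


class TestRandomSubspace:
    def test_exact_size_roi_reduces_to_whole_roi(self, rng):
        pats = rng.standard_normal((4, 5, 20))
        whole = mvpa.average_dissimilarity(pats).average
        sub = mvpa.random_subspace_ldc(pats, None, n_subsets=17, subset_size=20, seed=4)
        assert sub == pytest.approx(whole, abs=1e-12)

    def test_seed_determinism(self, rng):
        pats = rng.standard_normal((4, 5, 40))
        a = mvpa.random_subspace_ldc(pats, None, n_subsets=20, subset_size=10, seed=9)
        b = mvpa.random_subspace_ldc(pats, None, n_subsets=20, subset_size=10, seed=9)
        c = mvpa.random_subspace_ldc(pats, None, n_subsets=20, subset_size=10, seed=10)
        assert a == b
        assert a != c

    def test_small_roi_falls_back_to_whole_roi(self, rng, caplog):
        pats = rng.standard_normal((4, 5, 8))
        with caplog.at_level("WARNING", logger="seqobs.mvpa"):
            got = mvpa.random_subspace_ldc(pats, None, subset_size=160)
        assert got == pytest.approx(mvpa.average_dissimilarity(pats).average)
        assert "whole-ROI" in caplog.text

    def test_subset_count_convergence(self, rng):
        """More subsets converge to the same value within sampling error."""
        pats = rng.standard_normal((4, 8, 60)) + 2.0 * rng.standard_normal((4, 1, 60))
        few = mvpa.random_subspace_ldc(pats, None, n_subsets=300, subset_size=20, seed=1)
        many = mvpa.random_subspace_ldc(pats, None, n_subsets=3000, subset_size=20, seed=2)
        # SE of the subset mean at n=300, measured from a pilot spread
        pilot = [
            mvpa.random_subspace_ldc(pats, None, n_subsets=1, subset_size=20, seed=100 + i)
            for i in range(50)
        ]
        se = np.std(pilot, ddof=1) / np.sqrt(300)
        assert abs(few - many) < 4 * se
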