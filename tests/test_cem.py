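"""CEM family: ATGP seeding, SAM pooling, the CEM/K-CEM filters, Otsu
binarization and the I-CEM loop."""

import numpy as np
import pytest

import ivimhsi as hs
from ivimhsi import phantom as ph
from ivimhsi.detect_cem import (
    atgp,
    binarize,
    cem_filter,
    cem_weights,
    icem,
    kcem,
    otsu_threshold,
    pool_training_signature,
    sam_angle,
)
from ivimhsi.errors import DegenerateInputError, InvalidSpecError


class TestAtgp:
    def test_first_target_is_max_norm_pixel(self):
        X = np.array([[3.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        idx, sig, _ = atgp(X, 1)
        assert idx[0] == 0
        np.testing.assert_array_equal(sig[0], [3, 0])

    def test_second_target_tie_breaks_to_lowest_index(self):
        # after projecting out (3,0), residuals of (0,1) and (1,1) both have
        # norm 1; the tie goes to the lower flat index
        X = np.array([[3.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        idx, _, _ = atgp(X, 2)
        assert list(idx) == [0, 1]

    def test_rank_exhaustion_stops_early_with_warning(self):
        X = np.tile([2.0, 1.0], (5, 1))
        with pytest.warns(UserWarning, match="rank"):
            idx, _, _ = atgp(X, 2)
        assert len(idx) == 1

    def test_residual_norms_strictly_decreasing(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 8))
        _, _, norms = atgp(X, 6)
        assert np.all(np.diff(norms) < 0)


class TestSam:
    @pytest.mark.parametrize(
        "x,d,expected",
        [
            ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 0.0),
            ([1.0, 0.0], [0.0, 1.0], np.pi / 2),
            ([1.0, 1.0], [1.0, 0.0], np.pi / 4),
        ],
    )
    def test_known_angles(self, x, d, expected):
        assert sam_angle(np.array(x), np.array(d)) == pytest.approx(expected)

    def test_zero_vector_rejected(self):
        with pytest.raises(InvalidSpecError):
            sam_angle(np.zeros(3), np.ones(3))

    def test_pool_threshold_zero_returns_seed(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 2.0]])
        d = pool_training_signature(X, X[0], 0.0)
        np.testing.assert_array_equal(d, X[0])

    def test_pool_threshold_pi_returns_global_mean(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0.5, 2.0, (20, 4))
        d = pool_training_signature(X, X[7], np.pi)
        np.testing.assert_allclose(d, X.mean(axis=0))

    def test_pool_selects_only_close_spectra(self):
        seed = np.array([1.0, 0.0])
        near = np.array([np.cos(0.05), np.sin(0.05)])
        far = np.array([np.cos(0.5), np.sin(0.5)])
        d = pool_training_signature(np.vstack([near, far]), seed, 0.1)
        np.testing.assert_allclose(d, (seed + near) / 2)


class TestCemFilter:
    def test_unity_constraint_at_target(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 2, (50, 4))
        d = rng.uniform(0.5, 1.5, 4)
        w = cem_weights(X, d)
        assert abs(w @ d - 1.0) < 1e-10

    def test_hand_solved_two_pixel_instance(self):
        # pixels (1,0) and (0,1) equally frequent: R = I/2, w = (1,0)*2/2
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        y = cem_filter(X, np.array([1.0, 0.0]), ridge=0.0)
        assert y[1] == pytest.approx(0.0, abs=1e-12)
        assert y[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_kkt_oracle_on_random_instances(self):
        # oracle: solve min w'Rw s.t. d'w = 1 via the KKT block system
        rng = np.random.default_rng(3)
        for _ in range(25):
            L = rng.integers(2, 5)
            N = rng.integers(L + 1, 51)
            X = rng.uniform(0.1, 2.0, (N, L))
            d = rng.uniform(0.5, 1.5, L)
            ridge = 1e-8
            R = X.T @ X / N + ridge * np.eye(L)
            kkt = np.block([[2 * R, d[:, None]], [d[None, :], np.zeros((1, 1))]])
            sol = np.linalg.solve(kkt, np.concatenate([np.zeros(L), [1.0]]))
            np.testing.assert_allclose(cem_weights(X, d, ridge), sol[:L], atol=1e-8)

    def test_minimizes_energy_among_feasible_filters(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0.1, 2.0, (40, 3))
        d = rng.uniform(0.5, 1.5, 3)
        w = cem_weights(X, d, ridge=0.0)
        energy = np.mean((X @ w) ** 2)
        for _ in range(1000):
            p = rng.normal(size=3)
            p -= (p @ d) / (d @ d) * d  # keep w'd = 1
            w2 = w + 0.1 * p
            assert np.mean((X @ w2) ** 2) >= energy - 1e-12


class TestKcem:
    def test_unity_at_target(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 2, (60, 4))
        d = X[10] + 0.01
        Xd = np.vstack([X, d])
        y = kcem(Xd, d, seed=0)
        assert abs(y[-1] - 1.0) < 1e-9

    def test_linear_kernel_equals_cem_on_full_rank_toy(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0.5, 2.0, (10, 3))
        d = X[3] * 1.1
        ridge = 1e-6
        y_cem = cem_filter(X, d, ridge)
        y_lin = kcem(X, d, kernel="linear", sample_size=10, ridge=ridge, seed=0)
        np.testing.assert_allclose(y_lin, y_cem, atol=1e-6)

    def test_small_sigma_limit_is_local_around_target(self):
        # numeric limit: as sigma shrinks below the inter-pixel distances
        # the RBF detector responds only at the target itself
        rng = np.random.default_rng(7)
        X = rng.uniform(0.5, 2.0, (10, 3))
        d = X[3]
        dists = np.linalg.norm(X - d, axis=1)
        sigma = 0.01 * dists[dists > 0].min()
        y = kcem(X, d, sigma=sigma, sample_size=10, seed=0)
        assert y[3] == pytest.approx(1.0, abs=1e-9)
        off = np.delete(y, 3)
        assert np.abs(off).max() < 1e-6

    def test_non_positive_sigma_rejected(self):
        X = np.ones((5, 2))
        with pytest.raises(InvalidSpecError):
            kcem(X, np.ones(2), sigma=0.0)


class TestOtsu:
    def test_perfectly_bimodal_values(self):
        vals = np.concatenate([np.zeros(50), np.full(50, 10.0)])
        thr, mask = binarize(vals)
        assert 0 < thr < 10
        assert mask.sum() == 50

    def test_matches_brute_force_between_class_variance(self):
        # oracle: exhaustive search over 256-bin splits; compared on the
        # achieved objective, which is tie-robust (the empty inter-mode
        # valley yields a plateau of maximizers equal to the last bit)
        rng = np.random.default_rng(8)
        for _ in range(20):
            vals = np.concatenate(
                [rng.normal(0, 1, 400), rng.normal(6, 1, rng.integers(50, 300))]
            )
            counts, edges = np.histogram(vals, bins=256)
            centers = (edges[:-1] + edges[1:]) / 2
            w = counts / counts.sum()

            def var_at(t):
                w0, w1 = w[:t].sum(), w[t:].sum()
                if w0 == 0 or w1 == 0:
                    return -1.0
                m0 = (w[:t] @ centers[:t]) / w0
                m1 = (w[t:] @ centers[t:]) / w1
                return w0 * w1 * (m0 - m1) ** 2

            best_var = max(var_at(t) for t in range(1, 256))
            lib = otsu_threshold(vals)
            t_lib = int(np.argmin(np.abs(centers - lib))) + 1
            assert var_at(t_lib) >= best_var * (1 - 1e-12)

    def test_scale_equivariance_of_mask(self):
        rng = np.random.default_rng(9)
        vals = np.concatenate([rng.normal(0, 1, 300), rng.normal(5, 1, 100)])
        _, m1 = binarize(vals)
        _, m2 = binarize(2.0 * vals)
        np.testing.assert_array_equal(m1, m2)

    def test_constant_map_rejected(self):
        with pytest.raises(DegenerateInputError):
            otsu_threshold(np.full(100, 3.0))


class TestIcem:
    def test_noise_free_phantom_converges_second_iteration_exactly(self):
        out = hs.generate_phantom(hs.PhantomSpec(noise_sigma=0.0, seed=0))
        breast = out.labels > 0
        det = icem(out.cube, breast, seed=0)
        assert len(det.log) == 2
        assert det.log[-1].difference_rate == 0.0
        np.testing.assert_array_equal(det.mask, out.truth_mask)

    def test_seeded_determinism(self, breast_pixels):
        cube, breast, _, _ = breast_pixels
        a = icem(cube, breast, seed=42)
        b = icem(cube, breast, seed=42)
        np.testing.assert_array_equal(a.mask, b.mask)
        assert [l.difference_rate for l in a.log] == [l.difference_rate for l in b.log]

    def test_mass_phantom_dice(self, noisy_phantom, breast_pixels):
        cube, breast, _, _ = breast_pixels
        det = icem(cube, breast, seed=1)
        assert hs.dice(det.mask, noisy_phantom.truth_mask) >= 0.90

    def test_difference_rates_share_denominator_and_converge(self, breast_pixels):
        cube, breast, _, _ = breast_pixels
        det = icem(cube, breast, seed=3, max_iter=50)
        rates = [l.difference_rate for l in det.log[1:]]
        assert all(r is not None for r in rates)
        if len(det.log) < 50:
            assert rates[-1] <= 0.01
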