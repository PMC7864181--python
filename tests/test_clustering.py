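import numpy as np
import pytest
from dataclasses import replace

from ifcmms import (
    AlgoConfig,
    GrayImage,
    center_update,
    fcm,
    hesitation_entropy,
    ifcm_ms,
    membership_update,
    objective,
)
from ifcmms.clustering import ablation_configs


def brute_force_fcm(x, c, m, eta, max_iter, init_u):
    """Loop implementation of the classical FCM alternation (oracle)."""
    U = init_u.copy()
    n = x.size
    for _ in range(max_iter):
        V = np.empty(c)
        for i in range(c):
            w = U[i] ** m
            V[i] = (w * x).sum() / w.sum()
        U_new = np.empty_like(U)
        for k in range(n):
            d2 = (x[k] - V) ** 2
            if (d2 == 0).any():
                U_new[:, k] = 0.0
                U_new[int(np.argmax(d2 == 0)), k] = 1.0
            else:
                p = d2 ** (-1.0 / (m - 1.0))
                U_new[:, k] = p / p.sum()
        delta = np.abs(U_new - U).max()
        U = U_new
        if delta <= eta:
            break
    V_final = np.array([((U[i] ** m) * x).sum() / (U[i] ** m).sum() for i in range(c)])
    return U, V_final


class TestMembershipUpdate:
    def test_two_cluster_value(self):
        """m=2, S=(0.8, 0.4): u = (0.64, 0.16)/0.80 = (0.8, 0.2)."""
        S = np.array([[0.8], [0.4]])
        u = membership_update(S, 2.0)
        np.testing.assert_allclose(u[:, 0], [0.8, 0.2], rtol=1e-12)

    def test_equal_similarity_gives_uniform(self):
        u = membership_update(np.full((4, 7), 0.3), 2.0)
        np.testing.assert_allclose(u, 0.25, rtol=1e-12)

    def test_vanishing_similarity_limit(self):
        u = membership_update(np.array([[1.0], [1e-12]]), 2.0)
        assert u[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_columns_normalized(self):
        rng = np.random.default_rng(0)
        u = membership_update(rng.uniform(0.01, 1, size=(3, 50)), 1.8)
        np.testing.assert_allclose(u.sum(axis=0), 1.0, atol=1e-12)

    def test_all_zero_column_rejected(self):
        with pytest.raises(ValueError):
            membership_update(np.array([[0.0], [0.0]]), 2.0)

    def test_invalid_fuzzifier_rejected(self):
        with pytest.raises(ValueError):
            membership_update(np.ones((2, 2)), 1.0)


class TestCenterUpdate:
    def test_uniform_memberships_give_image_mean(self):
        grays = np.array([0.0, 10.0, 20.0, 30.0])
        coords = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        u = np.full((2, 4), 0.5)
        gray_c, spat_c = center_update(u, grays, coords)
        np.testing.assert_allclose(gray_c, 15.0)
        np.testing.assert_allclose(spat_c, [[0.5, 0.5], [0.5, 0.5]])

    def test_hard_memberships_give_region_means(self):
        grays = np.array([10.0, 10.0, 200.0])
        coords = np.zeros((3, 2))
        u = np.array([[1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        gray_c, _ = center_update(u, grays, coords)
        np.testing.assert_allclose(gray_c, [10.0, 200.0])

    def test_weighted_mean_value(self):
        """Weights (0.8, 0.2) on grays (100, 0): v = 80."""
        gray_c, _ = center_update(
            np.array([[0.8, 0.2]]), np.array([100.0, 0.0]), np.zeros((2, 2))
        )
        assert gray_c[0] == pytest.approx(80.0, rel=1e-12)

    def test_powered_weights_differ_from_plain(self):
        u = np.array([[0.8, 0.2], [0.2, 0.8]])
        grays = np.array([100.0, 0.0])
        plain, _ = center_update(u, grays, np.zeros((2, 2)), m=2.0, powered=False)
        powered, _ = center_update(u, grays, np.zeros((2, 2)), m=2.0, powered=True)
        assert plain[0] == pytest.approx(80.0)
        assert powered[0] == pytest.approx(100 * 0.64 / 0.68)

    def test_collapsed_cluster_reseeded(self):
        rng = np.random.default_rng(1)
        u = np.array([[1.0, 1.0], [0.0, 0.0]])
        gray_c, _ = center_update(u, np.array([5.0, 7.0]), np.zeros((2, 2)), rng=rng)
        assert gray_c[1] in (5.0, 7.0)

    def test_collapsed_cluster_without_rng_raises(self):
        with pytest.raises(ValueError):
            center_update(np.array([[1.0], [0.0]]), np.array([5.0]), np.zeros((1, 2)))


class TestObjective:
    def test_uniform_membership_value(self):
        """All S=1, pi=0, uniform u over c=2: J = n * 2 * 0.25 = n/2."""
        n = 12
        u = np.full((2, n), 0.5)
        J = objective(u, np.ones((2, n)), np.zeros((2, n)), 2.0)
        assert J == pytest.approx(n / 2, rel=1e-12)

    def test_hard_membership_value(self):
        n = 9
        u = np.zeros((3, n))
        u[0] = 1.0
        J = objective(u, np.ones((3, n)), np.zeros((3, n)), 2.0)
        assert J == pytest.approx(n, rel=1e-12)

    def test_entropy_term_additivity(self):
        u = np.full((2, 4), 0.5)
        pi = np.full((2, 4), 0.2)
        base = objective(u, np.ones((2, 4)), np.zeros((2, 4)), 2.0)
        J = objective(u, np.ones((2, 4)), pi, 2.0)
        assert J - base == pytest.approx(hesitation_entropy(pi), rel=1e-12)


class TestFCM:
    def test_hard_fixed_point(self, two_value_image):
        """Hard init on a two-value image is a fixed point of the alternation."""
        img = two_value_image(0)
        x = img.pixels.astype(float).ravel()
        init = np.vstack([(x == 10).astype(float), (x == 200).astype(float)])
        r = fcm(img, AlgoConfig(c=2, seed=0), init_u=init)
        assert r.converged and r.iterations <= 2
        assert sorted(c.gray_center for c in r.centers) == pytest.approx([10.0, 200.0], abs=1e-9)

    def test_recovers_two_value_centers(self, two_value_image):
        img = two_value_image(3)
        r = fcm(img, AlgoConfig(c=2, seed=3, max_iter=300))
        got = sorted(c.gray_center for c in r.centers)
        assert abs(got[0] - 10) < 1.0 and abs(got[1] - 200) < 1.0

    def test_objective_nonincreasing(self, two_value_image):
        r = fcm(two_value_image(5), AlgoConfig(c=2, seed=5, max_iter=300))
        trace = np.array(r.objective_trace)
        assert np.all(np.diff(trace) <= 1e-8)

    def test_matches_brute_force_oracle(self, two_value_image):
        img = two_value_image(7)
        x = img.pixels.astype(float).ravel()
        cfg = AlgoConfig(c=2, seed=7, max_iter=40)
        rng = np.random.default_rng(7)
        init = rng.uniform(size=(2, x.size))
        init /= init.sum(axis=0)
        r = fcm(img, cfg, init_u=init)
        U_o, V_o = brute_force_fcm(x, 2, 2.0, cfg.eta, cfg.max_iter, init)
        np.testing.assert_allclose(r.memberships.reshape(2, -1), U_o, atol=1e-6)
        np.testing.assert_allclose([c.gray_center for c in r.centers], V_o, atol=1e-6)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            fcm(GrayImage(np.full((8, 8), 42, dtype=np.uint8), 255), AlgoConfig(c=2))


class TestIFCMMS:
    def test_clean_two_blob_phantom_segmented_exactly(self, two_blob_spec):
        """Noiseless two-class phantom: the label map equals the generating
        mask (up to cluster order) for every seed."""
        from ifcmms import make_phantom

        for seed in range(5):
            img, mask = make_phantom(two_blob_spec(seed))
            r = ifcm_ms(img, AlgoConfig(c=2, seed=seed))
            bright = int(np.argmax([c.gray_center for c in r.centers]))
            np.testing.assert_array_equal(r.labels == bright, mask == 1)

    def test_deterministic_given_seed(self, small_phantom):
        img, _ = small_phantom(0, shape=(48, 48))
        r1 = ifcm_ms(img, AlgoConfig(c=4, seed=11))
        r2 = ifcm_ms(img, AlgoConfig(c=4, seed=11))
        np.testing.assert_array_equal(r1.labels, r2.labels)
        assert r1.objective_trace == r2.objective_trace

    def test_reduces_to_fcm_fixed_points(self, two_value_image):
        """With IFS, transfer and similarity off and a tight fixed gray scale,
        the update leaves classical FCM fixed points in place."""
        img = two_value_image(9)
        cfg = AlgoConfig(c=2, seed=9, max_iter=300)
        rf = fcm(img, cfg)
        assert rf.converged
        cfg2 = replace(
            cfg, use_ifs=False, use_transfer=False, use_similarity=False,
            fixed_gray_scale=0.005, max_iter=2,
        )
        ri = ifcm_ms(img, cfg2, init_u=rf.memberships.reshape(2, -1))
        got = sorted(c.gray_center for c in ri.centers)
        want = sorted(c.gray_center for c in rf.centers)
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_labels_invariant_under_init_permutation(self, small_phantom):
        img, _ = small_phantom(1, shape=(48, 48))
        rng = np.random.default_rng(21)
        init = rng.uniform(size=(4, 48 * 48))
        init /= init.sum(axis=0)
        cfg = AlgoConfig(c=4, seed=21)
        r1 = ifcm_ms(img, cfg, init_u=init)
        perm = np.array([2, 0, 3, 1])
        r2 = ifcm_ms(img, cfg, init_u=init[perm])
        np.testing.assert_array_equal(perm[r2.labels], r1.labels)

    def test_terminates_without_transfer(self, small_phantom):
        """The similarity/membership/center loop alone converges within the
        iteration cap on phantom fixtures."""
        from ifcmms import salt_and_pepper

        for seed in range(3):
            img, _ = small_phantom(seed)
            noisy = salt_and_pepper(img, 0.02, seed=seed + 50)
            r = ifcm_ms(noisy, replace(AlgoConfig(c=4, seed=seed), use_transfer=False))
            assert r.converged and r.iterations <= 100

    def test_nonconvergence_reported_not_raised(self, small_phantom):
        img, _ = small_phantom(2, shape=(48, 48))
        r = ifcm_ms(img, AlgoConfig(c=4, seed=2, max_iter=3))
        assert r.iterations == 3 and not r.converged
        assert len(r.objective_trace) == 3

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            ifcm_ms(GrayImage(np.zeros((8, 8), dtype=np.uint8), 255), AlgoConfig(c=2))

    def test_objective_trace_finite(self, small_phantom):
        img, _ = small_phantom(3, shape=(48, 48))
        r = ifcm_ms(img, AlgoConfig(c=4, seed=3, max_iter=20))
        assert np.all(np.isfinite(r.objective_trace))


@pytest.mark.parametrize(
    "kwargs",
    [{"c": 1}, {"m": 1.0}, {"eta": 0.0}, {"max_iter": 0}],
)
def test_config_validation(kwargs):
    with pytest.raises(ValueError):
        AlgoConfig(**kwargs)


def test_ablation_configs_add_switches_in_order():
    names_flags = [
        (cfg.use_ifs, cfg.use_transfer, cfg.use_similarity)
        for _, cfg in ablation_configs(AlgoConfig())
    ]
    assert names_flags == [
        (False, False, False),
        (True, False, False),
        (True, True, False),
        (True, True, True),
    ]
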