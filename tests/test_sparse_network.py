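"""Sparse cortex->FSI->SPN instance: wiring, Oja learning, separation."""

import numpy as np
import pytest

from striodm.exceptions import (
    InvalidParameterError,
    UndefinedStatisticError,
)
from striodm.sparse_network import (
    apply_stress,
    bhattacharyya_distance,
    build_sparse_network,
    compute_fsi,
    compute_sparse_activities,
    learn_network_weights,
    learn_oja_weights,
)
from striodm.synthetic import gaussian_with_spectrum, generate_cortical_activity


class TestWiring:
    def test_single_full_group(self):
        net = build_sparse_network(n_cortex=6, n_groups=1, group_size=6, q=4, seed=0)
        assert sorted(net.groups[0]) == list(range(6))

    def test_deterministic_under_seed(self):
        a = build_sparse_network(seed=5)
        b = build_sparse_network(seed=5)
        assert np.array_equal(a.groups, b.groups)
        assert np.array_equal(a.w_s, b.w_s)

    def test_membership_counts_near_uniform(self):
        net = build_sparse_network(n_cortex=50, n_groups=1000, group_size=4, seed=1)
        counts = np.bincount(net.groups.ravel(), minlength=50)
        expected = 1000 * 4 / 50
        # each neuron's membership ~ Binomial(n_groups, 4/50)
        sd = np.sqrt(1000 * (4 / 50) * (1 - 4 / 50))
        assert np.all(np.abs(counts - expected) < 4 * sd)

    def test_impossible_sampling_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_sparse_network(n_cortex=3, group_size=4)


class TestOjaLearning:
    def test_dominant_component_recovered(self):
        x, _ = gaussian_with_spectrum(3000, (4.0, 1.0), seed=2, rotate=False)
        W = learn_oja_weights(x, k=1, lr=0.05, epochs=20, seed=0)
        assert abs(W[:, 0] @ np.array([1.0, 0.0])) > 0.99

    def test_ordered_components_match_eigendecomposition(self):
        x, u = gaussian_with_spectrum(2000, (4.0, 2.0, 1.0, 0.5), seed=3)
        W = learn_oja_weights(x, k=4, lr=0.05, epochs=40, seed=0)
        cos = np.abs(np.sum(W * u, axis=0))
        assert np.all(cos > 0.97)

    def test_isotropic_norms_and_orthogonality(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((3000, 3))
        W = learn_oja_weights(x, k=3, lr=0.02, epochs=30, seed=1)
        np.testing.assert_allclose(np.linalg.norm(W, axis=0), 1.0, atol=1e-3)
        gram = W.T @ W
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 0.05

    def test_zero_learning_rate_keeps_init(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((100, 3))
        W1 = learn_oja_weights(x, k=1, lr=0.0, epochs=5, seed=9)
        W2 = learn_oja_weights(x, k=1, lr=0.0, epochs=50, seed=9)
        np.testing.assert_array_equal(W1, W2)

    def test_rank_deficiency_warns(self):
        x = np.outer(np.arange(50.0), np.ones(3))  # rank-1 data
        with pytest.warns(RuntimeWarning):
            learn_oja_weights(x, k=3, lr=0.05, epochs=2, seed=0)

    def test_network_learning_aligns_to_local_components(self):
        net = build_sparse_network(n_cortex=20, n_groups=30, group_size=4, q=2, seed=6)
        x, _ = generate_cortical_activity(
            1500, 20, amplitudes=(2.0,), noise_sd=0.3, seed=7
        )
        learned = learn_network_weights(net, x, epochs=10, seed=8)
        # compare every group's first learned vector with its local top PC
        cov = np.cov(x.T)
        cosines = []
        for g in range(net.n_groups):
            idx = net.groups[g]
            evals, evecs = np.linalg.eigh(cov[np.ix_(idx, idx)])
            pc1 = evecs[:, -1]
            cosines.append(abs(learned.w_s[g, 0] @ pc1))
        assert np.median(cosines) > 0.95


class TestActivities:
    def test_zero_input_gives_sigmoid_baseline(self):
        net = build_sparse_network(n_cortex=10, n_groups=20, group_size=3, q=3, seed=0)
        out = compute_sparse_activities(net, np.zeros(10), rmtg=0.3, z_dasnc=0.1)
        assert np.all(out["sspn"] == 0)
        np.testing.assert_allclose(out["dasnc"], 1 / (1 + np.exp(0.3 - 0.1)))

    def test_closed_gate_zeroes_mspn(self):
        net = build_sparse_network(n_cortex=10, n_groups=5, group_size=3, q=2, seed=1)
        rng = np.random.default_rng(0)
        out = compute_sparse_activities(net, rng.standard_normal(10), d=[0.0, 1.0])
        assert np.all(out["mspn"][:, 0] == 0)
        assert np.any(out["mspn"][:, 1] != 0)

    def test_hand_evaluated_group(self):
        net = build_sparse_network(n_cortex=2, n_groups=1, group_size=2, q=1, seed=0)
        net.groups[0] = [0, 1]
        net.fsi_members[0] = [0, 1]
        net.w_s[0, 0] = [1.0, 2.0]
        x = np.array([3.0, 4.0])
        out = compute_sparse_activities(net, x)
        # FSI = floor + mean|x| = 0.5 + 3.5 = 4; sSPN = (1*3+2*4)/(2*4)
        assert out["fsi"][0] == pytest.approx(4.0)
        assert out["sspn"][0, 0] == pytest.approx(11 / 8)

    def test_on_dimension_signal_raises_subpopulation_variance(self):
        """Signal along a decision-dimension widens that dimension's sSPN
        activity distribution relative to matched-power white noise."""
        net = build_sparse_network(n_cortex=30, n_groups=200, group_size=4, q=2, seed=2)
        x_train, loadings = generate_cortical_activity(
            2000, 30, amplitudes=(2.0,), noise_sd=0.3, seed=3
        )
        net = learn_network_weights(net, x_train, epochs=8, seed=4)
        rng = np.random.default_rng(5)
        wins = 0
        n_sim = 100
        for _ in range(n_sim):
            amp = 2.0 * rng.standard_normal()
            signal = amp * loadings[:, 0]
            noise = rng.standard_normal(30) * np.sqrt(signal @ signal / 30)
            v_sig = compute_sparse_activities(net, signal)["sspn"][:, 0].var()
            v_noise = compute_sparse_activities(net, noise)["sspn"][:, 0].var()
            wins += v_sig > v_noise
        # one-sided sign test at p < 0.01
        from scipy.stats import binomtest

        assert binomtest(wins, n_sim, 0.5, alternative="greater").pvalue < 0.01


class TestStress:
    def test_connection_removal_counts(self):
        net = build_sparse_network(n_cortex=20, n_groups=10, group_size=4, seed=0)
        stressed = apply_stress(net, n_removed=2, seed=1)
        assert stressed.fsi_members.shape == (10, 2)
        assert np.array_equal(stressed.groups, net.groups)

    def test_fsi_tracks_input_less_after_stress(self):
        net = build_sparse_network(n_cortex=40, n_groups=300, group_size=4, seed=2)
        stressed = apply_stress(net, n_removed=3, seed=3)
        rng = np.random.default_rng(4)
        r_full, r_str = [], []
        for _ in range(200):
            x = rng.standard_normal(40)
            drive = np.abs(x[net.groups]).mean(axis=1)
            r_full.append(np.corrcoef(drive, compute_fsi(net, x))[0, 1])
            r_str.append(np.corrcoef(drive, compute_fsi(stressed, x))[0, 1])
        assert np.mean(r_full) > np.mean(r_str)

    def test_must_keep_a_connection(self):
        net = build_sparse_network(n_cortex=20, n_groups=5, group_size=4, seed=0)
        with pytest.raises(InvalidParameterError):
            apply_stress(net, n_removed=4)


class TestBhattacharyya:
    def test_identical_samples_zero(self):
        a = np.array([0.1, 0.5, 0.9, 0.2])
        assert bhattacharyya_distance(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_equal_variance_closed_form(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, 200_000)
        b = rng.normal(2.0, 1.0, 200_000)
        # (mu_a - mu_b)^2 / (8 sigma^2) = 0.5 for unit variance, means 0 and 2
        assert bhattacharyya_distance(a, b) == pytest.approx(0.5, abs=0.02)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 50), rng.normal(1, 2, 80)
        assert bhattacharyya_distance(a, b) == pytest.approx(
            bhattacharyya_distance(b, a)
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            bhattacharyya_distance([1.0, 1.0, 1.0], [0.0, 1.0])

    def test_histogram_estimator_orders_like_gaussian(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 3000)
        near = rng.normal(0.5, 1, 3000)
        far = rng.normal(3.0, 1, 3000)
        for method in ("gaussian", "histogram"):
            assert bhattacharyya_distance(a, far, method=method) > bhattacharyya_distance(
                a, near, method=method
            )

    def test_separation_grows_with_signal_amplitude(self):
        """Reward- vs cost-dimension SPN distributions separate more as the
        cortical signal strengthens (averaged over simulations)."""
        net = build_sparse_network(n_cortex=30, n_groups=150, group_size=4, q=2, seed=3)
        x_train, loadings = generate_cortical_activity(
            1500, 30, amplitudes=(2.0, 2.0), noise_sd=0.3, seed=4
        )
        net = learn_network_weights(net, x_train, epochs=8, seed=5)
        rng = np.random.default_rng(6)
        amps = [0.5, 1.0, 2.0, 4.0, 8.0]
        means = []
        for amp in amps:
            dists = []
            for _ in range(100):
                x = amp * loadings[:, 0] + 0.3 * rng.standard_normal(30)
                acts = compute_sparse_activities(net, x)["sspn"]
                dists.append(bhattacharyya_distance(acts[:, 0], acts[:, 1]))
            means.append(np.mean(dists))
        assert all(a < b for a, b in zip(means, means[1:]))
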