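import math

import numpy as np
import pytest
from scipy.special import gammaln

from glmpp import (
    EventDataset,
    NetworkModel,
    Nonlinearity,
    bin_events,
    intensity,
    linear_drive,
    neg_log_likelihood,
    sample,
)


def straight_loop_nll(model, binned):
    """Independent likelihood oracle: explicit per-bin, per-channel loops
    summing kernel values over all earlier events, no convolutions."""
    dt = binned.bin_width
    C, T = binned.counts.shape
    total = 0.0
    for j in range(C):
        for t in range(T):
            u = model.base_rates[j]
            for i in range(C):
                kernel = model.kernel(i, j)
                for s in range(max(0, t - len(model.basis.lag_grid)), t):
                    if binned.counts[i, s]:
                        lag = (t - s) * dt
                        u += binned.counts[i, s] * float(kernel.evaluate([lag])[0])
            lam = float(model.nonlinearity(u))
            n = binned.counts[j, t]
            total += lam * dt - n * math.log(lam * dt) + float(gammaln(n + 1.0))
    return total


def random_model(rng, basis, C=3, scale=1.0):
    channels = [f"c{k}" for k in range(C)]
    W = rng.normal(0, 0.3, size=(C, C, basis.n_basis))
    b = rng.normal(0, 0.5, size=C)
    return NetworkModel(channels, b, W, basis, Nonlinearity("softplus", scale))


class TestNonlinearity:
    def test_softplus_at_zero_is_scaled_log2(self):
        assert Nonlinearity("softplus", 1.0)(0.0) == pytest.approx(math.log(2))
        assert Nonlinearity("softplus", 0.1)(0.0) == pytest.approx(0.1 * math.log(2))

    def test_exponential_at_zero_is_one(self):
        assert Nonlinearity("exponential")(0.0) == pytest.approx(1.0)

    def test_soft_threshold_stays_positive_and_finite(self):
        lam = Nonlinearity("softplus", 1.0)(-50.0)
        assert 0.0 < lam < 1e-20

    def test_monotonic_nonnegative(self):
        x = np.linspace(-30, 30, 301)
        for nl in [Nonlinearity("softplus", 0.1), Nonlinearity("exponential")]:
            y = nl(x)
            assert np.all(np.diff(y) >= 0) and np.all(y >= 0)

    def test_inverse_consistency(self):
        for nl in [Nonlinearity("softplus", 0.1), Nonlinearity("exponential")]:
            for r in [0.01, 0.2, 3.0]:
                assert float(nl(nl.inverse(r))) == pytest.approx(r, rel=1e-9)


class TestLinearDrive:
    def test_no_events_gives_base_drive(self, small_basis):
        m = NetworkModel.homogeneous(["a", "b"], 0.5, small_basis, scale=1.0)
        ds = EventDataset(["a", "b"], {"a": np.array([]), "b": np.array([])}, 5.0)
        u = linear_drive(m, bin_events(ds, small_basis.bin_width))
        np.testing.assert_allclose(u, m.base_rates[:, None] * np.ones_like(u))

    def test_single_event_injects_kernel_with_one_bin_delay(self, small_basis, rng):
        m = random_model(rng, small_basis, C=2)
        dt = small_basis.bin_width
        ds = EventDataset(["c0", "c1"], {"c0": np.array([dt / 2]), "c1": np.array([])}, 2.0)
        u = linear_drive(m, bin_events(ds, dt))
        # own bin untouched
        np.testing.assert_allclose(u[:, 0], m.base_rates)
        for k in [1, 5, 20]:
            for j in range(2):
                expected = m.base_rates[j] + float(m.kernel(0, j).evaluate([k * dt])[0])
                assert u[j, k] == pytest.approx(expected, abs=1e-10)

    def test_superposition_of_events(self, small_basis, rng):
        m = random_model(rng, small_basis, C=2)
        dt = small_basis.bin_width
        t1, t2 = 0.105, 0.255
        base = EventDataset(["c0", "c1"], {"c0": np.array([]), "c1": np.array([])}, 2.0)
        one = EventDataset(["c0", "c1"], {"c0": np.array([t1]), "c1": np.array([])}, 2.0)
        two = EventDataset(["c0", "c1"], {"c0": np.array([t2]), "c1": np.array([])}, 2.0)
        both = EventDataset(["c0", "c1"], {"c0": np.array([t1, t2]), "c1": np.array([])}, 2.0)
        u0 = linear_drive(m, bin_events(base, dt))
        u_both = linear_drive(m, bin_events(both, dt))
        u_sum = (linear_drive(m, bin_events(one, dt))
                 + linear_drive(m, bin_events(two, dt)) - u0)
        np.testing.assert_allclose(u_both, u_sum, atol=1e-9)

    def test_causality_future_events_cannot_change_past(self, small_basis, rng):
        m = random_model(rng, small_basis, C=2)
        dt = small_basis.bin_width
        full = EventDataset(["c0", "c1"],
                            {"c0": np.array([0.105, 1.505]), "c1": np.array([1.2])}, 2.0)
        trunc = EventDataset(["c0", "c1"],
                             {"c0": np.array([0.105]), "c1": np.array([])}, 2.0)
        lam_full = intensity(m, bin_events(full, dt))
        lam_trunc = intensity(m, bin_events(trunc, dt))
        cut = int(1.1 / dt)  # strictly before the first removed event's bin
        np.testing.assert_allclose(lam_full[:, :cut + 1], lam_trunc[:, :cut + 1])

    def test_link_nonlinearity_pairing_enforced(self, small_basis):
        with pytest.raises(ValueError, match="requires"):
            NetworkModel(["a"], np.zeros(1), np.zeros((1, 1, small_basis.n_basis)),
                         small_basis, Nonlinearity("softplus"), "multiplicative")


class TestNegLogLikelihood:
    def test_homogeneous_no_events_equals_rate_times_T(self, small_basis):
        m = NetworkModel.homogeneous(["a"], 0.7, small_basis, scale=1.0)
        ds = EventDataset(["a"], {"a": np.array([])}, 50.0)
        nll = neg_log_likelihood(m, bin_events(ds, small_basis.bin_width))
        assert nll == pytest.approx(0.7 * 50.0, rel=1e-9)

    def test_matches_straight_loop_oracle(self, small_basis, rng):
        m = random_model(rng, small_basis, C=3)
        data_model = NetworkModel.homogeneous(["c0", "c1", "c2"], 1.0, small_basis, scale=1.0)
        ds = sample(data_model, 10.0, seed=7)
        be = bin_events(ds, small_basis.bin_width)
        ours = neg_log_likelihood(m, be, penalty=0.0)
        oracle = straight_loop_nll(m, be)
        assert ours == pytest.approx(oracle, rel=1e-8)

    def test_gradient_matches_finite_differences(self, small_basis, rng):
        m = random_model(rng, small_basis, C=3)
        data_model = NetworkModel.homogeneous(["c0", "c1", "c2"], 1.0, small_basis, scale=1.0)
        ds = sample(data_model, 10.0, seed=8)
        be = bin_events(ds, small_basis.bin_width)
        f, (gb, gw) = neg_log_likelihood(m, be, penalty=0.3, with_grad=True)
        eps = 1e-6
        for j in range(3):
            b2 = m.base_rates.copy()
            b2[j] += eps
            m2 = NetworkModel(m.channels, b2, m.weights, small_basis, m.nonlinearity)
            fd = (neg_log_likelihood(m2, be, penalty=0.3) - f) / eps
            assert fd == pytest.approx(gb[j], rel=1e-4, abs=1e-7)
        for _ in range(8):
            i, j, b = (int(rng.integers(3)), int(rng.integers(3)),
                       int(rng.integers(small_basis.n_basis)))
            w2 = m.weights.copy()
            w2[i, j, b] += eps
            m2 = NetworkModel(m.channels, m.base_rates, w2, small_basis, m.nonlinearity)
            fd = (neg_log_likelihood(m2, be, penalty=0.3) - f) / eps
            assert fd == pytest.approx(gw[i, j, b], rel=1e-4, abs=1e-7)

    def test_negative_penalty_rejected(self, small_basis):
        m = NetworkModel.homogeneous(["a"], 0.5, small_basis)
        ds = EventDataset(["a"], {"a": np.array([])}, 5.0)
        with pytest.raises(ValueError):
            neg_log_likelihood(m, bin_events(ds, small_basis.bin_width), penalty=-1.0)

    def test_true_model_beats_perturbed_in_expectation(self, small_basis, rng):
        truth = random_model(rng, small_basis, C=2)
        perturbed = NetworkModel(truth.channels, truth.base_rates + 0.8,
                                 truth.weights * 0.2, small_basis, truth.nonlinearity)
        diffs = []
        for seed in range(20):
            ds = sample(truth, 60.0, seed=seed)
            be = bin_events(ds, small_basis.bin_width)
            diffs.append(neg_log_likelihood(perturbed, be) - neg_log_likelihood(truth, be))
        assert np.mean(diffs) > 0


class TestSerialization:
    def test_json_roundtrip_exact(self, small_basis, rng, tmp_path):
        m = random_model(rng, small_basis, C=3)
        p = tmp_path / "model.json"
        m.to_json(p)
        back = NetworkModel.from_json(p)
        assert back.channels == m.channels
        assert back.link_mode == m.link_mode
        np.testing.assert_array_equal(back.base_rates, m.base_rates)
        np.testing.assert_array_equal(back.weights, m.weights)
        assert back.nonlinearity == m.nonlinearity
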