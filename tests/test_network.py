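"""Recurrent network: encoders, dynamics, BPTT gradients, training invariants."""

import numpy as np
import pytest

from nemataxis.network import (
    DEFAULT_NEURONS,
    NetworkParams,
    NetworkTopology,
    SensoryParams,
    TrainingConfig,
    asel_input,
    aser_input,
    bptt_gradients,
    default_topology,
    evaluate_outputs,
    forward_trace,
    init_params,
    loss,
    network_step,
    normalize_teacher,
    train,
)


def tiny_topology():
    """3 neurons, 2 inputs, with chem, gap and derivative paths exercised."""
    return NetworkTopology(
        neuron_names=("A", "B", "C"),
        input_names=("x", "y"),
        chem_edges=(("x", "A"), ("y", "B"), ("A", "B"), ("B", "C"), ("C", "A")),
        gap_edges=(("A", "B"), ("B", "C")),
        output_assignment={"out": ("C",)},
    )


def tiny_params(rng, transmit="potential"):
    topo = tiny_topology()
    p = init_params(topo, rng, T_s=0.1, transmit=transmit)
    # nonzero derivative weights and asymmetric tau to exercise every term
    p.Wd = np.where(topo.chem_mask(), rng.normal(0.0, 0.2, p.Wd.shape), 0.0)
    p.tau = np.array([0.5, 1.5, 1.0])
    return topo, p


class TestEncoders:
    def test_asel_off_for_nonincreasing(self):
        p = SensoryParams()
        assert asel_input(p, 0.0) == 0.0
        assert asel_input(p, -0.5) == 0.0

    def test_asel_log_identity(self):
        p = SensoryParams(a_L=1.0, b_L=1.0)
        assert asel_input(p, np.e - 1) == pytest.approx(1.0)

    def test_aser_continuous_at_zero(self):
        p = SensoryParams()
        eps = 1e-12
        assert aser_input(p, 0.0) == 0.0
        assert abs(aser_input(p, eps)) < 1e-6
        assert abs(aser_input(p, -eps)) < 1e-6

    def test_aser_off_branch_log_identity(self):
        p = SensoryParams(a_R_neg=1.0, b_R_neg=-1.0)
        assert aser_input(p, -(np.e - 1)) == pytest.approx(1.0)

    def test_off_limb_dominates_iff_slope_larger(self):
        p = SensoryParams()
        d = 2e-6  # small signal: responses ~ a*b*dcdt
        stronger_off = abs(p.a_R_neg * p.b_R_neg) > abs(p.a_R_pos * p.b_R_pos)
        assert stronger_off == (abs(aser_input(p, -d)) > abs(aser_input(p, d)))

    def test_invalid_branch_signs_rejected(self):
        with pytest.raises(ValueError):
            SensoryParams(b_R_neg=1.0)


class TestDynamics:
    def test_rest_state_is_half_activation(self):
        topo = tiny_topology()
        p = init_params(topo, np.random.default_rng(0))
        p.W[:] = 0.0
        p.S[:] = 0.0
        u, U, _ = network_step(topo, p, np.zeros(3), np.zeros(2))
        assert U == pytest.approx(np.full(3, 0.5))
        assert u == pytest.approx(np.zeros(3))

    def test_gap_term_vanishes_at_equal_currents(self):
        topo = tiny_topology()
        p = init_params(topo, np.random.default_rng(0))
        p.W[:] = 0.0
        p.Wd[:] = 0.0
        p.tau[:] = 0.0
        u0 = np.full(3, 0.7)
        # with only gap coupling and equal currents, u is unchanged
        u1, _, _ = network_step(topo, p, u0, np.zeros(2))
        assert u1 == pytest.approx(u0)

    def test_single_neuron_fixed_point(self):
        topo = NetworkTopology(("A",), ("x",), (("x", "A"),), (), output_assignment={"out": ("A",)})
        p = init_params(topo, np.random.default_rng(0), T_s=0.1)
        w, tau, z = 0.8, 2.0, 1.5
        p.W[0, 1] = w
        p.tau[:] = tau
        u = np.zeros(1)
        for _ in range(2000):
            u, _, _ = network_step(topo, p, u, np.array([z]))
        assert u[0] == pytest.approx(w * z / tau, rel=1e-6)

    def test_rollout_composes(self):
        topo, p = tiny_params(np.random.default_rng(1))
        rng = np.random.default_rng(2)
        series = rng.normal(size=(40, 2))
        full = forward_trace(topo, p, series)
        # continuing a rollout step-by-step reproduces the same potentials
        u = np.zeros(3)
        z_prev = None
        for k in range(40):
            u, U, z_prev = network_step(topo, p, u, series[k], z_prev)
            np.testing.assert_allclose(U, full[k], atol=1e-12)

    def test_empty_series(self):
        topo, p = tiny_params(np.random.default_rng(1))
        assert forward_trace(topo, p, np.zeros((0, 2))).shape == (0, 3)

    def test_potentials_bounded(self):
        topo, p = tiny_params(np.random.default_rng(3))
        series = np.random.default_rng(4).normal(size=(200, 2)) * 3
        U = forward_trace(topo, p, series)
        assert np.all(U > 0) and np.all(U < 1)

    def test_leak_factor_follows_sampling_time(self):
        topo = NetworkTopology(("A",), ("x",), (("x", "A"),), (), output_assignment={"out": ("A",)})
        for T_s, tau in ((0.1, 1.0), (0.2, 1.0), (0.1, 3.0)):
            p = init_params(topo, np.random.default_rng(0), T_s=T_s)
            p.W[0, 1] = 0.0
            p.tau[:] = tau
            u = np.array([1.0])
            u1, _, _ = network_step(topo, p, u, np.zeros(1))
            assert u1[0] == pytest.approx(1.0 / (1.0 + T_s * tau))


class TestTeacherAndLoss:
    def test_normalize_linear_map(self):
        np.testing.assert_allclose(normalize_teacher([0.0, 5.0, 10.0]), [0.0, 0.5, 1.0])

    def test_normalize_affine_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        np.testing.assert_allclose(normalize_teacher(3.0 * x + 7.0), normalize_teacher(x), atol=1e-12)

    def test_normalize_negation_reflects(self):
        x = np.array([1.0, 2.0, 4.0])
        np.testing.assert_allclose(normalize_teacher(-x), 1.0 - normalize_teacher(x))

    def test_constant_teacher_rejected(self):
        with pytest.raises(ValueError):
            normalize_teacher(np.full(10, 3.3))

    def test_loss_values(self):
        U = np.array([[0.7]])
        d = np.array([[0.2]])
        assert loss(U, d, np.array([1.0])) == pytest.approx(0.125)
        assert loss(U, d, np.array([0.0])) == 0.0
        assert loss(d, d, np.array([1.0])) == 0.0


class TestGradients:
    @pytest.mark.parametrize("transmit", ["potential", "current"])
    def test_bptt_matches_finite_differences(self, transmit):
        """Every partial (chem, derivative, gap, tau) against central differences."""
        rng = np.random.default_rng(10)
        topo, p = tiny_params(rng, transmit=transmit)
        T = 5
        inputs = rng.normal(size=(T, 2))
        teachers = rng.uniform(0.2, 0.8, size=(T, 3))
        mu = topo.output_mask()

        def H(params):
            U = forward_trace(topo, params, inputs)
            return loss(U, teachers, mu)

        grads = bptt_gradients(topo, p, inputs, teachers)
        h = 1e-6
        cmask = topo.chem_mask()
        for name, mask in (("W", cmask), ("Wd", cmask)):
            g = grads[name]
            for i, j in zip(*np.where(mask)):
                q = p.copy()
                getattr(q, name)[i, j] += h
                hi = H(q)
                getattr(q, name)[i, j] -= 2 * h
                lo = H(q)
                fd = (hi - lo) / (2 * h)
                assert g[i, j] == pytest.approx(fd, rel=1e-5, abs=1e-10), (name, i, j)
        # gap: independent directional partials, checked one triangle entry at a time
        gmask = topo.gap_mask()
        for i, j in zip(*np.where(gmask)):
            q = p.copy()
            q.S = q.S.copy()
            q.S[i, j] += h  # breaks symmetry on purpose: directional partial
            object.__setattr__(q, "S", q.S)
            hi = _loss_unchecked(topo, q, inputs, teachers, mu)
            q.S[i, j] -= 2 * h
            lo = _loss_unchecked(topo, q, inputs, teachers, mu)
            fd = (hi - lo) / (2 * h)
            assert grads["S_dir"][i, j] == pytest.approx(fd, rel=1e-5, abs=1e-10), (i, j)
        for i in range(3):
            q = p.copy()
            q.tau[i] += h
            hi = H(q)
            q.tau[i] -= 2 * h
            lo = H(q)
            fd = (hi - lo) / (2 * h)
            assert grads["tau"][i] == pytest.approx(fd, rel=1e-5, abs=1e-10), i

    def test_shared_gap_gradient_is_sum_of_directional_partials(self):
        rng = np.random.default_rng(11)
        topo, p = tiny_params(rng)
        inputs = rng.normal(size=(5, 2))
        teachers = rng.uniform(0.2, 0.8, size=(5, 3))
        grads = bptt_gradients(topo, p, inputs, teachers)
        h = 1e-6
        mu = topo.output_mask()
        for (i, j) in ((0, 1), (1, 2)):
            q = p.copy()
            q.S[i, j] += h
            q.S[j, i] += h  # shared conductance moves both directions
            hi = _loss_unchecked(topo, q, inputs, teachers, mu)
            q.S[i, j] -= 2 * h
            q.S[j, i] -= 2 * h
            lo = _loss_unchecked(topo, q, inputs, teachers, mu)
            fd = (hi - lo) / (2 * h)
            assert grads["S_shared"][i, j] == pytest.approx(fd, rel=1e-5)

    def test_zero_mask_zero_gradients(self):
        rng = np.random.default_rng(12)
        topo, p = tiny_params(rng)
        topo = NetworkTopology(
            topo.neuron_names, topo.input_names, topo.chem_edges, topo.gap_edges,
            output_assignment={},
        )
        inputs = rng.normal(size=(5, 2))
        teachers = rng.uniform(size=(5, 3))
        grads = bptt_gradients(topo, p, inputs, teachers)
        for key in ("W", "Wd", "S_dir", "tau"):
            assert np.all(grads[key] == 0.0)


def _loss_unchecked(topo, params, inputs, teachers, mu):
    """Loss via the raw batched forward (bypasses the symmetry validator)."""
    from nemataxis.network import _forward_batched, _sigmoid

    u, _, _ = _forward_batched(
        params.W[None], params.Wd[None], params.S[None], params.tau[None],
        params.T_s, np.asarray(inputs)[None], params.transmit,
    )
    U = _sigmoid(u[1:, 0, :])
    return loss(U, teachers, mu)


class TestTraining:
    def _dataset(self, rng, topo, T=60):
        inputs = rng.normal(size=(T, 2))
        teachers = np.zeros((T, topo.n))
        teachers[:, 2] = normalize_teacher(np.cumsum(inputs[:, 0]))
        return {"inputs": inputs, "teachers": teachers, "times": np.arange(T) * 0.1}

    def test_zero_learning_rates_keep_parameters(self):
        rng = np.random.default_rng(20)
        topo, p = tiny_params(rng)
        ds = self._dataset(rng, topo)
        cfg = TrainingConfig(eta_w=0.0, eta_g=0.0, eta_tau=0.0, epochs=5,
                             train_window=(0.0, 3.0), validation_window=(3.0, 6.0))
        trained, hist = train(topo, p, [ds], cfg)
        np.testing.assert_array_equal(trained[0].W, p.W)
        np.testing.assert_array_equal(trained[0].S, p.S)
        assert np.ptp(hist["train"]) == 0.0

    def test_invariants_preserved_and_loss_decreases(self):
        rng = np.random.default_rng(21)
        topo, p = tiny_params(rng)
        ds = self._dataset(rng, topo)
        cfg = TrainingConfig(eta_w=0.05, eta_g=0.05, eta_tau=0.05, epochs=200,
                             train_window=(0.0, 3.0), validation_window=(3.0, 6.0))
        trained, hist = train(topo, p, [ds], cfg)
        q = trained[0]
        np.testing.assert_array_equal(q.S, q.S.T)
        assert np.all(q.S[~topo.gap_mask()] == 0.0)
        assert np.all(q.tau >= 0.0)
        assert hist["train"][-1, 0] < hist["train"][0, 0]

    def test_realizable_toy_problem_reaches_low_loss(self):
        # 2-neuron chain; teacher generated by a network of the same form
        rng = np.random.default_rng(22)
        topo = NetworkTopology(("A", "B"), ("x",), (("x", "A"), ("A", "B")), (),
                               output_assignment={"out": ("B",)})
        gen = init_params(topo, rng, T_s=0.1)
        gen.W[0, 2] = 1.2
        gen.W[1, 0] = 0.9
        gen.tau[:] = 1.0
        inputs = rng.normal(size=(80, 1))
        teachers = forward_trace(topo, gen, inputs)
        ds = {"inputs": inputs, "teachers": teachers, "times": np.arange(80) * 0.1}
        p0 = init_params(topo, np.random.default_rng(99), T_s=0.1)
        cfg = TrainingConfig(eta_w=0.5, eta_g=0.0, eta_tau=0.1, epochs=800,
                             train_window=(0.0, 8.0), validation_window=(8.0, 9.0))
        trained, hist = train(topo, p0, [ds], cfg)
        assert hist["train"][-1, 0] < 0.1 * hist["train"][0, 0]


class TestEvaluation:
    def test_affine_transform_perfect_correlation(self):
        topo = tiny_topology()
        rng = np.random.default_rng(30)
        d = rng.normal(size=100)
        U = np.zeros((100, 3))
        U[:, 2] = 2.0 * d + 1.0
        teachers = np.zeros((100, 3))
        teachers[:, 2] = d
        res = evaluate_outputs(U, teachers, topo)
        assert res["out"]["C"][0] == pytest.approx(1.0)

    def test_negated_teacher_anticorrelates(self):
        topo = tiny_topology()
        d = np.sin(np.arange(50))
        U = np.zeros((50, 3))
        U[:, 2] = -d
        teachers = np.zeros((50, 3))
        teachers[:, 2] = d
        assert evaluate_outputs(U, teachers, topo)["out"]["C"][0] == pytest.approx(-1.0)

    def test_independent_noise_uncorrelated(self):
        topo = tiny_topology()
        rng = np.random.default_rng(31)
        U = np.zeros((1000, 3))
        U[:, 2] = rng.normal(size=1000)
        teachers = np.zeros((1000, 3))
        teachers[:, 2] = rng.normal(size=1000)
        r, _ = evaluate_outputs(U, teachers, topo)["out"]["C"]
        assert abs(r) < 0.1

    def test_zero_variance_rejected(self):
        topo = tiny_topology()
        U = np.zeros((10, 3))
        teachers = np.zeros((10, 3))
        teachers[:, 2] = np.arange(10)
        with pytest.raises(ValueError):
            evaluate_outputs(U, teachers, topo)


class TestDefaultTopology:
    def test_loads_and_validates(self):
        topo = default_topology()
        assert topo.neuron_names == DEFAULT_NEURONS
        assert topo.n == 22 and topo.m == 3
        gmask = topo.gap_mask()
        np.testing.assert_array_equal(gmask, gmask.T)
        assert not np.any(np.diag(gmask))
        # every output neuron is reachable (has at least one incoming edge)
        cmask = topo.chem_mask()
        mu = topo.output_mask()
        assert np.all((cmask.sum(axis=1) + gmask.sum(axis=1))[mu > 0] > 0)
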