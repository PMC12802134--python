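"""The rule network: layer semantics, priors, gradients, logic oracle."""

import itertools

import numpy as np
import pytest
from scipy.special import expit

from mmrules.containers import LogNormalPrior
from mmrules.model import (
    AnnealingState,
    HyperParams,
    ModelData,
    ModelParams,
    RuleNetwork,
    Temperatures,
    aggregate_metabolites,
    aggregate_taxa,
    binary_concrete_log_pdf,
    detector_activation,
    predict,
    rule_activation,
    selector_value,
    soft_inclusion,
)


def _random_instance(seed=0, S=7, NM=6, DM=3, NT=8, DT=2, K=2, J=2, L=2):
    rng = np.random.default_rng(seed)
    hp = HyperParams(K=K, J=J, L=L)
    data = ModelData(
        X_M=rng.normal(size=(S, NM)),
        X_T=np.abs(rng.dirichlet(np.ones(NT), size=S)),
        E_M=rng.normal(size=(NM, DM)),
        E_T=rng.normal(size=(NT, DT)),
        y=rng.integers(0, 2, size=S),
        prior_M=LogNormalPrior(0.3, 0.5),
        prior_T=LogNormalPrior(-0.2, 0.8),
    )
    params = ModelParams(
        centers_M=rng.normal(size=(K, J, DM)),
        log_radii_M=rng.normal(size=(K, J)) * 0.3,
        thresholds_M=rng.normal(size=(K, J)) * 0.5,
        centers_T=rng.normal(size=(K, L, DT)),
        log_radii_T=rng.normal(size=(K, L)) * 0.3,
        thresholds_T=rng.uniform(0.2, 0.8, size=(K, L)),
        detector_logits=rng.normal(size=(K, J + L)),
        rule_logits=rng.normal(size=K),
        beta=rng.normal(size=K),
        beta0=np.array(0.3),
    )
    return data, hp, params


MODERATE = Temperatures(0.3, 0.7, 0.4, 0.6, 0.8)


class TestLayerPrimitives:
    def test_soft_inclusion_analytic_points(self):
        coords = np.array([[1.0, 0.0], [2.0, 0.0]])
        # feature at distance exactly = radius -> 0.5
        u = soft_inclusion(np.zeros(2), 1.0, coords, tau_u=0.25)
        assert u[0] == pytest.approx(0.5)
        # radius - distance = tau -> sigmoid(1)
        u2 = soft_inclusion(np.zeros(2), 2.25, coords, tau_u=0.25)
        assert u2[1] == pytest.approx(expit(1.0))

    def test_soft_inclusion_hard_limit(self):
        coords = np.array([[0.5, 0.0], [3.0, 0.0]])
        u = soft_inclusion(np.zeros(2), 1.0, coords, tau_u=1e-6)
        np.testing.assert_allclose(u, [1.0, 0.0], atol=1e-12)

    def test_aggregate_metabolites_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        u, X = rng.uniform(size=9), rng.normal(size=(5, 9))
        expected = np.array(
            [sum(u[i] * X[s, i] for i in range(9)) / u.sum() for s in range(5)]
        )
        np.testing.assert_allclose(aggregate_metabolites(u, X), expected, atol=1e-12)

    def test_aggregate_metabolites_one_hot_selects_column(self):
        X = np.arange(12.0).reshape(3, 4)
        u = np.array([0.0, 0.0, 1.0, 0.0])
        np.testing.assert_allclose(aggregate_metabolites(u, X), X[:, 2], atol=1e-9)

    def test_aggregate_taxa_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        u = rng.uniform(size=6)
        X = rng.dirichlet(np.ones(6), size=4)
        expected = np.array([sum(u[i] * X[s, i] for i in range(6)) for s in range(4)])
        np.testing.assert_allclose(aggregate_taxa(u, X), expected, atol=1e-12)

    def test_aggregate_taxa_all_ones_gives_closure(self):
        X = np.random.default_rng(3).dirichlet(np.ones(5), size=4)
        np.testing.assert_allclose(aggregate_taxa(np.ones(5), X), 1.0, atol=1e-12)

    def test_detector_activation_analytic_points(self):
        assert detector_activation(np.array([2.0]), 2.0, 0.5)[0] == pytest.approx(0.5)
        assert detector_activation(np.array([1.0]), 0.0, 0.5)[0] == pytest.approx(
            expit(2.0)
        )

    def test_detector_activation_monotone_in_aggregate(self):
        a = np.linspace(-3, 3, 50)
        g = detector_activation(a, 0.3, 0.7)
        assert np.all(np.diff(g) > 0)

    def test_rule_activation_empty_conjunction_is_true(self):
        assert rule_activation(np.zeros(4), np.zeros(4)) == pytest.approx(1.0)

    def test_rule_activation_and_with_false_is_false(self):
        assert rule_activation(np.array([1.0, 0.0]), np.array([1.0, 1.0])) == 0.0

    def test_rule_activation_matches_boolean_oracle_exhaustively(self):
        """All 2^10 binary (g, z) pairs over 5 detectors equal hard AND."""
        for g_bits in itertools.product([0, 1], repeat=5):
            g = np.array(g_bits, dtype=float)
            for z_bits in itertools.product([0, 1], repeat=5):
                z = np.array(z_bits, dtype=float)
                expected = all(g_bits[i] for i in range(5) if z_bits[i])
                assert rule_activation(g, z) == float(expected)

    def test_predict_bias_only(self):
        p = predict(np.ones((3, 2)), np.zeros(2), np.ones(2), 0.0)
        np.testing.assert_allclose(p, 0.5)

    def test_predict_single_rule_odds_factor(self):
        # one active rule with weight ln(24): odds of case x24
        p = predict(np.ones((1, 1)), np.ones(1), np.array([np.log(24.0)]), 0.0)
        odds = p[0] / (1 - p[0])
        assert odds == pytest.approx(24.0, rel=1e-9)

    def test_predict_logit_additivity(self):
        rng = np.random.default_rng(4)
        r = rng.uniform(size=(6, 3))
        q, beta, b0 = rng.uniform(size=3), rng.normal(size=3), 0.7
        p = predict(r, q, beta, b0)
        np.testing.assert_allclose(np.log(p / (1 - p)), r @ (q * beta) + b0, atol=1e-9)

    def test_selector_value_points(self):
        assert selector_value(np.array(0.0), 0.3) == pytest.approx(0.5)
        assert selector_value(np.array(0.25), 0.25) == pytest.approx(expit(1.0))
        assert selector_value(np.array(1.0), 0.1) == pytest.approx(expit(10.0))


class TestBinaryConcrete:
    def test_density_matches_independent_transcription(self):
        """Literal transcription of the Concrete pdf, coded separately."""

        def literal(x, alpha, lam):
            num = lam * alpha * x ** (-lam - 1) * (1 - x) ** (-lam - 1)
            den = (alpha * x ** (-lam) + (1 - x) ** (-lam)) ** 2
            return np.log(num / den)

        for x in (0.2, 0.5, 0.9):
            for alpha, lam in ((0.1, 0.5), (1.0, 1.0), (0.25, 0.2)):
                assert binary_concrete_log_pdf(
                    np.array(x), alpha, lam
                ) == pytest.approx(literal(x, alpha, lam), rel=1e-9)

    def test_density_integrates_to_one(self):
        from scipy.integrate import quad

        val, _ = quad(
            lambda x: np.exp(binary_concrete_log_pdf(np.array(x), 0.1, 0.7)),
            1e-6,
            1 - 1e-6,
        )
        assert val == pytest.approx(1.0, abs=1e-3)


class TestPosterior:
    def test_center_prior_monotone_in_variance(self):
        # less shrinkage: for centers far from 0 relative to the prior sd,
        # doubling the variance raises the prior density
        data, hp, params = _random_instance()
        params = params.copy()
        params.centers_M = params.centers_M * 0 + 300.0
        params.centers_T = params.centers_T * 0 + 300.0
        loose = RuleNetwork(data, HyperParams(K=2, J=2, L=2, center_prior_var=2e4))
        tight = RuleNetwork(data, hp)
        assert loose.log_prior(params, MODERATE) > tight.log_prior(params, MODERATE)

    def test_threshold_gradient_zero_inside_uniform_support(self):
        data, hp, params = _random_instance()
        net = RuleNetwork(data, hp)
        base = net.log_prior(params, MODERATE)
        shifted = params.copy()
        shifted.thresholds_M += 0.01
        assert net.log_prior(shifted, MODERATE) == pytest.approx(base)

    def test_perfect_predictions_drive_likelihood_to_zero(self):
        data, hp, params = _random_instance()
        net = RuleNetwork(data, hp)
        # shape a prediction exactly matching labels via the bias limit
        params2 = params.copy()
        params2.rule_logits = np.full(hp.K, -30.0)  # all rules off
        fwd = net.forward(params2, MODERATE)
        nll_terms = np.logaddexp(0.0, fwd["o"]) - data.y * fwd["o"]
        # with rules off, o = beta0: NLL is the Bernoulli entropy bound
        assert np.all(nll_terms > 0)

    def test_bias_line_search_moves_loss_toward_empirical_log_odds(self):
        data, hp, params = _random_instance(seed=5)
        net = RuleNetwork(data, hp)
        params.rule_logits = np.full(hp.K, -30.0)  # rules off: o = beta0
        ybar = data.y.mean()
        target = np.log(ybar / (1 - ybar))
        grid = np.linspace(-3, 3, 121)
        losses = []
        for b0 in grid:
            p2 = params.copy()
            p2.beta0 = np.array(b0)
            losses.append(net.negative_log_posterior(p2, MODERATE))
        best = grid[int(np.argmin(losses))]
        assert abs(best - target) < 0.1

    def test_gradient_matches_finite_differences(self):
        """The analytic backward pass agrees with central differences on
        every parameter of a random instance."""
        data, hp, params = _random_instance()
        net = RuleNetwork(data, hp)
        loss, grads = net.loss_and_grad(params, MODERATE)
        h = 1e-6
        for f in ModelParams.FIELDS:
            arr = getattr(params, f)
            g = np.atleast_1d(grads[f])
            it = np.nditer(np.atleast_1d(arr), flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                plus = params.copy()
                a = np.atleast_1d(getattr(plus, f))
                a[idx] += h
                setattr(plus, f, a.reshape(arr.shape) if arr.shape else a[0])
                minus = params.copy()
                b = np.atleast_1d(getattr(minus, f))
                b[idx] -= h
                setattr(minus, f, b.reshape(arr.shape) if arr.shape else b[0])
                fd = (
                    net.negative_log_posterior(plus, MODERATE)
                    - net.negative_log_posterior(minus, MODERATE)
                ) / (2 * h)
                assert abs(fd - g[idx]) / max(1.0, abs(fd)) < 1e-4, (f, idx)

    def test_outputs_within_ranges_for_random_params(self):
        for seed in range(3):
            data, hp, params = _random_instance(seed=seed)
            net = RuleNetwork(data, hp)
            fwd = net.forward(params, MODERATE)
            for key in ("u_M", "u_T", "g_M", "g_T", "z", "q", "m", "r", "p"):
                assert np.all(fwd[key] >= 0) and np.all(fwd[key] <= 1), key

    def test_prediction_permutation_equivariant_over_subjects(self):
        data, hp, params = _random_instance(seed=6)
        net = RuleNetwork(data, hp)
        p = net.predict_proba(params, MODERATE)
        perm = np.random.default_rng(0).permutation(data.n_subjects)
        data2 = ModelData(
            X_M=data.X_M[perm], X_T=data.X_T[perm], E_M=data.E_M, E_T=data.E_T,
            y=data.y[perm], prior_M=data.prior_M, prior_T=data.prior_T,
        )
        net2 = RuleNetwork(data2, hp)
        np.testing.assert_allclose(net2.predict_proba(params, MODERATE), p[perm])


class TestZeroTemperatureEquivalence:
    def test_network_equals_boolean_rule_evaluator(self):
        """At temperatures 1e-6 with saturated selectors, the network's
        thresholded prediction equals a hand-coded boolean evaluator."""
        rng = np.random.default_rng(11)
        hard = Temperatures(1e-6, 1e-6, 1e-6, 1e-6, 1e-6)
        for trial in range(10):
            data, hp, params = _random_instance(seed=100 + trial)
            # saturate selectors to +-30 logits (z, q in {0, 1})
            params.detector_logits = np.where(
                rng.random((hp.K, hp.J + hp.L)) < 0.5, -30.0, 30.0
            )
            params.rule_logits = np.where(rng.random(hp.K) < 0.5, -30.0, 30.0)
            params.beta = rng.normal(size=hp.K) * 3
            net = RuleNetwork(data, hp)
            p = net.predict_proba(params, hard)

            # boolean oracle, written independently of the network code
            z = (params.detector_logits > 0).astype(int)
            q = (params.rule_logits > 0).astype(int)
            expected = np.zeros(data.n_subjects)
            for s in range(data.n_subjects):
                logit = float(params.beta0)
                for k in range(hp.K):
                    if not q[k]:
                        continue
                    fires = True
                    for j in range(hp.J):
                        if not z[k, j]:
                            continue
                        dist = np.linalg.norm(
                            data.E_M - params.centers_M[k, j], axis=1
                        )
                        members = dist < np.exp(params.log_radii_M[k, j])
                        if members.any():
                            agg = data.X_M[s, members].sum() / members.sum()
                        else:
                            agg = 0.0  # epsilon-guarded mean of nothing
                        if not agg > params.thresholds_M[k, j]:
                            fires = False
                    for ell in range(hp.L):
                        if not z[k, hp.J + ell]:
                            continue
                        dist = np.linalg.norm(
                            data.E_T - params.centers_T[k, ell], axis=1
                        )
                        members = dist < np.exp(params.log_radii_T[k, ell])
                        agg = data.X_T[s, members].sum()
                        if not agg > params.thresholds_T[k, ell]:
                            fires = False
                    if fires:
                        logit += params.beta[k]
                expected[s] = 1.0 if logit > 0 else 0.0
            np.testing.assert_array_equal((p > 0.5).astype(float), expected)


class TestKernelAgreement:
    def test_compiled_kernel_matches_numpy_reference(self):
        """The numba likelihood kernel and the numpy backward pass agree on
        loss and every gradient."""
        from mmrules import _kernel

        if not _kernel.HAVE_NUMBA:
            return  # numpy path is then the only implementation
        data, hp, params = _random_instance(seed=21)
        net = RuleNetwork(data, hp)
        for hard in (False, True):
            l1, g1 = net._loss_and_grad_kernel(params, MODERATE, hard)
            l2, g2 = net._loss_and_grad_numpy(params, MODERATE, None, hard)
            assert l1 == pytest.approx(l2, rel=1e-9)
            for f in g1:
                np.testing.assert_allclose(
                    np.atleast_1d(g1[f]), np.atleast_1d(g2[f]),
                    rtol=1e-6, atol=1e-9,
                )


class TestAnnealing:
    def test_endpoints_and_plateau(self):
        ann = AnnealingState()
        t0 = ann.at(0, 1000)
        tend = ann.final(1000)
        assert t0.tau_z == pytest.approx(1.0)
        assert tend.tau_z == pytest.approx(0.1)
        assert t0.tau_u == pytest.approx(1e-2)
        assert tend.tau_u == pytest.approx(1e-3)
        # flat within the leading plateau
        assert ann.at(10, 1000).tau_z == pytest.approx(1.0)

    def test_monotone_decrease(self):
        ann = AnnealingState()
        taus = [ann.at(e, 500).tau_g_M for e in range(0, 500, 25)]
        assert all(a >= b for a, b in zip(taus, taus[1:]))
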