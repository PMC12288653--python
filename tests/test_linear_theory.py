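import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from softmode.grn_dynamics import LinearSystem
from softmode.linear_theory import (
    ControlGeometry,
    PerturbationEnsemble,
    SpectralModel,
    UncontrollableError,
    controlled_response,
    effective_rank,
    ensemble_effective_rank,
    expected_deviation,
    gap_benefit,
    linear_steady_state,
    mc_expected_deviation,
    optimal_geometry,
    uncontrolled_response,
)


def make_closed_loop_system(seed: int, n: int = 6):
    """Random stable symmetric system plus (s, a) giving a stable PI loop."""
    rng = np.random.default_rng(seed)
    while True:
        R = rng.standard_normal((n, n)) / np.sqrt(n)
        J = -(R @ R.T + 0.5 * np.eye(n))
        s = rng.standard_normal(n)
        s /= np.linalg.norm(s)
        a = s + 0.5 * rng.standard_normal(n)
        a /= np.linalg.norm(a)
        c_p, c_i = 1.0, 1.0
        aug = np.block(
            [[J - c_p * np.outer(a, s), -c_i * a[:, None]], [s[None, :], np.zeros((1, 1))]]
        )
        if np.all(np.linalg.eigvals(aug).real < -1e-6):
            return LinearSystem.from_jacobian(J), s, a, c_p, c_i


def integrate_pi_loop(system, s, a, c_p, c_i, delta_e, horizon_factor=40.0):
    n = system.n_dims
    aug = np.block(
        [[system.jacobian - c_p * np.outer(a, s), -c_i * a[:, None]],
         [s[None, :], np.zeros((1, 1))]]
    )
    slowest = np.max(np.linalg.eigvals(aug).real)
    t_end = horizon_factor / abs(slowest)

    def f(t, y):
        x, integ = y[:n], y[n]
        return np.concatenate(
            [system.jacobian @ x + delta_e - a * (c_p * (s @ x) + c_i * integ), [s @ x]]
        )

    sol = solve_ivp(f, (0, t_end), np.zeros(n + 1), rtol=1e-12, atol=1e-13)
    return sol.y[:n, -1]


class TestUncontrolledResponse:
    def test_isotropic(self):
        lin = LinearSystem.from_jacobian(-2.0 * np.eye(4))
        de = np.array([1.0, -2.0, 0.5, 0.0])
        np.testing.assert_allclose(uncontrolled_response(lin, de), de / 2.0)

    def test_slow_vs_fast_ratio(self):
        model = SpectralModel.create(5, gap=20.0)
        slow = uncontrolled_response(model, model.v0)
        fast = uncontrolled_response(model, model.basis[:, 1])
        assert np.linalg.norm(slow) / np.linalg.norm(fast) == pytest.approx(20.0)

    def test_zero_forcing(self):
        model = SpectralModel.create(4, gap=3.0)
        np.testing.assert_allclose(uncontrolled_response(model, np.zeros(4)), 0.0)


class TestEffectiveRank:
    def test_uniform_is_dimension(self):
        assert effective_rank(np.full(5, 0.2)) == pytest.approx(5.0)

    def test_rank_one(self):
        assert effective_rank([1.0, 0.0, 0.0]) == pytest.approx(1.0)

    def test_entropy_closed_form(self):
        assert effective_rank([0.5, 0.25, 0.25]) == pytest.approx(2 ** 1.5)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            effective_rank([1.2, -0.2])

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            effective_rank([0.5, 0.4])

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_bounds(self, raw):
        p = np.array(raw) / np.sum(raw)
        r = effective_rank(p)
        assert 1.0 - 1e-9 <= r <= len(p) + 1e-9


class TestEnsembleEffectiveRank:
    def test_collinear_samples(self):
        t = np.linspace(-1, 1, 50)
        samples = np.outer(t, np.array([1.0, 2.0, -1.0]))
        assert ensemble_effective_rank(samples) == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_gaussian(self):
        rng = np.random.default_rng(0)
        samples = rng.standard_normal((10_000, 10))
        assert ensemble_effective_rank(samples) == pytest.approx(10.0, rel=0.02)

    def test_isotropic_map_preserves_rank(self):
        rng = np.random.default_rng(1)
        de = rng.standard_normal((500, 6))
        dx = de / 3.0  # response through J = -3I
        assert ensemble_effective_rank(dx) == pytest.approx(
            ensemble_effective_rank(de), abs=1e-9
        )

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            ensemble_effective_rank(np.ones((1, 3)))

    def test_gap_reduces_rank(self):
        model = SpectralModel.create(10, gap=100.0, seed=2)
        rng = np.random.default_rng(3)
        de = rng.standard_normal((2000, 10))
        dx = de @ model.response_matrix().T
        assert ensemble_effective_rank(dx) < ensemble_effective_rank(de) / 2


class TestControlledResponse:
    def test_perfect_cancellation(self):
        model = SpectralModel.create(5, gap=10.0, seed=0)
        a = np.full(5, 0.2)
        a /= np.linalg.norm(a)
        de = 2.0 * a  # forcing parallel to a => rescaled forcing parallel to a-tilde
        s = a.copy()
        dx = controlled_response(model, (s, a), de)
        np.testing.assert_allclose(dx, np.zeros(5), atol=1e-10)

    def test_blind_when_sense_orthogonal(self):
        lin = LinearSystem.from_jacobian(-np.diag([1.0, 2.0, 4.0]))
        s = np.array([1.0, 0.0, 0.0])
        a = np.array([1.0, 0.0, 0.0])
        de = np.array([0.0, 1.0, 1.0])  # D de orthogonal to s
        dx = controlled_response(lin, (s, a), de)
        np.testing.assert_allclose(dx, uncontrolled_response(lin, de))

    def test_sensed_projection_zeroed(self):
        rng = np.random.default_rng(4)
        model = SpectralModel.create(7, gap=30.0, seed=4)
        s = rng.standard_normal(7)
        s /= np.linalg.norm(s)
        a = rng.standard_normal(7)
        a /= np.linalg.norm(a)
        for _ in range(5):
            dx = controlled_response(model, (s, a), rng.standard_normal(7))
            assert abs(s @ dx) < 1e-9

    def test_uncontrollable_error(self):
        lin = LinearSystem.from_jacobian(-np.eye(3))
        s = np.array([1.0, 0.0, 0.0])
        a = np.array([0.0, 1.0, 0.0])  # D a orthogonal to s
        with pytest.raises(UncontrollableError):
            controlled_response(lin, (s, a), np.ones(3))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_ode_integration(self, seed):
        system, s, a, c_p, c_i = make_closed_loop_system(seed)
        rng = np.random.default_rng(100 + seed)
        de = rng.standard_normal(6)
        algebraic = controlled_response(system, (s, a), de)
        numeric = integrate_pi_loop(system, s, a, c_p, c_i, de)
        np.testing.assert_allclose(algebraic, numeric, atol=1e-6)

    def test_slow_mode_component_cancelled_exactly(self):
        model = SpectralModel.create(6, gap=50.0, seed=5)
        v0 = model.v0
        rng = np.random.default_rng(6)
        de = rng.standard_normal(6)
        dx = controlled_response(model, (v0, v0), de)
        assert abs(v0 @ dx) < 1e-10
        # fast components pass through untouched
        fast = model.basis[:, 1:]
        np.testing.assert_allclose(
            fast.T @ dx, (fast.T @ de) / model.lambda_fast, atol=1e-10
        )


class TestLinearSteadyState:
    def test_multichannel_zeroes_all_sensed_projections(self):
        rng = np.random.default_rng(7)
        R = rng.standard_normal((6, 6))
        J = -(R @ R.T + np.eye(6))
        S = np.linalg.qr(rng.standard_normal((6, 3)))[0].T
        G = rng.standard_normal((6, 3))
        e = rng.standard_normal(6)
        dx = linear_steady_state(J, e, S, G, c_p=1.0, c_i=1.0)
        np.testing.assert_allclose(S @ dx, np.zeros(3), atol=1e-9)

    def test_full_observability_cancels_everything(self):
        rng = np.random.default_rng(8)
        J = -(np.eye(4) + 0.1 * rng.standard_normal((4, 4)))
        S = np.linalg.qr(rng.standard_normal((4, 4)))[0].T
        G = rng.standard_normal((4, 4))
        dx = linear_steady_state(J, rng.standard_normal(4), S, G)
        np.testing.assert_allclose(dx, np.zeros(4), atol=1e-9)

    def test_zero_gains_uncontrolled(self):
        J = -np.diag([1.0, 2.0])
        e = np.array([1.0, 1.0])
        dx = linear_steady_state(J, e, np.eye(2), np.eye(2), c_p=0.0, c_i=0.0)
        np.testing.assert_allclose(dx, [1.0, 0.5])

    def test_batched_forcing(self):
        J = -np.diag([1.0, 2.0, 4.0])
        E = np.eye(3)
        X = linear_steady_state(J, E)
        np.testing.assert_allclose(X, np.diag([1.0, 0.5, 0.25]))


class TestExpectedDeviation:
    def test_matches_printed_large_gap_form(self):
        # alpha = beta = 1: slow mode cancelled, fast modes pass at 1/lambda
        model = SpectralModel.create(12, gap=100.0, seed=9)
        mu = 2.0 * model.v0 + 0.7 * model.basis[:, 3]
        ens = PerturbationEnsemble(mean=mu, sd=np.ones(12))
        geom = ControlGeometry.from_ensemble(model, ens, 1.0, 1.0)
        mu_modes = model.basis.T @ mu
        expected = np.sqrt(np.sum(mu_modes[1:] ** 2) + 11.0) / model.lambda_fast
        assert expected_deviation(model, ens, geom) == pytest.approx(expected)

    def test_no_slow_content_normalized_to_one(self):
        # slow-aligned geometry cancels the slow mode, which is empty here,
        # so control buys nothing relative to the uncontrolled response
        model = SpectralModel.create(6, gap=50.0)
        mu = np.zeros(6)
        mu[1] = 1.0  # fast-mode mean only
        sd = np.zeros(6)
        sd[2] = 1.0  # fast-mode noise only
        ens = PerturbationEnsemble(mean=mu, sd=sd)
        geom = ControlGeometry.from_ensemble(model, ens, 1.0, 1.0)
        assert expected_deviation(model, ens, geom, normalized=True) == pytest.approx(1.0)

    def test_closed_form_vs_monte_carlo(self):
        model = SpectralModel.create(20, gap=10.0, seed=10)
        ens = PerturbationEnsemble(mean=1.5 * model.v0, sd=np.ones(20))
        geom = ControlGeometry.from_ensemble(model, ens, 0.9, 0.8)
        closed = expected_deviation(model, ens, geom)
        mc, se = mc_expected_deviation(model, ens, geom, n_samples=100_000, seed=11)
        assert abs(closed - mc) < 3 * se
        assert abs(closed - mc) / closed < 0.01

    def test_mc_zero_for_cancellable_mean_only(self):
        model = SpectralModel.create(5, gap=4.0)
        a = np.full(5, 1.0) / np.sqrt(5.0)
        ens = PerturbationEnsemble(mean=3.0 * a, sd=np.zeros(5))
        mc, _ = mc_expected_deviation(model, ens, (a, a), n_samples=100, seed=0)
        assert mc == pytest.approx(0.0, abs=1e-10)

    def test_mc_scale_homogeneity(self):
        model = SpectralModel.create(6, gap=5.0, seed=12)
        geom = (model.v0, model.v0)
        e1 = PerturbationEnsemble(mean=np.zeros(6), sd=np.ones(6))
        e2 = PerturbationEnsemble(mean=np.zeros(6), sd=2 * np.ones(6))
        m1, _ = mc_expected_deviation(model, e1, geom, n_samples=2000, seed=13)
        m2, _ = mc_expected_deviation(model, e2, geom, n_samples=2000, seed=13)
        assert m2 == pytest.approx(2 * m1, rel=1e-9)


class TestOptimalGeometry:
    def test_large_gap_aligns_with_slow_mode(self):
        model = SpectralModel.create(20, gap=100.0, seed=14)
        ens = PerturbationEnsemble(mean=2.0 * model.v0, sd=np.ones(20))
        opt = optimal_geometry(model, ens)
        assert opt.alpha >= 0.99
        assert opt.beta >= 0.99

    def test_monotone_in_gap(self):
        base = SpectralModel.create(20, gap=1.0, seed=15)
        mu = 2.0 * base.v0 + 0.5 * base.basis[:, 1]
        ens = PerturbationEnsemble(mean=mu, sd=np.ones(20))
        alphas, betas = [], []
        for gap in (1.0, 3.0, 10.0, 30.0, 100.0):
            opt = optimal_geometry(base.with_gap(gap), ens)
            alphas.append(opt.alpha)
            betas.append(opt.beta)
        assert np.all(np.diff(alphas) >= -1e-4)
        assert np.all(np.diff(betas) >= -1e-4)

    def test_gap_one_matches_brute_force_grid(self):
        model = SpectralModel.create(8, gap=1.0, seed=16)
        mu = 1.5 * model.v0 + 1.0 * model.basis[:, 1]
        ens = PerturbationEnsemble(mean=mu, sd=np.ones(8))
        opt = optimal_geometry(model, ens)

        def objective(al, be):
            try:
                return expected_deviation(
                    model, ens, ControlGeometry.from_ensemble(model, ens, al, be)
                )
            except UncontrollableError:
                return np.inf

        grid = np.linspace(0, 1, 101)
        best = min(objective(al, be) for al in grid for be in grid)
        assert opt.value <= best + 1e-4


class TestGapBenefit:
    def test_grows_with_dimension(self):
        benefits = []
        for n in (2, 50):
            model = SpectralModel.create(n, gap=100.0, seed=17)
            ens = PerturbationEnsemble(mean=2.0 * model.v0, sd=np.ones(n))
            benefits.append(gap_benefit(model, ens))
        assert benefits[1] > benefits[0]

    def test_zero_without_slow_content(self):
        model = SpectralModel.create(6, gap=100.0)
        mu = np.zeros(6)
        mu[1] = 2.0
        sd = np.zeros(6)
        sd[1:] = 1.0  # no slow-mode variance either
        ens = PerturbationEnsemble(mean=mu, sd=sd)
        assert gap_benefit(model, ens) == pytest.approx(0.0, abs=1e-6)

    def test_bounded_in_unit_interval(self):
        model = SpectralModel.create(10, gap=100.0, seed=18)
        ens = PerturbationEnsemble(mean=model.v0, sd=0.5 * np.ones(10))
        b = gap_benefit(model, ens)
        assert 0.0 - 1e-9 <= b <= 1.0 + 1e-9


class TestPerturbationEnsemble:
    def test_sampling_moments(self):
        ens = PerturbationEnsemble(mean=np.array([1.0, -1.0]), sd=np.array([0.5, 2.0]))
        draws = ens.sample(50_000, rng=0)
        np.testing.assert_allclose(draws.mean(axis=0), [1.0, -1.0], atol=0.03)
        np.testing.assert_allclose(draws.std(axis=0), [0.5, 2.0], atol=0.05)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            PerturbationEnsemble(mean=np.zeros(2), sd=np.array([-0.1, 1.0]))

    def test_geometry_unit_vectors(self):
        model = SpectralModel.create(5, gap=10.0, seed=19)
        ens = PerturbationEnsemble(mean=model.v0 + model.basis[:, 2], sd=np.ones(5))
        geom = ControlGeometry.from_ensemble(model, ens, 0.6, 0.3)
        assert np.linalg.norm(geom.sense(model)) == pytest.approx(1.0)
        assert np.linalg.norm(geom.act(model)) == pytest.approx(1.0)
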