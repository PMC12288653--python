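"""Nonlinear gene-network dynamics with saturating (Michaelis-Menten) interactions.

The state is a vector of expression levels ``n``.  Each gene ``a`` is produced
at rate ``sum_b k_ab * n_b / (n_b + K_ab)``, degraded linearly at rate
``gamma_a * n_a``, and may be forced by a static environmental vector and/or
acted on by a low-dimensional integral-feedback controller (see
:mod:`softmode.controller`).

This module owns fixed-point location, analytic Jacobians, eigenmode
bookkeeping (including the mode gap), and time integration of the augmented
(state + controller-integral) ODE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Union

import numpy as np
from scipy import optimize
from scipy.integrate import solve_ivp

if TYPE_CHECKING:  # pragma: no cover
    from softmode.controller import Controller

__all__ = [
    "ShapeError",
    "DegenerateFixedPointError",
    "FixedPointError",
    "UnstableSystemError",
    "GeneNetwork",
    "EnvForcing",
    "Trajectory",
    "LinearSystem",
    "SteadyStateResult",
    "rhs",
    "find_fixed_point",
    "jacobian_at",
    "linearize",
    "mode_gap",
    "integrate",
    "steady_state_deviation",
    "random_network",
]


class ShapeError(ValueError):
    """Dimension mismatch between network, forcing, or controller."""


class FixedPointError(RuntimeError):
    """Root finder failed to locate a fixed point."""


class DegenerateFixedPointError(FixedPointError):
    """The only fixed point found is the all-zero (extinct) state."""


class UnstableSystemError(RuntimeError):
    """Operation requires a stable linearization but one was not found."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneNetwork:
    """Parameters of the saturating interaction network.

    Parameters
    ----------
    k_mat
        ``(N, N)`` interaction strengths ``k_ab`` (rate units).  ``k_ab`` is the
        maximal rate at which gene ``b`` drives production of gene ``a``.
    K_mat
        ``(N, N)`` strictly positive half-saturation constants ``K_ab``.
    decay
        Length-``N`` strictly positive linear degradation rates ``gamma_a``.
    n_wt
        Optional wild-type fixed point; set by :func:`find_fixed_point`.
    fp_tol
        Residual tolerance used to validate ``n_wt``.
    """

    k_mat: np.ndarray
    K_mat: np.ndarray
    decay: np.ndarray
    n_wt: Optional[np.ndarray] = None
    fp_tol: float = 1e-10

    def __post_init__(self) -> None:
        self.k_mat = np.atleast_2d(np.asarray(self.k_mat, dtype=float))
        self.K_mat = np.atleast_2d(np.asarray(self.K_mat, dtype=float))
        self.decay = np.atleast_1d(np.asarray(self.decay, dtype=float))
        n = self.k_mat.shape[0]
        if self.k_mat.shape != (n, n) or self.K_mat.shape != (n, n):
            raise ShapeError(
                f"k_mat/K_mat must be square and matching, got {self.k_mat.shape} "
                f"and {self.K_mat.shape}"
            )
        if self.decay.shape != (n,):
            raise ShapeError(f"decay must have length {n}, got {self.decay.shape}")
        if not np.all(self.K_mat > 0):
            raise ValueError("K_mat entries must be strictly positive")
        if not np.all(self.decay > 0):
            raise ValueError("decay rates must be strictly positive")
        if self.n_wt is not None:
            self.n_wt = np.atleast_1d(np.asarray(self.n_wt, dtype=float))
            if self.n_wt.shape != (n,):
                raise ShapeError(f"n_wt must have length {n}")
            if np.any(self.n_wt < 0):
                raise ValueError("n_wt entries must be non-negative")
            resid = float(np.linalg.norm(rhs(self, self.n_wt)))
            if resid > max(self.fp_tol, 1e-8):
                raise ValueError(
                    f"n_wt is not a fixed point (residual {resid:.3e} > tol)"
                )

    @property
    def n_genes(self) -> int:
        return self.k_mat.shape[0]

    def copy(self) -> "GeneNetwork":
        return GeneNetwork(
            k_mat=self.k_mat.copy(),
            K_mat=self.K_mat.copy(),
            decay=self.decay.copy(),
            n_wt=None if self.n_wt is None else self.n_wt.copy(),
            fp_tol=self.fp_tol,
        )

    def with_params(self, k_mat: np.ndarray, K_mat: np.ndarray) -> "GeneNetwork":
        """New network with replaced interaction parameters; n_wt is dropped."""
        return GeneNetwork(
            k_mat=np.asarray(k_mat, float).copy(),
            K_mat=np.asarray(K_mat, float).copy(),
            decay=self.decay.copy(),
            n_wt=None,
            fp_tol=self.fp_tol,
        )


@dataclass
class EnvForcing:
    """Static per-gene environmental forcing.

    ``multiplicative`` mode adds ``delta_e[a] * n[a]`` to gene ``a``'s rate
    (a perturbation of its effective growth/decay rate); ``additive`` mode adds
    ``delta_e[a]`` directly.
    """

    delta_e: np.ndarray
    mode: str = "multiplicative"

    def __post_init__(self) -> None:
        self.delta_e = np.atleast_1d(np.asarray(self.delta_e, dtype=float))
        if self.mode not in ("multiplicative", "additive"):
            raise ValueError(f"unknown forcing mode {self.mode!r}")

    def term(self, state: np.ndarray) -> np.ndarray:
        if self.mode == "multiplicative":
            return self.delta_e * state
        return self.delta_e

    def effective_vector(self, n_wt: np.ndarray) -> np.ndarray:
        """Additive forcing vector seen by the linearization at ``n_wt``."""
        if self.mode == "multiplicative":
            return self.delta_e * n_wt
        return self.delta_e


@dataclass
class Trajectory:
    """Time grid, expression states, and controller integral accumulators."""

    times: np.ndarray
    states: np.ndarray  # (T, N)
    integrals: np.ndarray  # (T, k); k = 0 when uncontrolled

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        self.integrals = np.asarray(self.integrals, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self):
        """Tidy table: time, n_0..n_{N-1}, I_0..I_{k-1}."""
        import pandas as pd

        data = {"time": self.times}
        for j in range(self.states.shape[1]):
            data[f"n_{j}"] = self.states[:, j]
        for j in range(self.integrals.shape[1]):
            data[f"I_{j}"] = self.integrals[:, j]
        return pd.DataFrame(data)


@dataclass
class LinearSystem:
    """Linearization around a fixed point.

    Eigenvalues are sorted by ascending ``|Re(lambda)|`` so index 0 is the
    slowest mode; eigenvector columns are unit norm and match the ordering.
    """

    jacobian: np.ndarray
    eigvals: np.ndarray = field(default=None)  # type: ignore[assignment]
    eigvecs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.jacobian = np.atleast_2d(np.asarray(self.jacobian, dtype=float))
        if self.eigvals is None or self.eigvecs is None:
            vals, vecs = np.linalg.eig(self.jacobian)
            order = np.argsort(np.abs(vals.real), kind="stable")
            vals = vals[order]
            vecs = vecs[:, order]
            vecs = vecs / np.linalg.norm(vecs, axis=0, keepdims=True)
            self.eigvals = vals
            self.eigvecs = vecs

    @classmethod
    def from_jacobian(cls, jac: np.ndarray) -> "LinearSystem":
        return cls(jacobian=np.asarray(jac, dtype=float))

    @property
    def n_dims(self) -> int:
        return self.jacobian.shape[0]

    @property
    def stable(self) -> bool:
        return bool(np.all(self.eigvals.real < 0))

    def response_matrix(self) -> np.ndarray:
        """``-J^{-1}``: maps a static forcing to the steady-state offset."""
        return -np.linalg.inv(self.jacobian)


@dataclass
class SteadyStateResult:
    """Steady-state deviation from the wild-type fixed point."""

    delta_n: np.ndarray
    converged: bool
    t_final: float


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _production(network: GeneNetwork, state: np.ndarray) -> np.ndarray:
    # production saturates; evaluated at max(n, 0) so negative excursions
    # cannot generate negative production rates
    n = np.maximum(state, 0.0)
    frac = n[None, :] / (n[None, :] + network.K_mat)
    return (network.k_mat * frac).sum(axis=1)


def rhs(
    network: GeneNetwork,
    state: np.ndarray,
    forcing: Optional[EnvForcing] = None,
    controller: Optional["Controller"] = None,
    integrals: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Time derivative of the expression state.

    ``sum_b k_ab n_b/(n_b + K_ab) - gamma_a n_a (+ forcing) (- control action)``.
    The controller's deviation reference is ``network.n_wt``.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (network.n_genes,):
        raise ShapeError(
            f"state has shape {state.shape}, expected ({network.n_genes},)"
        )
    deriv = _production(network, state) - network.decay * state
    if forcing is not None:
        if forcing.delta_e.shape != (network.n_genes,):
            raise ShapeError("forcing length does not match network size")
        deriv = deriv + forcing.term(state)
    if controller is not None:
        if network.n_wt is None:
            raise ValueError("controller coupling requires network.n_wt to be set")
        if controller.n_genes != network.n_genes:
            raise ShapeError("controller dimensions do not match network size")
        if integrals is None:
            integrals = np.zeros(controller.k_channels)
        act = controller.control_terms(state - network.n_wt, integrals)
        deriv = deriv - act.action
    return deriv


def jacobian_at(network: GeneNetwork, state: np.ndarray) -> LinearSystem:
    """Analytic Jacobian of the uncontrolled, unforced dynamics at ``state``.

    ``J_ab = k_ab K_ab / (n_b + K_ab)^2 - gamma_a delta_ab``.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (network.n_genes,):
        raise ShapeError("state length does not match network size")
    n = np.maximum(state, 0.0)
    jac = network.k_mat * network.K_mat / (n[None, :] + network.K_mat) ** 2
    jac = jac - np.diag(network.decay)
    return LinearSystem.from_jacobian(jac)


def linearize(network: GeneNetwork) -> LinearSystem:
    """Linearization at the stored wild-type fixed point."""
    if network.n_wt is None:
        raise ValueError("network has no fixed point set; call find_fixed_point")
    return jacobian_at(network, network.n_wt)


def mode_gap(system: LinearSystem) -> float:
    """Ratio ``|Re lambda_1| / |Re lambda_0|`` of second-slowest to slowest mode."""
    if system.n_dims < 2:
        raise ValueError("mode gap is undefined for a 1-dimensional system")
    if not system.stable:
        raise UnstableSystemError("mode gap requires a stable system")
    re = np.abs(system.eigvals.real)
    return float(re[1] / re[0])


def find_fixed_point(
    network: GeneNetwork,
    guess: Optional[np.ndarray] = None,
    tol: float = 1e-12,
) -> np.ndarray:
    """Locate an interior fixed point of the unforced, uncontrolled dynamics.

    Sets ``network.n_wt`` on success.  Raises
    :class:`DegenerateFixedPointError` when the root found is (numerically)
    the all-zero state and :class:`FixedPointError` when the solver fails.
    """
    if guess is None:
        guess = np.ones(network.n_genes)
    guess = np.asarray(guess, dtype=float)
    if np.any(guess <= 0):
        raise ValueError("initial guess entries must be strictly positive")

    def fun(n: np.ndarray) -> np.ndarray:
        return rhs(network, n)

    def jac(n: np.ndarray) -> np.ndarray:
        return jacobian_at(network, n).jacobian

    sol = optimize.root(fun, guess, jac=jac, method="hybr", tol=tol)
    n_star = np.asarray(sol.x, dtype=float)
    resid = float(np.linalg.norm(fun(n_star)))
    if resid >= network.fp_tol:
        raise FixedPointError(
            f"fixed-point residual {resid:.3e} exceeds tolerance {network.fp_tol:.1e}"
        )
    if np.any(n_star < -1e-9):
        raise FixedPointError("root finder converged to a negative state")
    n_star = np.maximum(n_star, 0.0)
    scale = max(float(np.max(np.abs(guess))), 1.0)
    if np.linalg.norm(n_star) < 1e-8 * scale:
        raise DegenerateFixedPointError(
            "only the all-zero fixed point was found (pure-decay network?)"
        )
    network.n_wt = n_star
    return n_star


def _augmented_rhs(
    t: float,
    y: np.ndarray,
    network: GeneNetwork,
    forcing: Optional[EnvForcing],
    controller: Optional["Controller"],
) -> np.ndarray:
    n_genes = network.n_genes
    state = y[:n_genes]
    if controller is None:
        return rhs(network, state, forcing)
    integrals = y[n_genes:]
    deriv = rhs(network, state, forcing, controller, integrals)
    sensed = controller.sense_mat @ (state - network.n_wt)
    return np.concatenate([deriv, sensed])


def integrate(
    network: GeneNetwork,
    forcing: Optional[EnvForcing],
    controller: Optional["Controller"],
    t_span: Union[float, tuple],
    init: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_eval: Optional[int] = None,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the augmented ODE (N states + k controller integrals).

    Controller integral accumulators start at zero.  Reported states are
    clipped at zero (the RHS already evaluates production at ``max(n, 0)``).
    """
    init = np.asarray(init, dtype=float)
    if np.any(init < 0):
        raise ValueError("initial state entries must be non-negative")
    if np.isscalar(t_span):
        t0, t1 = 0.0, float(t_span)
    else:
        t0, t1 = map(float, t_span)
    if t1 <= t0:
        raise ValueError("t_span must be positive")
    k = 0 if controller is None else controller.k_channels
    y0 = np.concatenate([init, np.zeros(k)])
    t_eval = np.linspace(t0, t1, n_eval) if n_eval else None
    sol = solve_ivp(
        _augmented_rhs,
        (t0, t1),
        y0,
        args=(network, forcing, controller),
        method=method,
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t={sol.t[-1]:.4g}: {sol.message}"
        )
    n_genes = network.n_genes
    states = np.maximum(sol.y[:n_genes].T, 0.0)
    integrals = sol.y[n_genes:].T
    return Trajectory(times=sol.t, states=states, integrals=integrals)


def steady_state_deviation(
    network: GeneNetwork,
    forcing: Optional[EnvForcing],
    controller: Optional["Controller"] = None,
    tol_factor: float = 1e-8,
    t_max: Optional[float] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SteadyStateResult:
    """Integrate from ``n_wt`` until the state derivative is negligible.

    Convergence is declared at ``||dn/dt|| < tol_factor * ||n_wt||``; the
    deviation ``n(final) - n_wt`` is returned either way, with a flag.
    """
    if network.n_wt is None:
        raise ValueError("network has no fixed point set; call find_fixed_point")
    lin = linearize(network)
    if not lin.stable:
        raise UnstableSystemError("steady state requires a stable fixed point")
    t_unit = 1.0 / abs(lin.eigvals[0].real)
    if t_max is None:
        t_max = 1e3 * t_unit
    tol = tol_factor * float(np.linalg.norm(network.n_wt))
    k = 0 if controller is None else controller.k_channels
    state = network.n_wt.copy()
    integrals = np.zeros(k)
    t_now = 0.0
    converged = False
    # chunked integration: cheap convergence checks without event machinery
    chunk = max(t_max / 20.0, 10.0 * t_unit)
    while t_now < t_max:
        t_next = min(t_now + chunk, t_max)
        y0 = np.concatenate([state, integrals])
        sol = solve_ivp(
            _augmented_rhs,
            (t_now, t_next),
            y0,
            args=(network, forcing, controller),
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed at t={sol.t[-1]:.4g}")
        state = sol.y[: network.n_genes, -1]
        integrals = sol.y[network.n_genes :, -1]
        t_now = t_next
        deriv = rhs(network, state, forcing, controller, integrals if k else None)
        if np.linalg.norm(deriv) < tol:
            converged = True
            break
    return SteadyStateResult(
        delta_n=np.maximum(state, 0.0) - network.n_wt,
        converged=converged,
        t_final=t_now,
    )


def random_network(
    n_genes: int,
    seed: Optional[Union[int, np.random.Generator]] = None,
    sparsity: float = 0.5,
    k_range: tuple = (0.5, 2.0),
    K_range: tuple = (0.1, 10.0),
    decay: float = 1.0,
    max_tries: int = 500,
) -> GeneNetwork:
    """Draw a random stable network with an interior fixed point.

    ``k_ab`` is uniform on ``k_range`` with fraction ``sparsity`` of entries
    nonzero (the diagonal always kept, so every gene has a production route);
    ``K_ab`` is log-uniform on ``K_range``.  Draws are rejected until the
    fixed point exists, is interior, and is linearly stable.
    """
    rng = np.random.default_rng(seed)
    if not 1 <= n_genes:
        raise ValueError("n_genes must be positive")
    for _ in range(max_tries):
        mask = rng.random((n_genes, n_genes)) < sparsity
        np.fill_diagonal(mask, True)
        k_mat = rng.uniform(*k_range, size=(n_genes, n_genes)) * mask
        K_mat = np.exp(
            rng.uniform(np.log(K_range[0]), np.log(K_range[1]), size=(n_genes, n_genes))
        )
        net = GeneNetwork(k_mat=k_mat, K_mat=K_mat, decay=np.full(n_genes, decay))
        try:
            n_star = find_fixed_point(net, guess=np.ones(n_genes))
        except (FixedPointError, DegenerateFixedPointError):
            continue
        if np.min(n_star) < 1e-3:
            continue
        lin = linearize(net)
        if not lin.stable:
            continue
        return net
    raise RuntimeError(f"no stable interior network found in {max_tries} tries")
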