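"""Analytic linear theory of low-dimensional integral feedback.

Everything here lives in the linear regime around a stable fixed point with
Jacobian ``J``.  A static forcing ``delta_e`` displaces the uncontrolled
system by ``delta_x = -J^{-1} delta_e``.  A single-channel integral feedback
that senses ``s . delta_x`` and acts along ``a`` drives the sensed projection
to zero; the residual steady state is

    ``delta_x = D e - [(s . D e) / (s . D a)] D a``,       ``D = -J^{-1}``

which, in the eigenbasis with rescalings ``e_i / lambda_i`` and
``a_i / lambda_i``, is the familiar oblique-projection form.  The module
provides this response, its exact second-moment expectation over Gaussian
forcing ensembles, the entropy-based effective rank, the optimal
sensing/action geometry as a function of the mode gap, and a Monte-Carlo
oracle used to cross-check the closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import numpy as np
from scipy import optimize

from softmode.grn_dynamics import LinearSystem, UnstableSystemError

__all__ = [
    "UncontrollableError",
    "SpectralModel",
    "PerturbationEnsemble",
    "ControlGeometry",
    "OptimalGeometry",
    "uncontrolled_response",
    "controlled_response",
    "controlled_response_operator",
    "linear_steady_state",
    "effective_rank",
    "ensemble_effective_rank",
    "expected_deviation",
    "mc_expected_deviation",
    "optimal_geometry",
    "gap_benefit",
]


class UncontrollableError(RuntimeError):
    """The sensed projection cannot be moved by the action vector."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SpectralModel:
    """Stable linear system with one slow mode and N-1 equal fast modes.

    ``lambda_slow`` and ``lambda_fast`` are relaxation rates (``|Re lambda|``,
    positive); the mode gap is ``lambda_fast / lambda_slow``.  ``basis`` is an
    orthonormal matrix whose first column is the slow eigendirection.
    """

    n_dims: int
    lambda_slow: float
    lambda_fast: float
    basis: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_dims < 2:
            raise ValueError("SpectralModel needs n_dims >= 2")
        if not 0 < self.lambda_slow <= self.lambda_fast:
            raise ValueError("require lambda_fast >= lambda_slow > 0")
        if self.basis is None:
            self.basis = np.eye(self.n_dims)
        self.basis = np.asarray(self.basis, dtype=float)
        if self.basis.shape != (self.n_dims, self.n_dims):
            raise ValueError("basis shape mismatch")
        if not np.allclose(self.basis.T @ self.basis, np.eye(self.n_dims), atol=1e-9):
            raise ValueError("basis must be orthonormal")

    @classmethod
    def create(
        cls,
        n_dims: int,
        gap: float,
        lambda_fast: float = 1.0,
        seed: Optional[Union[int, np.random.Generator]] = None,
    ) -> "SpectralModel":
        """Model with given mode gap; random orthonormal basis when seeded."""
        if gap < 1:
            raise ValueError("mode gap must be >= 1")
        basis = None
        if seed is not None:
            rng = np.random.default_rng(seed)
            basis, _ = np.linalg.qr(rng.standard_normal((n_dims, n_dims)))
        return cls(
            n_dims=n_dims,
            lambda_slow=lambda_fast / gap,
            lambda_fast=lambda_fast,
            basis=basis,
        )

    @property
    def gap(self) -> float:
        return self.lambda_fast / self.lambda_slow

    @property
    def v0(self) -> np.ndarray:
        """Slow eigendirection (unit vector)."""
        return self.basis[:, 0]

    @property
    def rates(self) -> np.ndarray:
        out = np.full(self.n_dims, self.lambda_fast)
        out[0] = self.lambda_slow
        return out

    @property
    def jacobian(self) -> np.ndarray:
        return -(self.basis * self.rates) @ self.basis.T

    def response_matrix(self) -> np.ndarray:
        """``D = -J^{-1} = B diag(1/lambda) B^T``."""
        return (self.basis / self.rates) @ self.basis.T

    def with_gap(self, gap: float) -> "SpectralModel":
        return SpectralModel(
            n_dims=self.n_dims,
            lambda_slow=self.lambda_fast / gap,
            lambda_fast=self.lambda_fast,
            basis=self.basis.copy(),
        )


@dataclass
class PerturbationEnsemble:
    """Componentwise-independent Gaussian forcing ensemble."""

    mean: np.ndarray
    sd: np.ndarray
    seed: Optional[int] = None
    samples: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.sd = np.atleast_1d(np.asarray(self.sd, dtype=float))
        if self.sd.shape == (1,) and self.mean.shape[0] > 1:
            self.sd = np.full_like(self.mean, self.sd[0])
        if self.sd.shape != self.mean.shape:
            raise ValueError("mean and sd must have matching shapes")
        if np.any(self.sd < 0):
            raise ValueError("sd entries must be non-negative")
        if self.samples is not None:
            self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
            if self.samples.shape[1] != self.mean.shape[0]:
                raise ValueError("samples must have one column per dimension")

    @property
    def n_dims(self) -> int:
        return self.mean.shape[0]

    def sample(
        self, n: int, rng: Optional[Union[int, np.random.Generator]] = None
    ) -> np.ndarray:
        if rng is None:
            rng = np.random.default_rng(self.seed)
        elif not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        return self.mean + self.sd * rng.standard_normal((n, self.n_dims))


@dataclass
class ControlGeometry:
    """Sensing/action vectors interpolating slow mode and mean direction.

    ``s = alpha v0 + sqrt(1-alpha^2) mu_hat`` and likewise for the action with
    weight ``beta``.  ``mu_hat`` is a unit vector orthogonal to ``v0`` (the
    component of the mean forcing direction orthogonal to the slow mode), so
    both vectors are exactly unit norm.
    """

    alpha: float
    beta: float
    mu_hat: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValueError("alpha and beta must lie in [0, 1]")
        self.mu_hat = np.asarray(self.mu_hat, dtype=float)
        nrm = np.linalg.norm(self.mu_hat)
        if abs(nrm - 1.0) > 1e-8:
            raise ValueError("mu_hat must be a unit vector")

    @classmethod
    def from_ensemble(
        cls, model: SpectralModel, ensemble: PerturbationEnsemble, alpha: float, beta: float
    ) -> "ControlGeometry":
        """Build ``mu_hat`` from the mean forcing, projected off the slow mode.

        A mean (near-)parallel to ``v0`` leaves ``mu_hat`` undetermined; the
        first fast basis direction is used so the geometry stays well defined.
        """
        v0 = model.v0
        perp = ensemble.mean - (ensemble.mean @ v0) * v0
        nrm = np.linalg.norm(perp)
        if nrm < 1e-12:
            mu_hat = model.basis[:, 1]
        else:
            mu_hat = perp / nrm
        return cls(alpha=alpha, beta=beta, mu_hat=mu_hat)

    def sense(self, model: SpectralModel) -> np.ndarray:
        return self.alpha * model.v0 + np.sqrt(1.0 - self.alpha**2) * self.mu_hat

    def act(self, model: SpectralModel) -> np.ndarray:
        return self.beta * model.v0 + np.sqrt(1.0 - self.beta**2) * self.mu_hat


@dataclass
class OptimalGeometry:
    alpha: float
    beta: float
    value: float
    converged: bool


# ---------------------------------------------------------------------------
# Responses
# ---------------------------------------------------------------------------

SystemLike = Union[LinearSystem, SpectralModel]


def _response_matrix(system: SystemLike) -> np.ndarray:
    if isinstance(system, SpectralModel):
        return system.response_matrix()
    if not system.stable:
        raise UnstableSystemError("response requires a stable system")
    return system.response_matrix()


def uncontrolled_response(system: SystemLike, delta_e: np.ndarray) -> np.ndarray:
    """Steady-state offset ``-J^{-1} delta_e`` of the uncontrolled system."""
    delta_e = np.asarray(delta_e, dtype=float)
    return _response_matrix(system) @ delta_e


def _resolve_sa(
    system: SystemLike,
    geometry: Union[ControlGeometry, Tuple[np.ndarray, np.ndarray]],
) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(geometry, ControlGeometry):
        if not isinstance(system, SpectralModel):
            raise TypeError("ControlGeometry requires a SpectralModel")
        return geometry.sense(system), geometry.act(system)
    s, a = geometry
    return np.asarray(s, dtype=float), np.asarray(a, dtype=float)


def controlled_response_operator(
    system: SystemLike,
    geometry: Union[ControlGeometry, Tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    """Matrix ``A`` with ``delta_x = A delta_e`` for the integral-controlled
    steady state: ``A = (I - D a s^T / (s . D a)) D``."""
    s, a = _resolve_sa(system, geometry)
    D = _response_matrix(system)
    Da = D @ a
    denom = float(s @ Da)
    if abs(denom) < 1e-12 * (np.linalg.norm(s) * np.linalg.norm(Da) + 1e-300):
        raise UncontrollableError("sensed projection is orthogonal to D @ a")
    return D - np.outer(Da, s @ D) / denom


def controlled_response(
    system: SystemLike,
    geometry: Union[ControlGeometry, Tuple[np.ndarray, np.ndarray]],
    delta_e: np.ndarray,
) -> np.ndarray:
    """Steady state under single-channel integral feedback.

    Satisfies ``s . delta_x = 0``: the integral action zeroes the sensed
    error, independent of the (positive) gains.
    """
    delta_e = np.asarray(delta_e, dtype=float)
    return controlled_response_operator(system, geometry) @ delta_e


def linear_steady_state(
    jacobian: np.ndarray,
    forcing: np.ndarray,
    sense_mat: Optional[np.ndarray] = None,
    action_mat: Optional[np.ndarray] = None,
    c_p: float = 1.0,
    c_i: float = 1.0,
) -> np.ndarray:
    """k-channel generalization of the controlled steady state.

    ``forcing`` may be a single vector or a ``(m, N)`` batch (one row per
    draw); the result has the same shape.  With integral gain on, the sensed
    projections are zeroed exactly and the proportional gain drops out; with
    proportional-only control the effective Jacobian is ``J - c_p G S``; with
    both gains zero (or no controller) the response is uncontrolled.
    """
    J = np.asarray(jacobian, dtype=float)
    e = np.asarray(forcing, dtype=float)
    single = e.ndim == 1
    E = np.atleast_2d(e).T  # (N, m)
    if sense_mat is None or action_mat is None or (c_p == 0.0 and c_i == 0.0):
        X = -np.linalg.solve(J, E)
    elif c_i == 0.0:
        X = -np.linalg.solve(J - c_p * np.asarray(action_mat) @ np.asarray(sense_mat), E)
    else:
        S = np.asarray(sense_mat, dtype=float)
        G = np.asarray(action_mat, dtype=float)
        DE = -np.linalg.solve(J, E)  # (N, m)
        DG = -np.linalg.solve(J, G)  # (N, k)
        M = S @ DG  # (k, k)
        W = np.linalg.solve(M, S @ DE)  # (k, m)
        X = DE - DG @ W
    return X[:, 0] if single else X.T


# ---------------------------------------------------------------------------
# Effective rank
# ---------------------------------------------------------------------------


def effective_rank(variance_fractions: np.ndarray) -> float:
    """``exp`` of the Shannon entropy (natural log) of variance fractions."""
    p = np.asarray(variance_fractions, dtype=float)
    if np.any(p < 0):
        raise ValueError("variance fractions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"variance fractions must sum to 1, got {p.sum():.12f}")
    nz = p[p > 0]
    return float(np.exp(-np.sum(nz * np.log(nz))))


def ensemble_effective_rank(samples: np.ndarray) -> float:
    """Effective rank of a point cloud: PCA variance fractions of the
    mean-centered samples fed through :func:`effective_rank`."""
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    X = X - X.mean(axis=0, keepdims=True)
    svals = np.linalg.svd(X, compute_uv=False)
    var = svals**2
    total = var.sum()
    if total == 0:
        return 1.0
    return effective_rank(var / total)


# ---------------------------------------------------------------------------
# Expected deviation and optimal geometry
# ---------------------------------------------------------------------------


def _rms_deviation(A: np.ndarray, ensemble: PerturbationEnsemble) -> float:
    # E||A e||^2 = ||A mu||^2 + sum_j sd_j^2 ||A[:, j]||^2 for independent
    # componentwise-Gaussian e
    mean_term = float(np.sum((A @ ensemble.mean) ** 2))
    var_term = float(np.sum((A * ensemble.sd[None, :]) ** 2))
    return float(np.sqrt(mean_term + var_term))


def expected_deviation(
    model: SpectralModel,
    ensemble: PerturbationEnsemble,
    geometry: Union[ControlGeometry, Tuple[np.ndarray, np.ndarray]],
    normalized: bool = False,
) -> float:
    """Root-mean-square deviation ``sqrt(E||delta_x||^2)`` under control.

    With ``normalized=True`` the value is divided by the same statistic for
    the uncontrolled system, recovering the printed closed form (slow-mode
    content suppressed by the squared mode gap at optimal geometry).
    """
    A = controlled_response_operator(model, geometry)
    dev = _rms_deviation(A, ensemble)
    if not normalized:
        return dev
    base = _rms_deviation(model.response_matrix(), ensemble)
    return dev / base


def mc_expected_deviation(
    model: SpectralModel,
    ensemble: PerturbationEnsemble,
    geometry: Union[ControlGeometry, Tuple[np.ndarray, np.ndarray]],
    n_samples: int = 10_000,
    seed: Optional[int] = None,
    statistic: str = "rms",
) -> Tuple[float, float]:
    """Monte-Carlo oracle for the expected deviation norm.

    ``statistic='rms'`` estimates ``sqrt(E||dx||^2)`` (comparable to
    :func:`expected_deviation`); ``'mean'`` estimates ``E||dx||``.  Returns
    ``(value, standard_error)``; the rms standard error uses the delta method.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    draws = ensemble.sample(n_samples, rng=seed)
    A = controlled_response_operator(model, geometry)
    norms_sq = np.sum((draws @ A.T) ** 2, axis=1)
    if statistic == "rms":
        m2 = float(norms_sq.mean())
        se_m2 = float(norms_sq.std(ddof=1) / np.sqrt(n_samples)) if n_samples > 1 else np.inf
        val = np.sqrt(m2)
        return val, se_m2 / (2.0 * val) if val > 0 else se_m2
    if statistic == "mean":
        norms = np.sqrt(norms_sq)
        se = float(norms.std(ddof=1) / np.sqrt(n_samples)) if n_samples > 1 else np.inf
        return float(norms.mean()), se
    raise ValueError(f"unknown statistic {statistic!r}")


def optimal_geometry(
    model: SpectralModel,
    ensemble: PerturbationEnsemble,
    n_grid: int = 21,
    n_starts: int = 3,
    tol: float = 1e-6,
) -> OptimalGeometry:
    """Minimize the expected deviation over ``(alpha, beta)`` in ``[0,1]^2``.

    Warm-started from an ``n_grid x n_grid`` scan, refined by bounded local
    optimization from the best ``n_starts`` grid points.  Deterministic.
    """

    def objective(x: np.ndarray) -> float:
        geom = ControlGeometry.from_ensemble(model, ensemble, x[0], x[1])
        try:
            return expected_deviation(model, ensemble, geom)
        except UncontrollableError:
            return np.inf

    grid = np.linspace(0.0, 1.0, n_grid)
    vals = np.array([[objective(np.array([a, b])) for b in grid] for a in grid])
    flat = np.argsort(vals, axis=None)[:n_starts]
    best_x, best_f, converged = None, np.inf, False
    for idx in flat:
        i, j = np.unravel_index(idx, vals.shape)
        res = optimize.minimize(
            objective,
            x0=np.array([grid[i], grid[j]]),
            bounds=[(0.0, 1.0), (0.0, 1.0)],
            method="L-BFGS-B",
            options={"ftol": tol * 1e-3, "gtol": tol},
        )
        if res.fun < best_f:
            best_x, best_f, converged = res.x, float(res.fun), bool(res.success)
    return OptimalGeometry(
        alpha=float(best_x[0]), beta=float(best_x[1]), value=best_f, converged=converged
    )


def gap_benefit(
    model: SpectralModel,
    ensemble: PerturbationEnsemble,
    gap_low: float = 1.0,
    gap_high: float = 100.0,
) -> float:
    """Normalized expected deviation at ``gap_low`` minus at ``gap_high``,
    each evaluated at its own optimal geometry.  Lies in ``[0, 1]``."""
    out = []
    for gap in (gap_low, gap_high):
        m = model.with_gap(gap)
        opt = optimal_geometry(m, ensemble)
        geom = ControlGeometry.from_ensemble(m, ensemble, opt.alpha, opt.beta)
        out.append(expected_deviation(m, ensemble, geom, normalized=True))
    return out[0] - out[1]
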