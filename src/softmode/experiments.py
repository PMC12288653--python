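"""In-silico prediction experiments: dual buffering and knockout dimensionality.

Both experiments reuse a controller whose parameters were selected for
environmental robustness and ask (a) whether it also buffers mutational
(parameter) perturbations — it should, but only when the network has a
pronounced mode gap — and (b) what a controller knockout does to the
dimensionality of the environmental response — counterintuitively, the
knockout *lowers* it, because the exposed soft mode channels every
perturbation into one direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

import numpy as np

from softmode.controller import Controller, knockout
from softmode.grn_dynamics import (
    EnvForcing,
    GeneNetwork,
    LinearSystem,
    linearize,
    rhs,
    steady_state_deviation,
)
from softmode.linear_theory import (
    PerturbationEnsemble,
    SpectralModel,
    effective_rank,
    linear_steady_state,
)

__all__ = [
    "MutationSpec",
    "BufferingResult",
    "DimensionalityResult",
    "apply_mutation",
    "mutational_deviations",
    "environmental_deviations",
    "dual_buffering_experiment",
    "knockout_dimensionality_experiment",
    "alignment_score",
]


@dataclass
class MutationSpec:
    """Ensemble of small multiplicative parameter perturbations."""

    magnitude: float = 0.05
    n_mutations: int = 50
    target: str = "both"  # k_mat | K_mat | both
    seed: int = 0

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")
        if self.n_mutations < 1:
            raise ValueError("n_mutations must be >= 1")
        if self.target not in ("k_mat", "K_mat", "both"):
            raise ValueError(f"unknown mutation target {self.target!r}")


@dataclass
class BufferingResult:
    """Paired deviation norms, controller on vs knocked out, one condition."""

    condition: str  # environmental | mutational
    network_label: str  # gap | no-gap
    controlled_norms: np.ndarray
    knockout_norms: np.ndarray
    n_excluded: int = 0

    @property
    def buffering_ratio(self) -> float:
        return float(np.mean(self.controlled_norms) / np.mean(self.knockout_norms))


@dataclass
class DimensionalityResult:
    """PCA summaries of the environmental response, on vs knocked out."""

    controlled_variance_fractions: np.ndarray
    knockout_variance_fractions: np.ndarray
    n_excluded: int = 0

    @property
    def controlled_effective_rank(self) -> float:
        return effective_rank(self.controlled_variance_fractions)

    @property
    def knockout_effective_rank(self) -> float:
        return effective_rank(self.knockout_variance_fractions)

    @property
    def controlled_pc1_share(self) -> float:
        return float(self.controlled_variance_fractions[0])

    @property
    def knockout_pc1_share(self) -> float:
        return float(self.knockout_variance_fractions[0])


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------


def apply_mutation(
    network: GeneNetwork, spec: MutationSpec, draw_index: int
) -> GeneNetwork:
    """Multiplicative ``(1 + eps)`` perturbation of the targeted parameters.

    ``eps`` is a seeded normal of sd ``magnitude`` per targeted nonzero entry;
    factors are floored at a small positive value so ``K_mat`` stays valid for
    any draw.  The ancestral ``n_wt`` is kept as the homeostasis reference.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, draw_index]))
    k_mat = network.k_mat.copy()
    K_mat = network.K_mat.copy()
    if spec.target in ("k_mat", "both"):
        eps = rng.normal(0.0, spec.magnitude, k_mat.shape)
        k_mat = np.where(k_mat != 0, k_mat * np.maximum(1.0 + eps, 1e-6), 0.0)
    if spec.target in ("K_mat", "both"):
        eps = rng.normal(0.0, spec.magnitude, K_mat.shape)
        K_mat = K_mat * np.maximum(1.0 + eps, 1e-6)
    mutant = network.with_params(k_mat, K_mat)
    mutant.n_wt = None if network.n_wt is None else network.n_wt.copy()
    # the ancestral reference need not be a fixed point of the mutant; bypass
    # the constructor's residual validation by assigning after construction
    return mutant


def _mutation_forcing(network: GeneNetwork, mutant: GeneNetwork) -> np.ndarray:
    """Static forcing equivalent of a mutation: the mutant rate at the
    ancestral fixed point."""
    return rhs(mutant, network.n_wt)


def _controlled_linear_deviation(
    lin: LinearSystem, forcing: np.ndarray, controller: Optional[Controller]
) -> np.ndarray:
    if controller is None or controller.is_null:
        return linear_steady_state(lin.jacobian, forcing)
    return linear_steady_state(
        lin.jacobian,
        forcing,
        controller.sense_mat,
        controller.action_mat,
        controller.c_p,
        controller.c_i,
    )


def mutational_deviations(
    network: GeneNetwork,
    controller: Optional[Controller],
    spec: MutationSpec,
    mode: str = "linearized",
) -> Tuple[np.ndarray, int]:
    """Steady-state deviations from the ancestral fixed point for each
    mutational draw.  Returns ``(deviations, n_excluded)``; draws whose
    mutant loses stability are excluded (ODE mode) or flagged infinite and
    excluded (linearized mode).
    """
    if network.n_wt is None:
        raise ValueError("network needs a solved fixed point")
    lin = linearize(network)
    out: List[np.ndarray] = []
    n_excluded = 0
    for j in range(spec.n_mutations):
        mutant = apply_mutation(network, spec, j)
        forcing = _mutation_forcing(network, mutant)
        if mode == "linearized":
            dev = _controlled_linear_deviation(lin, forcing, controller)
            if not np.all(np.isfinite(dev)):
                n_excluded += 1
                continue
            out.append(dev)
        else:
            mutant.n_wt = network.n_wt.copy()
            try:
                res = steady_state_deviation(mutant, None, controller)
            except Exception:
                n_excluded += 1
                continue
            out.append(res.delta_n)
    return np.array(out), n_excluded


def environmental_deviations(
    network: GeneNetwork,
    controller: Optional[Controller],
    env_draws: np.ndarray,
    mode: str = "linearized",
) -> Tuple[np.ndarray, int]:
    """Steady-state deviations for a batch of multiplicative env forcings."""
    if network.n_wt is None:
        raise ValueError("network needs a solved fixed point")
    if mode == "linearized":
        lin = linearize(network)
        eff = env_draws * network.n_wt[None, :]
        return _controlled_linear_deviation(lin, eff, controller), 0
    out: List[np.ndarray] = []
    n_excluded = 0
    for de in env_draws:
        try:
            res = steady_state_deviation(
                network, EnvForcing(de, mode="multiplicative"), controller
            )
        except Exception:
            n_excluded += 1
            continue
        out.append(res.delta_n)
    return np.array(out), n_excluded


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------


def _buffering_cell(
    network: GeneNetwork,
    controller: Controller,
    label: str,
    condition: str,
    spec: MutationSpec,
    env_draws: np.ndarray,
    mode: str,
) -> BufferingResult:
    ko = knockout(controller)
    if condition == "mutational":
        on, ex_on = mutational_deviations(network, controller, spec, mode)
        off, ex_off = mutational_deviations(network, ko, spec, mode)
    else:
        on, ex_on = environmental_deviations(network, controller, env_draws, mode)
        off, ex_off = environmental_deviations(network, ko, env_draws, mode)
    return BufferingResult(
        condition=condition,
        network_label=label,
        controlled_norms=np.linalg.norm(on, axis=1),
        knockout_norms=np.linalg.norm(off, axis=1),
        n_excluded=ex_on + ex_off,
    )


def dual_buffering_experiment(
    network_gap: GeneNetwork,
    network_nogap: GeneNetwork,
    controller: Controller,
    mut_spec: MutationSpec,
    env_ensemble: PerturbationEnsemble,
    controller_nogap: Optional[Controller] = None,
    mode: str = "linearized",
    n_env: Optional[int] = None,
) -> List[BufferingResult]:
    """Four-cell experiment: {gap, no-gap} x {environmental, mutational}.

    Each cell pairs deviation norms with the controller active vs knocked
    out, using common perturbation draws, and reports the buffering ratio
    ``mean(controlled) / mean(knockout)``.  The same controller is applied to
    the no-gap network unless ``controller_nogap`` is given.
    """
    if controller_nogap is None:
        controller_nogap = controller
    if n_env is None:
        n_env = mut_spec.n_mutations
    results = []
    for label, net, ctrl in (
        ("gap", network_gap, controller),
        ("no-gap", network_nogap, controller_nogap),
    ):
        env_draws = env_ensemble.sample(n_env)
        for condition in ("environmental", "mutational"):
            results.append(
                _buffering_cell(net, ctrl, label, condition, mut_spec, env_draws, mode)
            )
    return results


def _variance_fractions(samples: np.ndarray) -> np.ndarray:
    X = samples - samples.mean(axis=0, keepdims=True)
    svals = np.linalg.svd(X, compute_uv=False)
    var = svals**2
    return var / var.sum()


def knockout_dimensionality_experiment(
    network: GeneNetwork,
    controller: Controller,
    env_ensemble: PerturbationEnsemble,
    n_perturbations: int = 200,
    mode: str = "linearized",
) -> DimensionalityResult:
    """PCA of environmental steady states with and without the controller.

    The same environmental draws feed both arms; each response cloud is
    mean-centered before its variance fractions are computed.
    """
    if n_perturbations < 2:
        raise ValueError("need at least 2 perturbations")
    env_draws = env_ensemble.sample(n_perturbations)
    on, ex_on = environmental_deviations(network, controller, env_draws, mode)
    off, ex_off = environmental_deviations(
        network, knockout(controller), env_draws, mode
    )
    return DimensionalityResult(
        controlled_variance_fractions=_variance_fractions(on),
        knockout_variance_fractions=_variance_fractions(off),
        n_excluded=ex_on + ex_off,
    )


# ---------------------------------------------------------------------------
# Alignment of mutational and environmental impacts
# ---------------------------------------------------------------------------


def _paired_mean_abs_cosine(A: np.ndarray, B: np.ndarray) -> float:
    m = min(A.shape[0], B.shape[0])
    An = A[:m] / np.linalg.norm(A[:m], axis=1, keepdims=True)
    Bn = B[:m] / np.linalg.norm(B[:m], axis=1, keepdims=True)
    return float(np.mean(np.abs(np.sum(An * Bn, axis=1))))


def alignment_score(
    system: Union[GeneNetwork, SpectralModel, LinearSystem],
    mut_spec: MutationSpec,
    env_ensemble: PerturbationEnsemble,
    n_env: Optional[int] = None,
) -> float:
    """Mean absolute cosine between mutational and environmental deviations.

    Both perturbation families relax through the same response matrix; with a
    pronounced mode gap both clouds collapse onto the slow mode and the score
    approaches 1.  For linear systems the "mutations" are random static
    forcings drawn like the environmental ones but from an independent
    stream.
    """
    if n_env is None:
        n_env = mut_spec.n_mutations
    if isinstance(system, GeneNetwork):
        dev_mut, _ = mutational_deviations(system, None, mut_spec)
        env_draws = env_ensemble.sample(n_env)
        dev_env, _ = environmental_deviations(system, None, env_draws)
    else:
        D = (
            system.response_matrix()
            if isinstance(system, SpectralModel)
            else -np.linalg.inv(system.jacobian)
        )
        rng = np.random.default_rng(np.random.SeedSequence([mut_spec.seed, 1]))
        dg = rng.normal(0.0, mut_spec.magnitude, (mut_spec.n_mutations, D.shape[0]))
        dev_mut = dg @ D.T
        dev_env = env_ensemble.sample(n_env) @ D.T
    return _paired_mean_abs_cosine(dev_mut, dev_env)
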