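"""In-silico evolution of networks under selection for homeostasis.

A simulated-annealing Metropolis chain perturbs the interaction parameters
(and optionally the controller) and accepts moves with probability
``min(1, exp(-delta_cost / T))``.  The cost is the residual per-gene relative
deviation from the fixed point under an ensemble of static environmental
perturbations, multiplied by a stiffness normalizer so that uniformly
rescaling every relaxation rate buys nothing.

Two cost choices matter and are deliberate:

* deviations are measured relative to each gene's wild-type level
  (``delta_n_a / n_wt_a``); measuring ``||delta_n|| / ||n_wt||`` instead lets
  evolution concentrate all expression in one gene, which collapses the
  effective forcing to one dimension and removes any pressure on the
  spectrum;
* the stiffness normalizer is the *geometric* mean of the relaxation rates.
  It is invariant under uniform rescaling of the dynamics, and—unlike the
  arithmetic mean, whose slow-mode benefit saturates at ``(N-1)/N``—it
  rewards a deepening mode gap monotonically (``~ gap^(-1/N)``), which is
  what lets the low-complexity arm evolve a soft mode at desk scale.

By default only the network is mutated: the controller is a fixed random
projection, as in the selection protocol this models.  A controller facing a
pronounced slow mode cancels it automatically (the response matrix is
dominated by the soft direction), so network-side evolution suffices; a
co-adapting optimal controller would instead flatten the landscape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

import numpy as np

from softmode.controller import Controller
from softmode.grn_dynamics import (
    DegenerateFixedPointError,
    EnvForcing,
    FixedPointError,
    GeneNetwork,
    find_fixed_point,
    linearize,
    mode_gap,
    steady_state_deviation,
)
from softmode.linear_theory import linear_steady_state

__all__ = [
    "FitnessConfig",
    "AnnealConfig",
    "EvolutionTrace",
    "fitness_cost",
    "propose",
    "anneal",
]

_STIFFNESS_MODES = ("none", "arithmetic", "geometric")


@dataclass
class FitnessConfig:
    """How the homeostasis cost is sampled and evaluated."""

    n_env_samples: int = 20
    env_sd: float = 0.1
    eval_mode: str = "linearized"  # or "ode"
    stiffness_norm: Union[bool, str] = "geometric"

    def __post_init__(self) -> None:
        if self.n_env_samples < 1:
            raise ValueError("n_env_samples must be >= 1")
        if self.env_sd <= 0:
            raise ValueError("env_sd must be positive")
        if self.eval_mode not in ("linearized", "ode"):
            raise ValueError(f"unknown eval_mode {self.eval_mode!r}")
        if self.stiffness_norm is True:
            self.stiffness_norm = "geometric"
        elif self.stiffness_norm is False:
            self.stiffness_norm = "none"
        if self.stiffness_norm not in _STIFFNESS_MODES:
            raise ValueError(f"unknown stiffness_norm {self.stiffness_norm!r}")


@dataclass
class AnnealConfig:
    """Annealing schedule and proposal distribution.

    The default temperatures are low relative to the cost scale (near-greedy
    descent with rare uphill moves): the per-move fitness gradient toward a
    soft mode is of order 1% of the cost, so higher temperatures random-walk
    over it.  Interaction parameters are clipped to ``k_bounds`` /
    ``K_bounds`` after each move, bounding the achievable stiffness the way
    saturating kinetics bound real rates.
    """

    n_steps: int = 2000
    T_init: float = 1e-4
    T_final: float = 1e-7
    cooling: str = "geometric"
    proposal_sd: float = 0.2
    mutate_network: bool = True
    mutate_controller: bool = False
    k_bounds: Tuple[float, float] = (0.25, 4.0)
    K_bounds: Tuple[float, float] = (0.1, 10.0)
    min_expression: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not self.T_init >= self.T_final > 0:
            raise ValueError("require T_init >= T_final > 0")
        if self.cooling != "geometric":
            raise ValueError(f"unknown cooling schedule {self.cooling!r}")
        if self.proposal_sd < 0:
            raise ValueError("proposal_sd must be >= 0")

    def temperature(self, step: int) -> float:
        if self.n_steps == 1:
            return self.T_init
        frac = step / (self.n_steps - 1)
        return self.T_init * (self.T_final / self.T_init) ** frac


@dataclass
class EvolutionTrace:
    """Per-step annealing record plus the best-so-far (elitist) snapshot."""

    records: List[dict] = field(default_factory=list)
    best_network: Optional[GeneNetwork] = None
    best_controller: Optional[Controller] = None
    best_cost: float = math.inf

    def append(self, **kwargs) -> None:
        self.records.append(kwargs)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.records)

    @property
    def final_cost(self) -> float:
        return self.records[-1]["cost"]

    @property
    def final_mode_gap(self) -> float:
        return self.records[-1]["mode_gap"]


def _relative_deviation_norms(
    network: GeneNetwork,
    controller: Optional[Controller],
    env_draws: np.ndarray,
    eval_mode: str,
) -> np.ndarray:
    """Per-draw ``||delta_n / n_wt|| / sqrt(N)`` for multiplicative forcing."""
    n_wt = network.n_wt
    root_n = math.sqrt(network.n_genes)
    if eval_mode == "linearized":
        lin = linearize(network)
        if not lin.stable:
            return np.full(env_draws.shape[0], np.inf)
        eff = env_draws * n_wt[None, :]
        try:
            if controller is None or controller.is_null:
                X = linear_steady_state(lin.jacobian, eff)
            else:
                X = linear_steady_state(
                    lin.jacobian,
                    eff,
                    controller.sense_mat,
                    controller.action_mat,
                    controller.c_p,
                    controller.c_i,
                )
        except np.linalg.LinAlgError:
            return np.full(env_draws.shape[0], np.inf)
        return np.linalg.norm(X / n_wt[None, :], axis=1) / root_n
    norms = np.empty(env_draws.shape[0])
    for i, de in enumerate(env_draws):
        res = steady_state_deviation(
            network, EnvForcing(de, mode="multiplicative"), controller
        )
        norms[i] = np.linalg.norm(res.delta_n / n_wt) / root_n
    return norms


def _stiffness(lin, mode: str) -> float:
    lam = np.abs(lin.eigvals.real)
    if mode == "arithmetic":
        return float(lam.mean())
    if mode == "geometric":
        return float(np.exp(np.mean(np.log(lam))))
    return 1.0


def fitness_cost(
    network: GeneNetwork,
    controller: Optional[Controller],
    fit_cfg: FitnessConfig,
    seed: Optional[int] = None,
    env_draws: Optional[np.ndarray] = None,
) -> float:
    """Mean relative deviation over environmental draws, stiffness-normalized.

    ``mean_j ||delta_n_j / n_wt|| / sqrt(N)`` times the stiffness normalizer
    (geometric mean of ``|Re lambda_i|`` by default).  Networks without a
    stable fixed point cost ``inf`` (auto-rejected by the annealer).
    """
    if network.n_wt is None:
        raise ValueError("network needs a solved fixed point")
    if env_draws is None:
        rng = np.random.default_rng(seed)
        env_draws = rng.normal(
            0.0, fit_cfg.env_sd, (fit_cfg.n_env_samples, network.n_genes)
        )
    lin = linearize(network)
    if not lin.stable:
        return math.inf
    norms = _relative_deviation_norms(network, controller, env_draws, fit_cfg.eval_mode)
    if not np.all(np.isfinite(norms)):
        return math.inf
    return float(np.mean(norms)) * _stiffness(lin, fit_cfg.stiffness_norm)


def _jitter_subset(
    values: np.ndarray, mask: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    out = values.copy()
    if sd == 0:
        return out
    nz = np.flatnonzero(mask.ravel())
    if nz.size == 0:
        return out
    # expect ~2 mutated entries per proposal, at least one
    p_hit = min(1.0, 2.0 / nz.size)
    hit = nz[rng.random(nz.size) < p_hit]
    if hit.size == 0:
        hit = nz[[rng.integers(nz.size)]]
    flat = out.ravel()
    flat[hit] *= np.exp(sd * rng.standard_normal(hit.size))
    return out


def propose(
    network: GeneNetwork,
    controller: Optional[Controller],
    proposal_sd: float,
    rng: np.random.Generator,
    mutate_network: bool = True,
    mutate_controller: bool = False,
    k_bounds: Optional[Tuple[float, float]] = None,
    K_bounds: Optional[Tuple[float, float]] = None,
) -> Tuple[GeneNetwork, Optional[Controller]]:
    """Multiplicative log-normal jitter on a random subset of parameters.

    Network moves touch nonzero ``k_ab`` and all ``K_ab`` entries, clipped to
    the given bounds; controller moves jitter sensing rows
    (re-orthonormalized afterwards) and action columns (re-normalized).
    Deterministic given the generator state.
    """
    new_net = network
    if mutate_network:
        k_mat = _jitter_subset(network.k_mat, network.k_mat != 0, proposal_sd, rng)
        K_mat = _jitter_subset(
            network.K_mat, np.ones_like(network.K_mat, bool), proposal_sd, rng
        )
        if k_bounds is not None:
            k_mat = np.where(k_mat != 0, np.clip(k_mat, *k_bounds), 0.0)
        if K_bounds is not None:
            K_mat = np.clip(K_mat, *K_bounds)
        new_net = network.with_params(k_mat, K_mat)
    new_ctrl = controller
    if controller is not None and mutate_controller and proposal_sd > 0:
        shape = controller.sense_mat.shape
        kick = proposal_sd * 0.5 * rng.standard_normal(shape)
        kick *= rng.random(shape) < min(1.0, 2.0 / controller.sense_mat.size)
        sense = controller.sense_mat + kick
        q, _ = np.linalg.qr(sense.T)
        sense = q.T[: controller.k_channels]
        # keep row orientation consistent with the previous sensing rows
        signs = np.sign(np.sum(sense * controller.sense_mat, axis=1))
        signs[signs == 0] = 1.0
        sense = sense * signs[:, None]
        a_shape = controller.action_mat.shape
        a_kick = proposal_sd * 0.5 * rng.standard_normal(a_shape)
        a_kick *= rng.random(a_shape) < min(1.0, 2.0 / controller.action_mat.size)
        action = controller.action_mat + a_kick
        nrm = np.linalg.norm(action, axis=0, keepdims=True)
        nrm[nrm == 0] = 1.0
        new_ctrl = Controller(
            sense_mat=sense,
            action_mat=action / nrm,
            c_p=controller.c_p,
            c_i=controller.c_i,
        )
    return new_net, new_ctrl


def anneal(
    network: GeneNetwork,
    controller: Optional[Controller],
    fit_cfg: FitnessConfig,
    anneal_cfg: AnnealConfig,
) -> EvolutionTrace:
    """Simulated-annealing chain; bit-reproducible given config and seed.

    Within each step the current and proposed parameters are scored on the
    same environmental draws (common random numbers), so acceptance decisions
    compare like with like.  Proposals whose fixed point cannot be found, is
    degenerate, leaves the interior, or is unstable are rejected outright.
    """
    rng = np.random.default_rng(anneal_cfg.seed)
    cur_net = network.copy()
    if network.n_wt is None:
        find_fixed_point(cur_net)
    else:
        cur_net.n_wt = network.n_wt.copy()
    cur_ctrl = controller.copy() if controller is not None else None

    trace = EvolutionTrace()
    for step in range(anneal_cfg.n_steps):
        T = anneal_cfg.temperature(step)
        env_draws = rng.normal(
            0.0, fit_cfg.env_sd, (fit_cfg.n_env_samples, cur_net.n_genes)
        )
        cost_cur = fitness_cost(cur_net, cur_ctrl, fit_cfg, env_draws=env_draws)
        prop_net, prop_ctrl = propose(
            cur_net,
            cur_ctrl,
            anneal_cfg.proposal_sd,
            rng,
            mutate_network=anneal_cfg.mutate_network,
            mutate_controller=anneal_cfg.mutate_controller,
            k_bounds=anneal_cfg.k_bounds,
            K_bounds=anneal_cfg.K_bounds,
        )
        accepted = False
        if anneal_cfg.mutate_network:
            try:
                fp = find_fixed_point(
                    prop_net, guess=np.maximum(cur_net.n_wt, anneal_cfg.min_expression)
                )
                if np.min(fp) < anneal_cfg.min_expression:
                    prop_net = None
            except (FixedPointError, DegenerateFixedPointError):
                prop_net = None
        else:
            prop_net = cur_net
        if prop_net is not None:
            cost_prop = fitness_cost(prop_net, prop_ctrl, fit_cfg, env_draws=env_draws)
            if math.isfinite(cost_prop):
                delta = cost_prop - cost_cur
                if delta <= 0 or rng.random() < math.exp(-delta / T):
                    accepted = True
                    cur_net, cur_ctrl, cost_cur = prop_net, prop_ctrl, cost_prop
        gap = mode_gap(linearize(cur_net))
        if accepted and cost_cur < trace.best_cost:
            trace.best_cost = cost_cur
            trace.best_network = cur_net.copy()
            trace.best_network.n_wt = cur_net.n_wt.copy()
            trace.best_controller = cur_ctrl.copy() if cur_ctrl is not None else None
        trace.append(
            step=step,
            cost=cost_cur,
            accepted=accepted,
            temperature=T,
            mode_gap=gap,
        )
    if trace.best_network is None:  # nothing accepted: fall back to the start
        trace.best_network = cur_net
        trace.best_controller = cur_ctrl
        trace.best_cost = trace.records[-1]["cost"]
    return trace
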