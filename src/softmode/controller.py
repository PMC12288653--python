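"""Low-dimensional proportional-integral controllers.

A controller with complexity ``k`` projects the N-dimensional deviation from
the wild-type fixed point onto ``k`` orthonormal sensing directions, forms a
PI error signal per channel, and pushes back along per-channel action vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np

from softmode.grn_dynamics import ShapeError

__all__ = ["Controller", "ControlAction", "make_random_controller", "knockout"]


@dataclass
class ControlAction:
    """Per-channel sensed errors and the resulting state-space action."""

    sensed: np.ndarray  # k-vector s_i . delta_n (also d/dt of the integrals)
    action: np.ndarray  # N-vector sum_i g^(i) I_i


@dataclass
class Controller:
    """k-channel PI controller.

    Parameters
    ----------
    sense_mat
        ``(k, N)`` sensing vectors; rows unit-norm, linearly independent.
    action_mat
        ``(N, k)`` action vectors, one column per channel (rate units).
    c_p, c_i
        Proportional and integral gains, shared across channels.
    """

    sense_mat: np.ndarray
    action_mat: np.ndarray
    c_p: float = 1.0
    c_i: float = 1.0

    def __post_init__(self) -> None:
        self.sense_mat = np.atleast_2d(np.asarray(self.sense_mat, dtype=float))
        self.action_mat = np.atleast_2d(np.asarray(self.action_mat, dtype=float))
        k, n = self.sense_mat.shape
        if self.action_mat.shape != (n, k):
            raise ShapeError(
                f"action_mat must be ({n}, {k}), got {self.action_mat.shape}"
            )
        if k > n:
            raise ValueError(f"controller complexity k={k} exceeds n_genes={n}")
        if self.c_p < 0 or self.c_i < 0:
            raise ValueError("gains must be non-negative")
        row_norms = np.linalg.norm(self.sense_mat, axis=1)
        if not np.allclose(row_norms, 1.0, atol=1e-8):
            raise ValueError("sense_mat rows must have unit norm")
        if np.linalg.matrix_rank(self.sense_mat) < k:
            raise ValueError("sense_mat rows must be linearly independent")

    @property
    def k_channels(self) -> int:
        return self.sense_mat.shape[0]

    @property
    def n_genes(self) -> int:
        return self.sense_mat.shape[1]

    @property
    def is_null(self) -> bool:
        """True when both gains are zero (the action vanishes identically)."""
        return self.c_p == 0.0 and self.c_i == 0.0

    def control_terms(
        self, delta_n: np.ndarray, integral_state: np.ndarray
    ) -> ControlAction:
        """Evaluate sensed errors and the action for the current deviation.

        ``I_i = c_p (s_i . delta_n) + c_i * integral_state_i`` and the action
        is ``action_mat @ I``.  The returned ``sensed`` vector is the time
        derivative of the integral accumulators.
        """
        delta_n = np.asarray(delta_n, dtype=float)
        integral_state = np.asarray(integral_state, dtype=float)
        if delta_n.shape != (self.n_genes,):
            raise ShapeError("delta_n length does not match controller")
        if integral_state.shape != (self.k_channels,):
            raise ShapeError("integral_state length does not match k_channels")
        sensed = self.sense_mat @ delta_n
        errors = self.c_p * sensed + self.c_i * integral_state
        return ControlAction(sensed=sensed, action=self.action_mat @ errors)

    def copy(self) -> "Controller":
        return Controller(
            sense_mat=self.sense_mat.copy(),
            action_mat=self.action_mat.copy(),
            c_p=self.c_p,
            c_i=self.c_i,
        )


def make_random_controller(
    n_genes: int,
    k: int,
    seed: Optional[Union[int, np.random.Generator]] = None,
    c_p: float = 1.0,
    c_i: float = 1.0,
) -> Controller:
    """Isotropically random controller: orthonormal sensing rows, unit action
    columns.  Deterministic given ``seed``."""
    if not 1 <= k <= n_genes:
        raise ValueError(f"need 1 <= k <= n_genes, got k={k}, n_genes={n_genes}")
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n_genes, k))
    q, _ = np.linalg.qr(raw)
    sense = q.T[:k]
    action = rng.standard_normal((n_genes, k))
    action = action / np.linalg.norm(action, axis=0, keepdims=True)
    return Controller(sense_mat=sense, action_mat=action, c_p=c_p, c_i=c_i)


def knockout(controller: Controller) -> Controller:
    """Zero-gain copy: structure preserved, action identically zero."""
    return replace(controller.copy(), c_p=0.0, c_i=0.0)
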