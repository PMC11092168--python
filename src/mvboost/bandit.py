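"""Adversarial multi-armed bandit over views.

Each view is an arm.  Arm-selection probabilities follow an exponentially
weighted average (EWA) forecaster of the EXP3.P family: the probability of
an arm depends exponentially on its cumulative importance-weighted reward,
mixed with a uniform exploration term,

    p_j = (1 - gamma) * exp(sigma * R_j) / sum_k exp(sigma * R_k) + gamma / K

where ``R_j`` accumulates ``reward / p_j`` for the rounds in which arm j was
played.  Dividing the observed reward by the selection probability gives an
unbiased estimate of every arm's reward and encourages low-probability arms,
promoting diversity among the selected views.  No distributional assumption
is made about the rewards (the adversarial setting).

``sigma`` (> 0) is the learning rate; ``gamma`` in (0, 1) the exploration
rate, guaranteeing the floor ``p_j >= gamma / K``.  The softmax is
stabilized by subtracting ``max_k sigma * R_k`` before exponentiation, which
leaves the probabilities unchanged (translation invariance) but keeps the
exponentials bounded however large the cumulative rewards grow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import ParameterError

__all__ = [
    "BanditState",
    "init_bandit",
    "select_view",
    "importance_weighted_reward",
    "update_bandit",
    "DEFAULT_SIGMA",
    "DEFAULT_GAMMA",
]

DEFAULT_SIGMA = 0.15
DEFAULT_GAMMA = 0.3


@dataclass
class BanditState:
    K: int
    p: np.ndarray
    R: np.ndarray
    sigma: float
    gamma: float
    rng: np.random.Generator = field(repr=False)


def init_bandit(
    K: int,
    sigma: float = DEFAULT_SIGMA,
    gamma: float = DEFAULT_GAMMA,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BanditState:
    """Uniform probabilities, zero cumulative rewards, seeded generator.

    ``rng`` may be passed instead of ``seed`` to share one pseudo-random
    stream with a surrounding algorithm.
    """
    if K < 1:
        raise ParameterError(f"need at least one arm, got K={K}")
    if sigma <= 0:
        raise ParameterError(f"sigma must be > 0, got {sigma}")
    if not 0 < gamma < 1:
        raise ParameterError(f"gamma must be in (0, 1), got {gamma}")
    if rng is None:
        rng = np.random.default_rng(seed)
    return BanditState(
        K=K,
        p=np.full(K, 1.0 / K),
        R=np.zeros(K),
        sigma=float(sigma),
        gamma=float(gamma),
        rng=rng,
    )


def select_view(state: BanditState) -> int:
    """Sample an arm (0-based) from the categorical distribution ``p``."""
    u = state.rng.random()
    return int(np.searchsorted(np.cumsum(state.p), u, side="right").clip(0, state.K - 1))


def importance_weighted_reward(raw_reward: float, p_j: float) -> float:
    """Observed reward divided by the probability of the played arm."""
    if p_j <= 0:
        raise ParameterError(f"selection probability must be positive, got {p_j}")
    return raw_reward / p_j


def update_bandit(state: BanditState, j: int, reward: float) -> BanditState:
    """Credit arm j with the importance-weighted reward and recompute ``p``.

    Updates the state in place (and returns it).  The division uses the
    probability under which j was actually selected, i.e. ``p`` before the
    recomputation.
    """
    if not 0 <= j < state.K:
        raise ParameterError(f"arm index {j} out of range for K={state.K}")
    state.R[j] += importance_weighted_reward(reward, state.p[j])
    _recompute_p(state)
    return state


def _recompute_p(state: BanditState) -> None:
    z = state.sigma * state.R
    z = z - z.max()  # log-sum-exp stabilization; p is translation invariant
    e = np.exp(z)
    state.p = (1.0 - state.gamma) * e / e.sum() + state.gamma / state.K
    if not np.isfinite(state.p).all():  # pragma: no cover
        raise FloatingPointError("bandit probabilities overflowed")
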