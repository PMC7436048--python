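"""Continuous grey wolf optimizer core: pack state, coefficient draws, update rules.

The grey wolf optimizer maintains a pack of search agents whose continuous
positions are pulled toward the three current best solutions (the alpha, beta
and delta leaders).  The exploration/exploitation balance is governed by a
scalar ``a`` that decays linearly from 2 to 0 over the run; each agent draws
fresh random coefficient vectors A (in [-a, a]) and C (in [0, 2]) per leader,
per dimension, per iteration.

This module is agnostic of binarization: positions stay continuous and binary
inclusion masks are derived views handled elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_LEADERS = 3


@dataclass(frozen=True)
class SearchConfig:
    """Pack size, iteration budget and problem dimension.

    ``n_agents`` must be at least 4 so the three leaders still leave one
    follower (omega) to be guided.
    """

    n_agents: int = 40
    n_iterations: int = 30
    dimension: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 4:
            raise ValueError("n_agents must be >= 4 (three leaders plus at least one omega)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be positive")
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")


@dataclass
class Leader:
    """One leader: continuous position, derived binary mask, and its fitness."""

    position: np.ndarray
    mask: np.ndarray
    fitness: float


@dataclass
class PackState:
    """Positions, masks and fitnesses of all agents at one iteration.

    Invariant: leader fitnesses are sorted, f(alpha) <= f(beta) <= f(delta).
    """

    positions: np.ndarray
    masks: np.ndarray
    fitnesses: np.ndarray
    leaders: list[Leader] = field(default_factory=list)
    iteration: int = 0

    @property
    def n_agents(self) -> int:
        return self.positions.shape[0]

    @property
    def dimension(self) -> int:
        return self.positions.shape[1]


@dataclass
class CoefficientDraw:
    """Per-agent random coefficients for one update: A_i, C_i and distances D_i.

    ``A`` and ``C`` have shape (3, D) — one row per leader.  ``D_lead`` holds
    the leader distances |C_i * X_leader_i - X| once computed.
    """

    a: float
    A: np.ndarray
    C: np.ndarray
    D_lead: np.ndarray | None = None


def linear_schedule(t: int, m_iter: int) -> float:
    """Exploration coefficient a = 2 - t * 2 / m_iter, decaying linearly 2 -> 0."""
    if not 0 <= t <= m_iter:
        raise ValueError(f"iteration index {t} outside [0, {m_iter}]")
    return 2.0 - t * 2.0 / m_iter


def draw_coefficients(a: float, dimension: int, rng: np.random.Generator) -> CoefficientDraw:
    """Draw A = 2a*r1 - a and C = 2*r2 componentwise, independently per leader.

    r1, r2 ~ U(0,1); every component of A lies in [-a, a] and of C in [0, 2].
    """
    if not 0.0 <= a <= 2.0:
        raise ValueError("a must lie in [0, 2]")
    r1 = rng.random((N_LEADERS, dimension))
    r2 = rng.random((N_LEADERS, dimension))
    return CoefficientDraw(a=a, A=2.0 * a * r1 - a, C=2.0 * r2)


def leader_guided_update(
    position: np.ndarray, leaders: list[Leader], coeffs: CoefficientDraw
) -> np.ndarray:
    """New continuous position: mean of the three leader-attraction terms.

    For each leader i: D_i = |C_i * X_leader_i - X| and X_i = |X_leader_i - A_i * D_i|;
    the update returns (X_1 + X_2 + X_3) / 3.  Both absolute values are applied
    componentwise exactly as in the canonical formulation, so the output is
    componentwise nonnegative.  The computed D_i are stored on ``coeffs`` for
    reuse by the Gaussian-CDF leader-vote binarization.
    """
    position = np.asarray(position, dtype=float)
    lead_pos = np.stack([ld.position for ld in leaders])  # (3, D)
    if lead_pos.shape[1] != position.shape[0]:
        raise ValueError("dimension mismatch between position and leaders")
    D_lead = np.abs(coeffs.C * lead_pos - position[None, :])
    X_i = np.abs(lead_pos - coeffs.A * D_lead)
    coeffs.D_lead = D_lead
    return X_i.mean(axis=0)


def update_leaders(pack: PackState) -> PackState:
    """Refresh the alpha/beta/delta triple: the three agents with smallest fitness.

    Ties are broken by lower agent index (stable sort), so equal-fitness agents
    keep a deterministic order.
    """
    if np.any(~np.isfinite(pack.fitnesses)):
        raise RuntimeError("cannot update leaders: uncomputed fitness present")
    order = np.argsort(pack.fitnesses, kind="stable")
    pack.leaders = [
        Leader(
            position=pack.positions[i].copy(),
            mask=pack.masks[i].copy(),
            fitness=float(pack.fitnesses[i]),
        )
        for i in order[:N_LEADERS]
    ]
    return pack
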