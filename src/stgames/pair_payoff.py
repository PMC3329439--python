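"""Stationary pair play and the 16x16 expected payoff matrix.

Two memory-one strategies playing an iterated game form a Markov chain over
the four outcome states (CC, CD, DC, DD).  The transition probability from
state ``XY`` factorizes as the product of the focal player's cooperation
probability in ``XY`` and the opponent's cooperation probability in ``YX``
(the opponent sees CD and DC exchanged).  In the limit of an infinitely
repeated game (continuation probability -> 1) the expected per-round payoff
of the focal player is the dot product of the chain's stationary
distribution with the payoff vector (R, S, T, P).

With implementation error ``eps > 0`` for both players the chain is strictly
positive, hence irreducible, and the stationary distribution is unique.
``eps = 0`` is allowed here for limit and oracle checks; reducible chains are
then flagged with a warning and an arbitrary stationary vector is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .game_space import OPPONENT_VIEW, Game, Strategy, enumerate_strategies

_ROW_SUM_TOL = 1e-12
_STATIONARY_TOL = 1e-10


@dataclass(frozen=True)
class PairChain:
    """The 4-state Markov chain of a focal/opponent strategy pair."""

    M: np.ndarray
    focal: Strategy
    opponent: Strategy

    def __post_init__(self):
        if self.M.shape != (4, 4):
            raise ValueError("pair chain must be 4x4")
        if np.any(np.abs(self.M.sum(axis=1) - 1.0) > _ROW_SUM_TOL):
            raise ValueError("pair chain rows must sum to 1")


@dataclass(frozen=True)
class StationaryDistribution:
    """Stationary probabilities of (CC, CD, DC, DD)."""

    v: np.ndarray

    def __post_init__(self):
        if self.v.shape != (4,) or np.any(self.v < -_STATIONARY_TOL):
            raise ValueError("invalid stationary vector")


@dataclass(frozen=True)
class PayoffMatrix:
    """Expected per-round payoffs between all ordered strategy pairs.

    ``W[i, j]`` is the payoff of the strategy with canonical index ``i``
    (code = ``i`` in binary) against index ``j``, in the order of
    :func:`stgames.game_space.enumerate_strategies`.
    """

    W: np.ndarray
    game: Game
    eps: float

    def to_dataframe(self):
        import pandas as pd

        from .game_space import code_of_index

        codes = [code_of_index(i) for i in range(16)]
        return pd.DataFrame(self.W, index=codes, columns=codes)


def build_pair_chain(focal: Strategy, opponent: Strategy) -> PairChain:
    """Transition matrix of the pair chain.

    Row ``XY`` is the outer product of the focal player's (cooperate,
    defect) probabilities in state ``XY`` with the opponent's in state
    ``YX``, flattened in the (CC, CD, DC, DD) order.
    """
    p = focal.probs
    q = opponent.probs[list(OPPONENT_VIEW)]
    M = np.empty((4, 4))
    for s in range(4):
        M[s] = (p[s] * q[s], p[s] * (1 - q[s]), (1 - p[s]) * q[s], (1 - p[s]) * (1 - q[s]))
    return PairChain(M=M, focal=focal, opponent=opponent)


def stationary_distribution(chain: PairChain) -> StationaryDistribution:
    """Unique left eigenvector of the pair chain for eigenvalue 1.

    Solved as the linear system (v M = v, sum v = 1) for determinism and
    accuracy.  When the chain is reducible (possible only at eps = 0) the
    system is singular; a warning is issued and one stationary vector is
    returned via least squares.
    """
    M = chain.M
    A = M.T - np.eye(4)
    A[3, :] = 1.0
    b = np.array([0.0, 0.0, 0.0, 1.0])
    try:
        v = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        v = None
    if v is None or np.any(v < -1e-9) or np.max(np.abs(v @ M - v)) > _STATIONARY_TOL:
        warnings.warn(
            "pair chain is reducible (eps = 0?); returning one stationary vector",
            RuntimeWarning,
            stacklevel=2,
        )
        # Least-squares solve of the full (over-determined) stationarity system.
        A_full = np.vstack([M.T - np.eye(4), np.ones(4)])
        b_full = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
        v, *_ = np.linalg.lstsq(A_full, b_full, rcond=None)
    v = np.clip(v, 0.0, None)
    return StationaryDistribution(v=v / v.sum())


def expected_payoff(focal: Strategy, opponent: Strategy, game: Game) -> float:
    """Expected per-round payoff of ``focal`` against ``opponent``."""
    v = stationary_distribution(build_pair_chain(focal, opponent)).v
    return float(v @ game.payoff_vector())


def payoff_matrix(game: Game, eps: float) -> PayoffMatrix:
    """The full 16x16 expected payoff matrix at error rate ``eps``."""
    strategies = enumerate_strategies(eps)
    W = np.empty((16, 16))
    payoffs = game.payoff_vector()
    for i, si in enumerate(strategies):
        for j, sj in enumerate(strategies):
            v = stationary_distribution(build_pair_chain(si, sj)).v
            W[i, j] = v @ payoffs
    return PayoffMatrix(W=W, game=game, eps=eps)


@njit(cache=False)
def _simulate_states(M_cum: np.ndarray, rounds: int, seed: int) -> np.ndarray:
    """Sample a trajectory of the 4-state pair chain; returns state counts."""
    np.random.seed(seed)
    counts = np.zeros(4, dtype=np.int64)
    # Start from the uniform distribution over states; with eps > 0 the
    # stationary distribution is approached geometrically fast regardless.
    u = np.random.random()
    state = 0
    while state < 3 and u > 0.25 * (state + 1):
        state += 1
    for _ in range(rounds):
        u = np.random.random()
        nxt = 0
        while nxt < 3 and u > M_cum[state, nxt]:
            nxt += 1
        state = nxt
        counts[state] += 1
    return counts


def simulate_play(
    focal: Strategy, opponent: Strategy, game: Game, rounds: int, seed: int
) -> tuple[float, float]:
    """Direct Monte-Carlo play-out of the iterated game.

    Both players execute their intended actions with per-action error built
    into their cooperation probabilities.  Returns the empirical mean
    per-round payoff of the focal player and its standard error.  Serves as
    an independent check on :func:`expected_payoff`.
    """
    chain = build_pair_chain(focal, opponent)
    M_cum = np.cumsum(chain.M, axis=1)
    counts = _simulate_states(M_cum, rounds, seed)
    freqs = counts / rounds
    payoffs = game.payoff_vector()
    mean = float(freqs @ payoffs)
    var = float(freqs @ (payoffs - mean) ** 2)
    # Effective sample size correction for autocorrelation of the state
    # sequence: integrated autocorrelation time bounded via the chain's
    # second-largest eigenvalue modulus.
    lam = sorted(abs(np.linalg.eigvals(chain.M)))[-2]
    lam = min(float(lam), 0.999)
    tau_int = (1 + lam) / (1 - lam)
    se = float(np.sqrt(var * tau_int / rounds))
    return mean, se
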