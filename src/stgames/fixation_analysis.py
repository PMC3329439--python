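"""Fixation probabilities of single mutants and the fixation-based chain.

With two strategies present, the imitation dynamics is a birth-death chain
on the number ``k`` of mutants, with absorbing ends at 0 and N.  The per-step
birth probability ``b_k`` (a resident imitates a mutant) combines the
probability of drawing a resident-mutant pair with the linear imitation
probability evaluated at the mixture payoffs; ``d_k`` is the reverse event.
The probability that a single mutant eventually takes over is the classical
absorption formula

    rho = 1 / (1 + sum_{k=1}^{N-1} prod_{j=1}^{k} d_j / b_j),

accumulated in log space to remain finite under strong selection.

A lower bound on the mean absorption time certifies quasi-stationarity of
anti-coordination pairs: the chain must, with the first-passage probability,
reach an interior state and spend there the expected sojourn before escaping
for good, so

    t >= max_k  P(reach k from 1) * E[steps spent at k]

which grows exponentially with N inside a stochastic well while remaining
below the exact linear-solve time for neutral pairs.

The fixation-based Markov chain replaces simulated invasion outcomes with
fixation probabilities: its 16 nodes are the homogeneous populations and the
edge resident -> mutant carries ``rho(resident, mutant)``, with weights
below a pruning threshold dropped.  By construction it contains no mixed
node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .game_space import Game, code_of_index
from .markov_analysis import ChainMatrix
from .pair_payoff import payoff_matrix
from .population_dynamics import ImitationRule

__all__ = [
    "BirthDeathRates",
    "FixationResult",
    "FixationParams",
    "birth_death_rates",
    "fixation_probability",
    "fixation_time_lower_bound",
    "mean_absorption_time",
    "fixation_matrix",
    "build_fixation_chain",
]


@dataclass(frozen=True)
class BirthDeathRates:
    """Per-step birth/death probabilities of the two-strategy chain.

    ``b[k-1]`` and ``d[k-1]`` are the probabilities, with ``k`` mutants
    present (k = 1..N-1), that one step increases or decreases ``k``.
    """

    b: np.ndarray
    d: np.ndarray

    def __post_init__(self):
        if self.b.shape != self.d.shape or self.b.ndim != 1:
            raise ValueError("b and d must be 1-d arrays of equal length")
        for arr in (self.b, self.d):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError("rates must be probabilities")

    @property
    def N(self) -> int:
        return self.b.size + 1


@dataclass(frozen=True)
class FixationResult:
    rho: float
    time_lower_bound: float
    degenerate: bool = False


@dataclass(frozen=True)
class FixationParams:
    """Configuration of the fixation-based invasion chain.

    ``prune_threshold = None`` resolves to ``0.1 / N``: fixation
    probabilities scale with the neutral-drift value 1/N, so the cutoff
    separating "observable" from "negligible" transitions must follow that
    scale; 0.1/N keeps transitions an order of magnitude below drift out of
    the chain regardless of population size.  An absolute threshold can be
    supplied instead.
    """

    N: int = 1000
    eps: float = 0.01
    mu: float = 0.01
    prune_threshold: Optional[float] = None


def birth_death_rates(
    resident: int,
    mutant: int,
    game: Game,
    N: int,
    eps: float,
    rule: Optional[ImitationRule] = None,
) -> BirthDeathRates:
    """Birth/death probabilities for a mutant lineage in a resident population.

    Payoffs are expected payoffs against the self-excluded mixture of ``k``
    mutants and ``N - k`` residents; the pair-sampling factor counts ordered
    focal/opponent draws of unlike individuals.  Pass ``rule`` to reuse a
    precomputed payoff matrix (it fixes the global payoff-difference
    normalization).
    """
    if N < 2:
        raise ValueError("N must be at least 2")
    if resident == mutant:
        raise ValueError("resident and mutant must differ")
    if rule is None:
        rule = ImitationRule.from_payoff_matrix(payoff_matrix(game, eps))
    W = rule.W
    k = np.arange(1, N)
    pi_m = ((k - 1) * W[mutant, mutant] + (N - k) * W[mutant, resident]) / (N - 1)
    pi_r = (k * W[resident, mutant] + (N - k - 1) * W[resident, resident]) / (N - 1)
    pair = k * (N - k) / (N * (N - 1))
    dp = (pi_m - pi_r) / rule.delta_pi_max
    p_up = np.clip(0.5 * (1.0 + dp), 0.0, 1.0)
    return BirthDeathRates(b=pair * p_up, d=pair * (1.0 - p_up))


def fixation_probability(rates: BirthDeathRates) -> float:
    """Absorption probability at N of a single mutant (state k = 1)."""
    b, d = rates.b, rates.d
    if np.any(b == 0):
        warnings.warn("some birth rate is zero; fixation is impossible", RuntimeWarning)
        return 0.0
    log_cum = np.cumsum(np.log(d) - np.log(b))  # log prod_{j<=k} d_j/b_j, k=1..N-1
    log_denom = logsumexp(np.concatenate([[0.0], log_cum]))
    return float(np.exp(-log_denom))


def _log_sojourn_terms(rates: BirthDeathRates) -> np.ndarray:
    """Log of P(reach k from 1) * E[total steps spent at k], k = 1..N-1.

    ``gamma_k`` is the cumulative product of death/birth ratios; the
    first-passage probability of ever visiting ``k`` from a single mutant is
    ``1 / sum_{j<k} gamma_j`` and the expected total sojourn per visited
    state is the reciprocal of its never-return escape rate.
    """
    b, d = rates.b, rates.d
    n = b.size
    log_gamma = np.concatenate([[0.0], np.cumsum(np.log(d) - np.log(b))])  # k = 0..n
    log_Gm = np.array([logsumexp(log_gamma[:k]) for k in range(1, n + 1)])  # sum_{j<k}
    log_Gp = np.array([logsumexp(log_gamma[k:]) for k in range(1, n + 1)])  # sum_{j>=k}
    log_up = np.log(b) + log_gamma[1:] - log_Gp
    log_down = np.log(d) + log_gamma[:-1] - log_Gm
    log_escape = np.logaddexp(log_up, log_down)
    return -log_Gm - log_escape


def mean_absorption_time(rates: BirthDeathRates) -> float:
    """Exact mean absorption time (either end) from a single mutant.

    Decomposes the time into per-state total sojourns: each interior state
    contributes its first-passage probability times its expected total
    occupancy.  Evaluated in log space, so it stays finite where the time
    grows exponentially with N.  Measured in elementary time steps.
    """
    b, d = rates.b, rates.d
    if np.any(b == 0) or np.any(d == 0):
        raise ValueError("mean absorption time requires strictly positive rates")
    return float(np.exp(logsumexp(_log_sojourn_terms(rates))))


def fixation_time_lower_bound(rates: BirthDeathRates) -> float:
    """Lower bound on the mean absorption time from a single mutant.

    Measured in elementary (direct) time steps.  For every interior state
    ``k`` the chain reaches ``k`` from 1 with the first-passage probability
    ``1 / sum_{j<k} gamma_j`` (gamma_j the cumulative death/birth ratio
    products) and, once there, is expected to stay -- counting returns --
    for the reciprocal of its never-return escape rate.  The largest such
    product is reported; everything is evaluated in log space.
    """
    b, d = rates.b, rates.d
    if np.any(b == 0) or np.any(d == 0):
        return np.inf if np.any(b == 0) else 0.0
    return float(np.exp(np.max(_log_sojourn_terms(rates))))


def fixation_matrix(
    game: Game, N: int, eps: float, rule: Optional[ImitationRule] = None
) -> np.ndarray:
    """16x16 matrix of single-mutant fixation probabilities.

    Entry (a, b) is the probability that one individual of strategy ``b``
    introduced in a homogeneous population of ``a`` eventually fixes.
    Diagonal entries are zero.
    """
    if rule is None:
        rule = ImitationRule.from_payoff_matrix(payoff_matrix(game, eps))
    rho = np.zeros((16, 16))
    for a in range(16):
        for b in range(16):
            if a == b:
                continue
            rates = birth_death_rates(a, b, game, N, eps, rule=rule)
            rho[a, b] = fixation_probability(rates)
    return rho


def build_fixation_chain(game: Game, params: FixationParams) -> ChainMatrix:
    """Markov chain over the 16 homogeneous populations from fixation
    probabilities, with weights below ``prune_threshold`` dropped."""
    rho = fixation_matrix(game, params.N, params.eps)
    threshold = params.prune_threshold if params.prune_threshold is not None else 0.1 / params.N
    rho = np.where(rho >= threshold, rho, 0.0)
    Q = rho / 15.0
    off = Q.sum(axis=1)
    mu_max = 1.0 / off.max() if off.max() > 0 else np.inf
    if not 0 < params.mu <= mu_max:
        raise ValueError(f"mu must lie in (0, {mu_max:.6g}]")
    P = params.mu * Q
    np.fill_diagonal(P, 1.0 - P.sum(axis=1))
    labels = tuple(code_of_index(i) for i in range(16))
    return ChainMatrix(P=P, node_labels=labels, mu=params.mu)
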