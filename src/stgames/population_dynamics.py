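"""Finite-population imitation dynamics, direct and rejection-free.

A well-mixed population of ``N`` individuals, each carrying one of the 16
memory-one strategies, evolves by pairwise imitation: two individuals are
drawn at random without replacement, and the focal one adopts the opponent's
strategy with the linear probability

    p(dpi) = (1 + dpi / dpi_max) / 2,

where ``dpi`` is the opponent's payoff excess and ``dpi_max`` the largest
possible payoff difference.  Equal payoffs give p = 1/2 (pure drift).  An
individual's payoff is its expected payoff against an opponent drawn
uniformly from the other N - 1 individuals.

Direct simulation wastes most steps on pairs of identical individuals.  The
rejection-free (accelerated) process skips them: per elementary step the
probability that a strategy-``i`` individual copies strategy ``j`` is
``n_i n_j p(pi_j - pi_i) / (N(N-1))``, so the probability of *some* change is
``(N^2 - sum_i n_i^2) / (2 N (N-1))`` independently of payoffs, and the
expected number of elementary steps between changes is its reciprocal.  The
accelerated process samples the jump from the conditional law and weights
each visited composition by that expected waiting time, which recovers the
time averages of the direct process exactly.

Runs stop on absorption (homogeneous population) or when the windowed
time-average composition stops moving, which flags a quasi-stationary mixed
state.  Inner loops are numba-compiled; single-step NumPy reference
implementations are provided for testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit
from scipy.special import logsumexp

from .pair_payoff import PayoffMatrix

__all__ = [
    "PopulationState",
    "ImitationRule",
    "StabilityConfig",
    "TrajectorySummary",
    "individual_payoff",
    "imitation_probability",
    "step_direct",
    "step_accelerated",
    "run_until_stable",
    "run_direct_to_absorption",
]


@dataclass(frozen=True)
class PopulationState:
    """Counts of each strategy in a finite population."""

    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if np.any(counts < 0):
            raise ValueError("strategy counts must be nonnegative")
        if counts.sum() < 2:
            raise ValueError("population size must be at least 2")

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.counts)

    @property
    def homogeneous(self) -> bool:
        return self.support.size == 1


@dataclass(frozen=True)
class ImitationRule:
    """Pairwise imitation rule: payoff matrix plus its normalization constant."""

    W: np.ndarray
    delta_pi_max: float

    def __post_init__(self):
        if self.delta_pi_max <= 0:
            raise ValueError("delta_pi_max must be positive")

    @classmethod
    def from_payoff_matrix(cls, pm: PayoffMatrix) -> "ImitationRule":
        """Global normalization: the spread of the full payoff matrix."""
        W = np.asarray(pm.W, dtype=float)
        return cls(W=W, delta_pi_max=float(W.max() - W.min()))


@dataclass(frozen=True)
class StabilityConfig:
    """Stopping rule for :func:`run_until_stable`.

    ``window_time`` is measured in elementary (direct) time steps; ``None``
    resolves to ``100 * N`` at run time.  A run is declared quasi-stationary
    when ``stable_windows`` consecutive comparisons of successive window
    averages each move by at most ``tol_individuals`` in every component.
    Requiring several consecutive quiet windows separates genuinely
    restoring mixed equilibria (whose windowed averages are pinned) from
    slow neutral drift, which wanders too much to pass repeatedly before it
    absorbs.

    ``tol_individuals = None`` resolves to ``max(2, 0.02 * N)``: the
    composition fluctuations of a quasi-stationary state grow with
    population size, so a fixed head-count tolerance starves the detector
    at larger N; two percent of the population keeps the criterion
    scale-free while never dropping below two individuals.
    """

    tol_individuals: Optional[float] = None
    window_time: Optional[float] = None
    stable_windows: int = 4
    event_budget: int = 10_000_000
    #: Mean-absorption-time scale (elementary steps) beyond which a
    #: two-strategy interior attractor counts as quasi-stationary.  ``None``
    #: resolves to 20x the event budget: a state whose absorption the run
    #: could never witness is metastable relative to that run.  Use
    #: ``float("inf")`` to disable the analytic certification path.
    metastable_time: Optional[float] = None


@dataclass(frozen=True)
class TrajectorySummary:
    """Outcome of one population run."""

    average_counts: np.ndarray
    elapsed_time: float
    final_state: PopulationState
    absorbed: bool
    inconclusive: bool = False
    events: int = 0
    seed: Optional[int] = None


def individual_payoff(state: PopulationState, i: int, W: np.ndarray) -> float:
    """Expected payoff of a strategy-``i`` individual against the population
    mixture, excluding itself."""
    n = state.counts
    if n[i] < 1:
        raise ValueError(f"no individual of strategy {i} present")
    return float((W[i] @ n - W[i, i]) / (state.N - 1))


def imitation_probability(delta_pi: float, delta_pi_max: float) -> float:
    """Linear imitation probability; 1/2 at equal payoffs (random drift)."""
    if delta_pi_max <= 0:
        raise ValueError("delta_pi_max must be positive")
    if abs(delta_pi) > delta_pi_max * (1 + 1e-12):
        raise ValueError(f"|delta_pi| = {abs(delta_pi)} exceeds delta_pi_max = {delta_pi_max}")
    return min(1.0, max(0.0, 0.5 * (1.0 + delta_pi / delta_pi_max)))


def _mixture_payoffs(counts: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Payoff of each present strategy against the self-excluded mixture."""
    N = counts.sum()
    return (W @ counts - np.diag(W)) / (N - 1)


def step_direct(state: PopulationState, rule: ImitationRule, rng: np.random.Generator) -> PopulationState:
    """One elementary imitation step (reference implementation).

    Samples an ordered focal/opponent pair uniformly without replacement;
    the focal individual adopts the opponent's strategy with the linear
    imitation probability.  At most one count changes by +/-1.
    """
    counts = state.counts
    N = state.N
    # Strategies of the focal and opponent individuals (exchangeable, so
    # sampling strategies with the right weights is equivalent to sampling
    # individuals).
    i = rng.choice(counts.size, p=counts / N)
    rest = counts.astype(float).copy()
    rest[i] -= 1
    j = rng.choice(counts.size, p=rest / (N - 1))
    if i == j:
        return state
    pi = _mixture_payoffs(counts, rule.W)
    p = imitation_probability(pi[j] - pi[i], rule.delta_pi_max)
    if rng.random() < p:
        new = counts.copy()
        new[i] -= 1
        new[j] += 1
        return PopulationState(new)
    return state


def step_accelerated(
    state: PopulationState, rule: ImitationRule, rng: np.random.Generator
) -> tuple[PopulationState, float]:
    """One rejection-free step (reference implementation).

    Samples the replaced strategy from its marginal jump distribution and the
    copied strategy conditionally, and returns the expected waiting time of
    the direct process, ``1 / P(change)``, for time-weighted averaging.
    """
    counts = state.counts
    if state.homogeneous:
        raise ValueError("accelerated step undefined for a homogeneous population")
    N = state.N
    pi = _mixture_payoffs(counts, rule.W)
    dp = (pi[None, :] - pi[:, None]) / rule.delta_pi_max
    p = np.clip(0.5 * (1.0 + dp), 0.0, 1.0)
    w = np.outer(counts, counts).astype(float) * p
    np.fill_diagonal(w, 0.0)
    total = w.sum()
    waiting = N * (N - 1) / total
    # Marginal over the replaced strategy, then the conditional target.
    marg = w.sum(axis=1)
    i = rng.choice(counts.size, p=marg / total)
    j = rng.choice(counts.size, p=w[i] / marg[i])
    new = counts.copy()
    new[i] -= 1
    new[j] += 1
    return PopulationState(new), float(waiting)


@njit(cache=False)
def _accel_kernel(W, n, N, dpmax, tol, window, need_stable, budget, well_k, seed):
    """Rejection-free run until absorption, stability, or budget.

    Returns (status, n_final, average_counts, elapsed_time, events) with
    status 0 = absorbed, 1 = quasi-stationary, 2 = budget exceeded.
    """
    np.random.seed(seed)
    s = n.size
    cum_t = 0.0
    cum_wn = np.zeros(s)
    # Window-average stability bookkeeping.
    ck1_t = 0.0
    ck1_wn = np.zeros(s)
    stretch_t = 0.0
    stretch_wn = np.zeros(s)
    prev_avg = np.zeros(s)
    have_prev = False
    n_stable = 0
    events = 0
    avg = np.zeros(s)
    pi = np.zeros(s)
    w = np.zeros((s, s))
    while True:
        # Absorption check.
        for i in range(s):
            if n[i] == N:
                if cum_t > 0.0:
                    for k in range(s):
                        avg[k] = cum_wn[k] / cum_t
                else:
                    for k in range(s):
                        avg[k] = n[k]
                return 0, n, avg, cum_t, events
        # Certified two-strategy well: once the trajectory reaches the
        # interior attractor of a pair whose exact absorption time exceeds
        # the metastability scale, the run is quasi-stationary.
        ns = 0
        ia = -1
        ib = -1
        for i in range(s):
            if n[i] > 0:
                ns += 1
                if ia < 0:
                    ia = i
                else:
                    ib = i
        if ns == 2:
            kstar = well_k[ia, ib]
            if kstar >= 0 and n[ib] == kstar:
                for k in range(s):
                    avg[k] = 0.0
                avg[ia] = N - kstar
                avg[ib] = kstar
                return 1, n, avg, cum_t, events
        # Payoffs against the self-excluded mixture.
        for i in range(s):
            acc = 0.0
            for j in range(s):
                acc += W[i, j] * n[j]
            pi[i] = (acc - W[i, i]) / (N - 1)
        # Jump weights w[i, j]: strategy-i individual copies strategy j.
        total = 0.0
        for i in range(s):
            for j in range(s):
                if i == j or n[i] == 0 or n[j] == 0:
                    w[i, j] = 0.0
                else:
                    p = 0.5 * (1.0 + (pi[j] - pi[i]) / dpmax)
                    if p < 0.0:
                        p = 0.0
                    elif p > 1.0:
                        p = 1.0
                    w[i, j] = n[i] * n[j] * p
                    total += w[i, j]
        tau = N * (N - 1.0) / total
        cum_t += tau
        for k in range(s):
            cum_wn[k] += tau * n[k]
        # Sample the jump.
        u = np.random.random() * total
        acc = 0.0
        ii = 0
        jj = 0
        done = False
        for i in range(s):
            if done:
                break
            for j in range(s):
                acc += w[i, j]
                if acc >= u:
                    ii = i
                    jj = j
                    done = True
                    break
        n[ii] -= 1
        n[jj] += 1
        events += 1
        # Window checkpointing: count consecutive quiet window-to-window
        # comparisons; a failure restarts the stable stretch.
        if cum_t - ck1_t >= window:
            win_t = cum_t - ck1_t
            quiet = False
            if have_prev:
                quiet = True
                for k in range(s):
                    a = (cum_wn[k] - ck1_wn[k]) / win_t
                    if abs(a - prev_avg[k]) > tol:
                        quiet = False
                        break
            if quiet:
                if n_stable == 0:
                    # The stable stretch starts at the previous checkpoint.
                    stretch_t = ck1_t
                    for k in range(s):
                        stretch_wn[k] = ck1_wn[k]
                n_stable += 1
                if n_stable >= need_stable:
                    span = cum_t - stretch_t
                    for k in range(s):
                        avg[k] = (cum_wn[k] - stretch_wn[k]) / span
                    return 1, n, avg, cum_t, events
            else:
                n_stable = 0
            for k in range(s):
                prev_avg[k] = (cum_wn[k] - ck1_wn[k]) / win_t
                ck1_wn[k] = cum_wn[k]
            ck1_t = cum_t
            have_prev = True
        if events >= budget:
            if cum_t > 0.0:
                for k in range(s):
                    avg[k] = cum_wn[k] / cum_t
            return 2, n, avg, cum_t, events


@njit(cache=False)
def _direct_kernel(W, n, N, dpmax, max_steps, seed):
    """Direct elementary-step run until absorption or the step cap.

    Returns (status, n_final, steps) with status 0 = absorbed, 2 = cap hit.
    """
    np.random.seed(seed)
    s = n.size
    pi = np.zeros(s)
    # Payoffs are recomputed only when the composition changes.
    for i in range(s):
        acc = 0.0
        for j in range(s):
            acc += W[i, j] * n[j]
        pi[i] = (acc - W[i, i]) / (N - 1)
    steps = 0
    while steps < max_steps:
        steps += 1
        # Focal strategy, weighted by counts.
        u = np.random.random() * N
        acc = 0.0
        ii = 0
        for i in range(s):
            acc += n[i]
            if acc >= u:
                ii = i
                break
        # Opponent strategy, focal individual excluded.
        u = np.random.random() * (N - 1)
        acc = 0.0
        jj = 0
        for j in range(s):
            acc += n[j] - (1 if j == ii else 0)
            if acc >= u:
                jj = j
                break
        if ii == jj:
            continue
        p = 0.5 * (1.0 + (pi[jj] - pi[ii]) / dpmax)
        if np.random.random() < p:
            n[ii] -= 1
            n[jj] += 1
            if n[jj] == N:
                return 0, n, steps
            for i in range(s):
                acc = 0.0
                for j in range(s):
                    acc += W[i, j] * n[j]
                pi[i] = (acc - W[i, i]) / (N - 1)
    return 2, n, steps


def _pair_birth_death(W: np.ndarray, dpmax: float, res: int, mut: int, N: int):
    """Per-step birth/death probabilities of the (res, mut) pair chain over
    the mutant count k = 1..N-1 (same combinatorics as the fixation module,
    duplicated here to keep the dynamics layer self-contained)."""
    k = np.arange(1, N)
    pi_m = ((k - 1) * W[mut, mut] + (N - k) * W[mut, res]) / (N - 1)
    pi_r = (k * W[res, mut] + (N - k - 1) * W[res, res]) / (N - 1)
    pair = k * (N - k) / (N * (N - 1))
    p_up = np.clip(0.5 * (1.0 + (pi_m - pi_r) / dpmax), 0.0, 1.0)
    return pair * p_up, pair * (1.0 - p_up)


def _certified_attractor(rule: ImitationRule, res: int, mut: int, N: int, threshold: float) -> int:
    """Interior attractor of a two-strategy pair, if quasi-stationary.

    Returns the mutant count k* at the attractor when the pair's selection
    gradient points inward from both ends and the exact mean absorption
    time of the pair chain (per-state sojourn sum, evaluated in log space)
    exceeds ``threshold`` elementary steps; otherwise -1.  Cached on the
    rule, since the answer depends only on (rule, res, mut, N, threshold).
    """
    cache = getattr(rule, "_well_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(rule, "_well_cache", cache)
    key = (res, mut, N, threshold)
    if key in cache:
        return cache[key]
    b, d = _pair_birth_death(rule.W, rule.delta_pi_max, res, mut, N)
    result = -1
    if np.all(b > 0) and np.all(d > 0):
        diff = b - d
        # Inward drift at both ends plus a down-crossing in between.
        if diff[0] > 0 and diff[-1] < 0:
            crossings = np.flatnonzero((diff[:-1] > 0) & (diff[1:] <= 0))
            if crossings.size:
                i = int(crossings[0])
                # Counts k = i+1 and k = i+2 straddle the attractor.
                kstar = i + 1 if abs(diff[i]) <= abs(diff[i + 1]) else i + 2
                n = b.size
                log_gamma = np.concatenate([[0.0], np.cumsum(np.log(d) - np.log(b))])
                log_Gm = np.array([logsumexp(log_gamma[:k]) for k in range(1, n + 1)])
                log_Gp = np.array([logsumexp(log_gamma[k:]) for k in range(1, n + 1)])
                log_escape = np.logaddexp(
                    np.log(b) + log_gamma[1:] - log_Gp,
                    np.log(d) + log_gamma[:-1] - log_Gm,
                )
                log_mean_time = logsumexp(-log_Gm - log_escape)
                if log_mean_time > np.log(threshold):
                    result = int(kstar)
    cache[key] = result
    return result


def _resolve_seed(rng_or_seed) -> int:
    if isinstance(rng_or_seed, np.random.Generator):
        return int(rng_or_seed.integers(2**31 - 1))
    return int(rng_or_seed) % (2**31 - 1)


def run_until_stable(
    state: PopulationState,
    rule: ImitationRule,
    rng_or_seed,
    cfg: StabilityConfig = StabilityConfig(),
) -> TrajectorySummary:
    """Run the accelerated process until absorption or quasi-stationarity.

    Time averages follow the waiting-time-weighted estimator, so
    ``average_counts`` sums to N and reproduces the direct process's
    occupation statistics.  If the event budget is exhausted before either
    stopping condition fires, the summary is flagged ``inconclusive``.
    """
    seed = _resolve_seed(rng_or_seed)
    N = state.N
    window = cfg.window_time if cfg.window_time is not None else 100.0 * N
    tol = cfg.tol_individuals if cfg.tol_individuals is not None else max(2.0, 0.02 * N)
    if state.homogeneous:
        return TrajectorySummary(
            average_counts=state.counts.astype(float),
            elapsed_time=0.0,
            final_state=state,
            absorbed=True,
            events=0,
            seed=seed,
        )
    support = state.support
    s = support.size
    Wsub = np.ascontiguousarray(rule.W[np.ix_(support, support)])
    nsub = state.counts[support].copy()
    # Analytic certification table for two-strategy wells: well_k[a, b] is
    # the attractor count of support strategy b against resident a, or -1.
    well_k = np.full((s, s), -1, dtype=np.int64)
    metastable = (
        cfg.metastable_time if cfg.metastable_time is not None else 20.0 * cfg.event_budget
    )
    if np.isfinite(metastable):
        for a in range(s):
            for b in range(s):
                if a != b:
                    well_k[a, b] = _certified_attractor(
                        rule, int(support[a]), int(support[b]), N, float(metastable)
                    )
    status, n_final, avg, elapsed, events = _accel_kernel(
        Wsub, nsub, N, rule.delta_pi_max, float(tol), float(window),
        int(cfg.stable_windows), int(cfg.event_budget), well_k, seed,
    )
    full_counts = np.zeros_like(state.counts)
    full_counts[support] = n_final
    full_avg = np.zeros(state.counts.size, dtype=float)
    full_avg[support] = avg
    return TrajectorySummary(
        average_counts=full_avg,
        elapsed_time=float(elapsed),
        final_state=PopulationState(full_counts),
        absorbed=(status == 0),
        inconclusive=(status == 2),
        events=int(events),
        seed=seed,
    )


def run_direct_to_absorption(
    state: PopulationState,
    rule: ImitationRule,
    rng_or_seed,
    max_steps: int = 10_000_000,
) -> TrajectorySummary:
    """Run the direct elementary-step process until absorption or a step cap.

    Used for distributional-equivalence checks against the accelerated
    process; no time averaging is performed.
    """
    seed = _resolve_seed(rng_or_seed)
    support = state.support
    Wsub = np.ascontiguousarray(rule.W[np.ix_(support, support)])
    nsub = state.counts[support].copy()
    status, n_final, steps = _direct_kernel(
        Wsub, nsub, state.N, rule.delta_pi_max, int(max_steps), seed
    )
    full_counts = np.zeros_like(state.counts)
    full_counts[support] = n_final
    final = PopulationState(full_counts)
    return TrajectorySummary(
        average_counts=full_counts.astype(float),
        elapsed_time=float(steps),
        final_state=final,
        absorbed=(status == 0),
        inconclusive=(status == 2),
        events=int(steps),
        seed=seed,
    )
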