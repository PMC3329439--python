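"""Markov-chain analysis of invasion graphs.

The invasion graph defines a Markov chain over stable populations: with a
small invasion rate ``mu`` per step, the chain leaves node ``a`` for node
``b`` with probability ``mu`` times the average, over possible invaders, of
the fraction of invasions that carry ``a`` to ``b``.  In canonical form the
chain splits into transient nodes and disjoint recurrent (sink) classes.
For each transient node the probability of ultimately entering each
recurrent class solves a linear system; its unweighted mean over transient
nodes summarizes how reachable each class is, and the within-class
stationary vector gives the long-run occupation of the class's nodes.

All reported quantities are invariant to ``mu`` across its admissible
range: ``mu`` only rescales off-diagonal mass uniformly, which changes
neither reachability, nor absorption probabilities, nor stationary vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .invasion_graph import InvasionGraphResult

__all__ = [
    "ChainMatrix",
    "MarkovDecomposition",
    "build_chain",
    "decompose",
    "absorption_probabilities",
    "class_stationary",
    "summary_table",
]

_ROW_TOL = 1e-12
_CONS_TOL = 1e-10


@dataclass(frozen=True)
class ChainMatrix:
    """Row-stochastic transition matrix over invasion-graph nodes."""

    P: np.ndarray
    node_labels: tuple[str, ...]
    mu: float

    def __post_init__(self):
        if np.any(np.abs(self.P.sum(axis=1) - 1.0) > _ROW_TOL):
            raise ValueError("chain rows must sum to 1")


@dataclass(frozen=True)
class MarkovDecomposition:
    """Transient/recurrent structure of an invasion chain."""

    transient: tuple[int, ...]
    recurrent_classes: tuple[tuple[int, ...], ...]
    absorption: np.ndarray  # x[i, k]: transient row i -> class k
    averaged_absorption: np.ndarray  # mean of x over transient rows
    stationary: tuple[np.ndarray, ...]  # per-class stationary vectors


def build_chain(
    graph: InvasionGraphResult, mu: float = 0.01, min_weight: float = 0.0
) -> ChainMatrix:
    """Assemble the transition matrix from invasion outcome fractions.

    Off-diagonal entry (a, b) is ``mu / m_a`` times the summed outcome
    fraction of invasions of ``a`` that end in ``b``, where ``m_a`` is the
    number of strategies that can invade ``a`` (those absent from it); the
    diagonal closes each row.  ``mu`` must be small enough to keep all
    diagonals nonnegative.

    ``min_weight`` drops outcome fractions at or below the given value
    before assembly.  Fractions estimated from ``r`` realizations resolve
    transition probabilities only down to 1/r, so ``min_weight = 1/r``
    removes transitions supported by a single realization, which are
    statistically indistinguishable from noise.
    """
    n = len(graph.nodes)
    Q = np.zeros((n, n))
    for e in graph.edges:
        if e.source != e.target and e.weight > min_weight:
            m = graph.attempted_invaders.get(e.source, 15)
            Q[e.source, e.target] += e.weight / m
    off = Q.sum(axis=1)
    mu_max = 1.0 / off.max() if off.max() > 0 else np.inf
    if not 0 < mu <= mu_max:
        raise ValueError(f"mu must lie in (0, {mu_max:.6g}] to keep the chain stochastic")
    P = mu * Q
    np.fill_diagonal(P, 1.0 - P.sum(axis=1))
    return ChainMatrix(P=P, node_labels=tuple(node.label for node in graph.nodes), mu=mu)


def decompose(chain: ChainMatrix, weight_floor: float = 0.0) -> MarkovDecomposition:
    """Identify transient nodes and recurrent classes, then solve for
    absorption probabilities and within-class stationary vectors.

    Recurrent classes are the sink strongly-connected components of the
    digraph of off-diagonal transitions exceeding ``weight_floor``.  A
    positive floor emulates pruning of transitions supported by too few
    realizations to be trustworthy.
    """
    P = chain.P
    n = P.shape[0]
    G = nx.DiGraph()
    G.add_nodes_from(range(n))
    for a in range(n):
        for b in range(n):
            if a != b and P[a, b] > weight_floor:
                G.add_edge(a, b)
    cond = nx.condensation(G)
    classes = []
    transient: list[int] = []
    for comp_id in cond.nodes:
        members = sorted(cond.nodes[comp_id]["members"])
        if cond.out_degree(comp_id) == 0:
            classes.append(tuple(members))
        else:
            transient.extend(members)
    classes.sort()
    transient = sorted(transient)
    absorption, averaged = absorption_probabilities(P, transient, classes)
    stationary = tuple(class_stationary(P, cls) for cls in classes)
    return MarkovDecomposition(
        transient=tuple(transient),
        recurrent_classes=tuple(classes),
        absorption=absorption,
        averaged_absorption=averaged,
        stationary=stationary,
    )


def absorption_probabilities(
    P: np.ndarray, transient: list[int], classes: list[tuple[int, ...]]
) -> tuple[np.ndarray, np.ndarray]:
    """Probability of ultimately entering each recurrent class.

    Solves ``(I - T) x_k = R 1_k`` on the transient block, where ``T`` is
    the transient-to-transient block and ``R 1_k`` the one-step mass into
    class ``k``.  The unweighted mean over transient nodes is returned
    alongside; with no transient nodes the mean is degenerate (NaN).
    """
    K = len(classes)
    t = len(transient)
    if t == 0:
        return np.zeros((0, K)), np.full(K, np.nan)
    T = P[np.ix_(transient, transient)]
    B = np.column_stack([P[np.ix_(transient, list(cls))].sum(axis=1) for cls in classes])
    A = np.eye(t) - T
    # Row-equilibrate: each transient row's total escape mass (its diagonal
    # in A) can span many orders of magnitude when some nodes are only
    # weakly connected, which would otherwise make the solve ill
    # conditioned; scaling rows leaves the solution unchanged.
    scale = np.diag(A).copy()
    scale[scale <= 0] = 1.0
    try:
        As = A / scale[:, None]
        Bs = B / scale[:, None]
        x = np.linalg.solve(As, Bs)
        # One step of iterative refinement for stiff chains.
        x += np.linalg.solve(As, Bs - As @ x)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defended invariant
        raise RuntimeError("singular absorption system; decomposition inconsistent") from exc
    sums = x.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise RuntimeError("absorption probabilities do not conserve mass")
    # Restore exact conservation (residual round-off only).
    x = x / sums[:, None]
    return x, x.mean(axis=0)


def class_stationary(P: np.ndarray, cls: tuple[int, ...]) -> np.ndarray:
    """Stationary distribution of a recurrent class's submatrix."""
    sub = P[np.ix_(list(cls), list(cls))]
    # A floor-pruned class may leak tiny mass; renormalize rows.
    sub = sub / sub.sum(axis=1, keepdims=True)
    m = len(cls)
    if m == 1:
        return np.ones(1)
    A = sub.T - np.eye(m)
    A[-1, :] = 1.0
    b = np.zeros(m)
    b[-1] = 1.0
    pi = np.linalg.solve(A, b)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def summary_table(chain: ChainMatrix, decomp: MarkovDecomposition):
    """Per-(class, node) summary: within-class stationary probability and the
    transient-averaged probability of reaching the class."""
    import pandas as pd

    rows = []
    for k, cls in enumerate(decomp.recurrent_classes):
        for pos, node in enumerate(cls):
            rows.append(
                {
                    "class": k,
                    "node": node,
                    "strategies": chain.node_labels[node],
                    "pi": float(decomp.stationary[k][pos]),
                    "Xbar": float(decomp.averaged_absorption[k]),
                }
            )
    return pd.DataFrame(rows)
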