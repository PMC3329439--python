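"""Systematic invasion experiments and the invasion graph.

Starting from the 16 homogeneous populations, every stable population (node)
is invaded by every strategy it does not contain: a small fraction of the
residents is converted to the invader and the imitation dynamics is run to
absorption or quasi-stationarity, over many independent realizations.  Each
realization ends (a) back in the resident population, (b) in a homogeneous
population of the invader, or (c) in a mixed quasi-stationary equilibrium.
Outcomes are recorded as weighted directed edges labeled by the invading
strategy; newly discovered mixed equilibria become nodes and are invaded in
turn, until no new node appears.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .game_space import Game, code_of_index
from .pair_payoff import payoff_matrix
from .population_dynamics import (
    ImitationRule,
    PopulationState,
    StabilityConfig,
    TrajectorySummary,
    run_until_stable,
)

__all__ = [
    "EquilibriumNode",
    "InvasionEdge",
    "InvasionParams",
    "InvasionGraphResult",
    "merge_node",
    "run_invasion",
    "build_invasion_graph",
    "nodes_dataframe",
    "edges_dataframe",
    "to_dot",
]


@dataclass(frozen=True)
class EquilibriumNode:
    """A stable population: homogeneous or quasi-stationary mixed."""

    id: int
    composition: dict[int, float]  # strategy index -> fraction, sums to 1
    kind: str  # "homogeneous" | "mixed"

    @property
    def support(self) -> frozenset[int]:
        return frozenset(self.composition)

    @property
    def label(self) -> str:
        return "+".join(code_of_index(i) for i in sorted(self.composition))


@dataclass(frozen=True)
class InvasionEdge:
    """Outcome fractions of invading ``source`` with ``invader``."""

    source: int
    target: int
    invader: str  # 4-digit strategy code
    weight: float


@dataclass(frozen=True)
class InvasionParams:
    """Configuration of the invasion protocol."""

    N: int = 1000
    eps: float = 0.01
    invader_fraction: float = 0.05
    realizations: int = 100
    merge_tol: float = 0.05
    min_presence: float = 0.01
    stability: StabilityConfig = field(default_factory=StabilityConfig)
    node_cap: int = 200


@dataclass
class InvasionGraphResult:
    """The closed invasion graph for one game."""

    game: Game
    params: InvasionParams
    nodes: list[EquilibriumNode]
    edges: list[InvasionEdge]
    inconclusive: dict[tuple[int, str], int]
    attempted_invaders: dict[int, int]
    truncated: bool = False


def merge_node(
    composition: dict[int, float],
    nodes: list[EquilibriumNode],
    merge_tol: float,
) -> Optional[int]:
    """Identify ``composition`` with an existing node, if any.

    Two compositions merge when they have the same strategy support and
    their fractions differ by at most ``merge_tol`` in max norm.  Returns
    the matching node id, or ``None`` if the composition is new.
    """
    support = frozenset(composition)
    for node in nodes:
        if node.support != support:
            continue
        dev = max(abs(composition[i] - node.composition[i]) for i in support)
        if dev <= merge_tol:
            return node.id
    return None


def _counts_from_composition(
    composition: dict[int, float], invader: int, params: InvasionParams
) -> PopulationState:
    """Initial counts: residents scaled down, ``invader_fraction`` converted."""
    N = params.N
    n_inv = max(1, round(params.invader_fraction * N))
    counts = np.zeros(16, dtype=np.int64)
    resident_total = N - n_inv
    # Largest-remainder apportionment of the residents.
    items = sorted(composition.items())
    raw = np.array([f * resident_total for _, f in items])
    base = np.floor(raw).astype(np.int64)
    rem = resident_total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    for (idx, _), c in zip(items, base):
        counts[idx] = c
    counts[invader] += n_inv
    return PopulationState(counts)


def _classify(summary: TrajectorySummary, params: InvasionParams) -> Optional[dict[int, float]]:
    """Composition reached by one realization, or ``None`` if inconclusive."""
    if summary.inconclusive:
        return None
    if summary.absorbed:
        idx = int(summary.final_state.support[0])
        return {idx: 1.0}
    fracs = summary.average_counts / summary.average_counts.sum()
    keep = {int(i): float(fracs[i]) for i in np.flatnonzero(fracs >= params.min_presence)}
    total = sum(keep.values())
    return {i: f / total for i, f in keep.items()}


def run_invasion(
    node: EquilibriumNode,
    invader: int,
    rule: ImitationRule,
    params: InvasionParams,
    seed_seq: np.random.SeedSequence,
    nodes: list[EquilibriumNode],
) -> tuple[dict[int, float], int, list[EquilibriumNode]]:
    """Invade ``node`` with strategy ``invader`` over many realizations.

    Returns (outcome fractions over node ids, number of inconclusive
    realizations, newly registered nodes).  Outcome fractions are over the
    conclusive realizations and sum to 1; unseen compositions are matched
    against ``nodes`` (plus any new nodes) via :func:`merge_node` and
    registered when genuinely new.
    """
    if invader in node.composition:
        raise ValueError("invader already present in the resident population")
    start = _counts_from_composition(node.composition, invader, params)
    child_seeds = seed_seq.generate_state(params.realizations) % (2**31 - 1)
    counts: dict[int, int] = {}
    inconclusive = 0
    new_nodes: list[EquilibriumNode] = []
    registry = list(nodes)
    for r in range(params.realizations):
        summary = run_until_stable(start, rule, int(child_seeds[r]), params.stability)
        comp = _classify(summary, params)
        if comp is None:
            inconclusive += 1
            continue
        nid = merge_node(comp, registry, params.merge_tol)
        if nid is None:
            nid = len(registry)
            kind = "homogeneous" if len(comp) == 1 else "mixed"
            new = EquilibriumNode(id=nid, composition=comp, kind=kind)
            registry.append(new)
            new_nodes.append(new)
        counts[nid] = counts.get(nid, 0) + 1
    conclusive = params.realizations - inconclusive
    fractions = {nid: c / conclusive for nid, c in counts.items()} if conclusive else {}
    return fractions, inconclusive, new_nodes


def build_invasion_graph(
    game: Game, params: InvasionParams, seed: int
) -> InvasionGraphResult:
    """Breadth-first closure of the invasion protocol.

    Seeds the 16 homogeneous nodes, invades every node with every strategy
    absent from it, registers new (mixed) equilibria as nodes, and repeats
    on newly added nodes until closure or the node cap.
    """
    pm = payoff_matrix(game, params.eps)
    rule = ImitationRule.from_payoff_matrix(pm)
    master = np.random.SeedSequence(seed)
    nodes: list[EquilibriumNode] = [
        EquilibriumNode(id=i, composition={i: 1.0}, kind="homogeneous") for i in range(16)
    ]
    edges: list[InvasionEdge] = []
    inconclusive: dict[tuple[int, str], int] = {}
    attempted: dict[int, int] = {}
    truncated = False
    queue = list(range(16))
    processed: set[int] = set()
    while queue:
        nid = queue.pop(0)
        if nid in processed:
            continue
        processed.add(nid)
        node = nodes[nid]
        invaders = [i for i in range(16) if i not in node.composition]
        attempted[nid] = len(invaders)
        for inv in invaders:
            # Independent, reproducible stream per (node, invader); node ids
            # are assigned deterministically in BFS order for a fixed seed.
            sub = np.random.SeedSequence(entropy=master.entropy, spawn_key=(nid, inv))
            fractions, n_inc, new_nodes = run_invasion(node, inv, rule, params, sub, nodes)
            if n_inc:
                inconclusive[(nid, code_of_index(inv))] = n_inc
            for new in new_nodes:
                if len(nodes) >= params.node_cap:
                    truncated = True
                    continue
                nodes.append(new)
                queue.append(new.id)
            for target, w in fractions.items():
                if target < len(nodes):
                    edges.append(
                        InvasionEdge(source=nid, target=target, invader=code_of_index(inv), weight=w)
                    )
    if truncated:
        import warnings

        warnings.warn("invasion graph truncated at node cap; result is partial", RuntimeWarning)
    return InvasionGraphResult(
        game=game,
        params=params,
        nodes=nodes,
        edges=edges,
        inconclusive=inconclusive,
        attempted_invaders=attempted,
        truncated=truncated,
    )


def nodes_dataframe(result: InvasionGraphResult):
    import pandas as pd

    rows = [
        {
            "id": n.id,
            "label": n.label,
            "kind": n.kind,
            "composition": ";".join(
                f"{code_of_index(i)}:{f:.4f}" for i, f in sorted(n.composition.items())
            ),
        }
        for n in result.nodes
    ]
    return pd.DataFrame(rows)


def edges_dataframe(result: InvasionGraphResult):
    import pandas as pd

    rows = [
        {"source": e.source, "target": e.target, "invader": e.invader, "weight": e.weight}
        for e in result.edges
    ]
    return pd.DataFrame(rows)


def to_dot(result: InvasionGraphResult) -> str:
    """GraphViz DOT export with edge widths proportional to weight."""
    lines = ["digraph invasion {", "  rankdir=LR;"]
    for n in result.nodes:
        shape = "ellipse" if n.kind == "homogeneous" else "box"
        lines.append(f'  n{n.id} [label="{n.label}", shape={shape}];')
    for e in result.edges:
        if e.source == e.target:
            continue
        width = 0.5 + 3.0 * e.weight
        lines.append(
            f'  n{e.source} -> n{e.target} [label="{e.invader}", penwidth={width:.2f}];'
        )
    lines.append("}")
    return "\n".join(lines)
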