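"""Full-study orchestration over a grid of (S, T) points.

For each game the pipeline runs both analyses -- the simulation-based
invasion graph and the fixation-probability chain -- decomposes each into
transient and recurrent structure, and emits comparable per-game summaries
plus a global index.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import markov_analysis
from .fixation_analysis import FixationParams, build_fixation_chain
from .game_space import Game, WslsTriple, classify_quadrant, wsls_strategies
from .invasion_graph import (
    InvasionGraphResult,
    InvasionParams,
    build_invasion_graph,
    edges_dataframe,
    nodes_dataframe,
    to_dot,
)
from .markov_analysis import ChainMatrix, MarkovDecomposition, build_chain, decompose
from .pair_payoff import payoff_matrix

__all__ = ["SweepConfig", "GameReport", "analyze_game", "run_sweep", "DEFAULT_GRID"]

#: One interior point per quadrant region discussed in the study: Harmony,
#: low-S Snowdrift, high-S Snowdrift (anti-coordination), moderate- and
#: large-temptation Prisoner's Dilemma, and Stag Hunt.
DEFAULT_GRID: tuple[tuple[float, float], ...] = (
    (0.5, 0.5),
    (0.5, 1.5),
    (2.0, 3.0),
    (-0.5, 1.5),
    (-1.5, 2.5),
    (-0.5, 0.5),
)


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of a full (S, T) sweep."""

    st_points: tuple[tuple[float, float], ...] = DEFAULT_GRID
    invasion: InvasionParams = field(default_factory=InvasionParams)
    mu: float = 0.01
    prune_threshold: Optional[float] = None  # None -> 0.1 / N (drift-relative)
    sim_min_weight: Optional[float] = None  # None -> 1 / realizations
    fixation_N: Optional[int] = None  # defaults to invasion.N
    seed: int = 0
    outdir: Optional[str] = None


@dataclass
class GameReport:
    """All analysis products for one game."""

    game: Game
    quadrant: str
    wsls: Optional[WslsTriple]
    graph: InvasionGraphResult
    simulation_chain: ChainMatrix
    simulation_decomposition: MarkovDecomposition
    simulation_summary: pd.DataFrame
    fixation_chain: ChainMatrix
    fixation_decomposition: MarkovDecomposition
    fixation_summary: pd.DataFrame
    diagnostics: dict


def _point_seed(master_seed: int, S: float, T: float) -> int:
    """Deterministic per-point seed derived from the master seed and (S, T)."""
    ss = np.random.SeedSequence(
        entropy=master_seed, spawn_key=(hash_float(S), hash_float(T))
    )
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def hash_float(x: float) -> int:
    """Stable 32-bit key for a float grid coordinate."""
    return int(np.float64(x).view(np.uint64) % (2**32))


def analyze_game(game: Game, config: SweepConfig) -> GameReport:
    """Run both analyses for one game and assemble the report."""
    seed = _point_seed(config.seed, game.S, game.T)
    try:
        wsls = wsls_strategies(game)
    except ValueError:
        wsls = None  # degenerate payoff ordering
    graph = build_invasion_graph(game, config.invasion, seed)
    # Transitions supported by a single realization are below the protocol's
    # statistical resolution and are dropped from the chain.
    min_weight = (
        config.sim_min_weight
        if config.sim_min_weight is not None
        else 1.0 / config.invasion.realizations
    )
    sim_chain = build_chain(graph, mu=config.mu, min_weight=min_weight)
    sim_dec = decompose(sim_chain)
    fix_params = FixationParams(
        N=config.fixation_N or config.invasion.N,
        eps=config.invasion.eps,
        mu=config.mu,
        prune_threshold=config.prune_threshold,
    )
    fix_chain = build_fixation_chain(game, fix_params)
    fix_dec = decompose(fix_chain)
    diagnostics = {
        "seed": seed,
        "n_nodes": len(graph.nodes),
        "n_mixed_nodes": sum(1 for n in graph.nodes if n.kind == "mixed"),
        "inconclusive_runs": int(sum(graph.inconclusive.values())),
        "truncated": graph.truncated,
    }
    return GameReport(
        game=game,
        quadrant=classify_quadrant(game),
        wsls=wsls,
        graph=graph,
        simulation_chain=sim_chain,
        simulation_decomposition=sim_dec,
        simulation_summary=markov_analysis.summary_table(sim_chain, sim_dec),
        fixation_chain=fix_chain,
        fixation_decomposition=fix_dec,
        fixation_summary=markov_analysis.summary_table(fix_chain, fix_dec),
        diagnostics=diagnostics,
    )


def _write_report(report: GameReport, outdir: Path, eps: float) -> None:
    tag = f"S{report.game.S:+.3g}_T{report.game.T:+.3g}".replace(".", "p")
    d = outdir / tag
    d.mkdir(parents=True, exist_ok=True)
    payoff_matrix(report.game, eps).to_dataframe().to_csv(d / "payoff_matrix.csv")
    nodes_dataframe(report.graph).to_csv(d / "nodes.csv", index=False)
    edges_dataframe(report.graph).to_csv(d / "edges.csv", index=False)
    (d / "invasion_graph.dot").write_text(to_dot(report.graph))
    report.simulation_summary.to_csv(d / "simulation_summary.csv", index=False)
    report.fixation_summary.to_csv(d / "fixation_summary.csv", index=False)
    summary = {
        "game": {"S": report.game.S, "T": report.game.T},
        "quadrant": report.quadrant,
        "wsls": asdict(report.wsls) if report.wsls else None,
        "diagnostics": report.diagnostics,
        "simulation_recurrent_classes": [
            [report.simulation_chain.node_labels[i] for i in cls]
            for cls in report.simulation_decomposition.recurrent_classes
        ],
        "fixation_recurrent_classes": [
            [report.fixation_chain.node_labels[i] for i in cls]
            for cls in report.fixation_decomposition.recurrent_classes
        ],
    }
    (d / "summary.json").write_text(json.dumps(summary, indent=2))


def run_sweep(config: SweepConfig) -> tuple[list[Optional[GameReport]], pd.DataFrame]:
    """Analyze every grid point independently; failures are isolated.

    Returns the per-point reports (``None`` where a point failed) and a
    global index table.
    """
    reports: list[Optional[GameReport]] = []
    rows = []
    outdir = Path(config.outdir) if config.outdir else None
    for S, T in config.st_points:
        game = Game(S=S, T=T)
        row = {"S": S, "T": T, "quadrant": classify_quadrant(game)}
        try:
            report = analyze_game(game, config)
            if outdir is not None:
                _write_report(report, outdir, config.invasion.eps)
            row.update(
                status="ok",
                n_recurrent_classes=len(report.simulation_decomposition.recurrent_classes),
                n_mixed_nodes=report.diagnostics["n_mixed_nodes"],
                top_class="|".join(
                    report.simulation_chain.node_labels[i]
                    for i in report.simulation_decomposition.recurrent_classes[
                        int(np.nanargmax(report.simulation_decomposition.averaged_absorption))
                        if len(report.simulation_decomposition.recurrent_classes) > 1
                        else 0
                    ]
                ),
            )
        except Exception as exc:  # per-point isolation
            report = None
            row.update(status=f"error: {exc}")
        reports.append(report)
        rows.append(row)
    index = pd.DataFrame(rows)
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        index.to_csv(outdir / "index.csv", index=False)
    return reports, index
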