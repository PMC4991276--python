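"""Experiment drivers: payoff-by-openness, openness learning, group formation.

Three studies share one round engine. In the first, agents with fixed,
randomly drawn openness accumulate payoffs under different infection
prevalences, exposing the trade-off between the opportunity gains of distant
interaction and its infection risk. In the second, agents additionally learn
their openness from round payoffs, so the population drifts open when
infection is rare and closed when it is common. In the third, all agents
share one openness value and pairwise affinities evolve by reciprocity and
transitivity; the emergent mutually-cooperative groups are then extracted and
their spatial makeup measured against the random-grouping null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .adaptation import LearningParams, reciprocity_update, transitivity_update, update_openness
from .community import build_threshold_graph, girvan_newman_partition, group_stats
from .interaction import (
    AgentState,
    InfectionParams,
    PayoffScheme,
    RoundRecord,
    play_round,
)
from .topology import GridSpec, sample_pair

__all__ = [
    "ExperimentConfig",
    "SimulationState",
    "run_round",
    "run_replication",
    "run_sim1",
    "run_sim2",
    "run_sim3",
    "replication_rng",
    "FULL_SIM3_ROUNDS",
    "FULL_SIM3_REPLICATIONS",
]

# Full-scale group-formation study: 2,000,000 cycles, 50 replications.
FULL_SIM3_ROUNDS = 2_000_000
FULL_SIM3_REPLICATIONS = 50
# Scaled defaults used for routine runs; the full scale sits behind a flag.
SCALED_SIM3_ROUNDS = 200_000
SCALED_SIM3_REPLICATIONS = 5


@dataclass(frozen=True)
class ExperimentConfig:
    """A reproducible experiment definition.

    ``rounds`` counts sampled pair-rounds (time cycles). ``k_values`` is the
    infection-prevalence sweep for the payoff and learning studies;
    ``openness_values`` the openness sweep for the group-formation study,
    which uses the single prevalence ``k``. Learning switches follow the study
    design: the payoff study freezes everything, the learning study adapts
    openness only, the group study adapts affinities only.
    """

    experiment: str
    grid: GridSpec
    rounds: int
    replications: int
    master_seed: int
    k_values: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    openness_values: tuple[float, ...] = (-1.0, -0.5, 0.0, 0.5, 1.0)
    k: float = 0.0
    payoffs: PayoffScheme = field(default_factory=PayoffScheme)
    learning: LearningParams = field(default_factory=LearningParams)
    openness_learning: bool = False
    affinity_dynamics: bool = False
    infection_requires_own_cooperation: bool = False
    threshold: float = 0.5
    recording_interval: int = 1000

    def __post_init__(self) -> None:
        if self.experiment not in ("sim1", "sim2", "sim3"):
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.rounds < 0:
            raise ValueError("rounds must be non-negative")
        if self.replications < 1:
            raise ValueError("replications must be positive")
        for k in (*self.k_values, self.k):
            if not 0.0 <= k <= 1.0:
                raise ValueError(f"infection parameter k={k} outside [0, 1]")
        for o in self.openness_values:
            if not -1.0 <= o <= 1.0:
                raise ValueError(f"openness value {o} outside [-1, 1]")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")

    @classmethod
    def sim1(cls, **kwargs) -> "ExperimentConfig":
        """Fixed-openness payoff study: 20x20 grid, 100,000 rounds per k."""
        kwargs.setdefault("grid", GridSpec(20, 20))
        kwargs.setdefault("rounds", 100_000)
        kwargs.setdefault("replications", 1)
        kwargs.setdefault("master_seed", 0)
        return cls(
            experiment="sim1",
            openness_learning=False,
            affinity_dynamics=False,
            **kwargs,
        )

    @classmethod
    def sim2(cls, **kwargs) -> "ExperimentConfig":
        """Openness-learning study: as sim1 but openness adapts to payoffs."""
        kwargs.setdefault("grid", GridSpec(20, 20))
        kwargs.setdefault("rounds", 100_000)
        kwargs.setdefault("replications", 1)
        kwargs.setdefault("master_seed", 0)
        return cls(
            experiment="sim2",
            openness_learning=True,
            affinity_dynamics=False,
            **kwargs,
        )

    @classmethod
    def sim3(cls, full: bool = False, **kwargs) -> "ExperimentConfig":
        """Group-formation study: 8x8 grid, shared openness, affinity dynamics.

        Scaled by default (200,000 cycles x 5 replications); ``full=True``
        selects the full scale (2,000,000 x 50).
        """
        kwargs.setdefault("grid", GridSpec(8, 8))
        kwargs.setdefault("rounds", FULL_SIM3_ROUNDS if full else SCALED_SIM3_ROUNDS)
        kwargs.setdefault(
            "replications", FULL_SIM3_REPLICATIONS if full else SCALED_SIM3_REPLICATIONS
        )
        kwargs.setdefault("master_seed", 0)
        return cls(
            experiment="sim3",
            openness_learning=False,
            affinity_dynamics=True,
            **kwargs,
        )


@dataclass
class SimulationState:
    """Mutable per-replication state: agents, affinities, accumulators."""

    grid: GridSpec
    agents: list[AgentState]
    affinity: np.ndarray
    total_payoff: np.ndarray
    rounds_run: int = 0
    rounds_played: int = 0

    @classmethod
    def initialize(
        cls,
        grid: GridSpec,
        openness: np.ndarray | float,
        affinity_init: float = 0.5,
    ) -> "SimulationState":
        n = grid.n_agents
        openness_arr = np.broadcast_to(np.asarray(openness, dtype=float), (n,)).copy()
        agents = [
            AgentState(index=a, position=grid.position(a), openness=float(openness_arr[a]))
            for a in range(n)
        ]
        affinity = np.full((n, n), affinity_init, dtype=float)
        np.fill_diagonal(affinity, 0.0)  # diagonal unused
        return cls(
            grid=grid,
            agents=agents,
            affinity=affinity,
            total_payoff=np.zeros(n),
        )

    @property
    def openness(self) -> np.ndarray:
        return np.array([a.openness for a in self.agents])


def replication_rng(
    master_seed: int, condition_index: int, replication: int
) -> np.random.Generator:
    """Independent, individually re-runnable stream for one replication.

    Streams are addressed by (condition index, replication index) through the
    seed-sequence spawn key, so any single replication can be reproduced
    without running the others.
    """
    ss = np.random.SeedSequence(master_seed, spawn_key=(condition_index, replication))
    return np.random.default_rng(ss)


def run_round(
    state: SimulationState,
    config: ExperimentConfig,
    rng: np.random.Generator,
    k: Optional[float] = None,
) -> RoundRecord:
    """One time cycle: sample a pair, resolve the round, apply enabled learning.

    Update order within a played round: payoffs, infection draws, openness
    update (if learning openness), reciprocity, transitivity (after mutual
    cooperation). Unplayed rounds leave all state except the round counter
    untouched.
    """
    pair = sample_pair(state.grid, rng)
    i, j = pair.agent_i, pair.agent_j
    infection = InfectionParams(
        k=config.k if k is None else k,
        requires_own_cooperation=config.infection_requires_own_cooperation,
    )
    rec = play_round(
        state.agents[i],
        state.agents[j],
        float(state.affinity[i, j]),
        config.payoffs,
        infection,
        state.grid,
        rng,
        pair=pair,
    )
    state.rounds_run += 1
    if rec.played:
        state.rounds_played += 1
        state.total_payoff[i] += rec.net_payoff_i
        state.total_payoff[j] += rec.net_payoff_j
        lp = config.learning
        if config.openness_learning:
            state.agents[i].openness = update_openness(
                state.agents[i].openness, rec.net_payoff_i, lp
            )
            state.agents[j].openness = update_openness(
                state.agents[j].openness, rec.net_payoff_j, lp
            )
        if config.affinity_dynamics:
            c = reciprocity_update(
                float(state.affinity[i, j]), rec.coop_i, rec.coop_j, lp.beta
            )
            state.affinity[i, j] = c
            state.affinity[j, i] = c
            if rec.coop_i and rec.coop_j:
                transitivity_update(
                    state.affinity, i, j, lp.delta, lp.transitivity_condition
                )
    return rec


def run_replication(
    config: ExperimentConfig,
    rng: np.random.Generator,
    openness: np.ndarray | float,
    k: float,
    record_openness: bool = False,
) -> tuple[SimulationState, list[tuple[int, float]]]:
    """Run one full replication; optionally record the mean-openness trajectory."""
    state = SimulationState.initialize(config.grid, openness)
    trajectory: list[tuple[int, float]] = []
    interval = max(1, config.recording_interval)
    if record_openness:
        trajectory.append((0, float(np.mean(state.openness))))
    for t in range(config.rounds):
        run_round(state, config, rng, k=k)
        if record_openness and (t + 1) % interval == 0:
            trajectory.append((t + 1, float(np.mean(state.openness))))
    return state, trajectory


def run_sim1(config: ExperimentConfig) -> pd.DataFrame:
    """Payoff-by-openness study.

    For each infection prevalence k and replication, agents receive i.i.d.
    uniform[-1, 1] openness (frozen) and affinity fixed at 0.5; rounds are run
    and each agent's total net payoff accumulated. Returns one row per
    (k, replication, agent) with the agent's openness and total payoff.
    """
    if config.experiment != "sim1" or config.openness_learning or config.affinity_dynamics:
        raise ValueError("config is not a sim1 configuration")
    rows = []
    for ci, k in enumerate(config.k_values):
        for rep in range(config.replications):
            rng = replication_rng(config.master_seed, ci, rep)
            openness = rng.uniform(-1.0, 1.0, size=config.grid.n_agents)
            state, _ = run_replication(config, rng, openness, k)
            for a in range(config.grid.n_agents):
                rows.append(
                    {
                        "experiment": "sim1",
                        "k": k,
                        "replication": rep,
                        "agent": a,
                        "openness": openness[a],
                        "total_payoff": state.total_payoff[a],
                    }
                )
    return pd.DataFrame(rows)


def bin_payoffs(per_agent: pd.DataFrame, width: float = 0.1) -> pd.DataFrame:
    """Mean payoff per openness bin, the plotting-ready view of the payoff study."""
    df = per_agent.copy()
    # bins [-1, -1+w), ..., clipping the right edge into the last bin
    nbins = int(round(2.0 / width))
    idx = np.clip(((df["openness"] + 1.0) / width).astype(int), 0, nbins - 1)
    df["openness_bin"] = -1.0 + (idx + 0.5) * width
    return (
        df.groupby(["experiment", "k", "openness_bin"], as_index=False)
        .agg(mean_total_payoff=("total_payoff", "mean"), n_agents=("agent", "count"))
    )


def run_sim2(config: ExperimentConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Openness-learning study.

    As the payoff study, but after each played round both participants update
    their openness from their net payoff. Returns (summary, trajectory):
    the summary has one row per (k, replication) with start/end mean openness;
    the trajectory samples population-mean openness every recording interval.
    """
    if config.experiment != "sim2" or not config.openness_learning:
        raise ValueError("config is not a sim2 configuration")
    summary_rows = []
    traj_rows = []
    for ci, k in enumerate(config.k_values):
        for rep in range(config.replications):
            rng = replication_rng(config.master_seed, ci, rep)
            openness = rng.uniform(-1.0, 1.0, size=config.grid.n_agents)
            start_mean = float(np.mean(openness))
            state, traj = run_replication(
                config, rng, openness, k, record_openness=True
            )
            end_mean = float(np.mean(state.openness))
            summary_rows.append(
                {
                    "experiment": "sim2",
                    "k": k,
                    "replication": rep,
                    "mean_openness_start": start_mean,
                    "mean_openness_end": end_mean,
                }
            )
            traj_rows.extend(
                {
                    "experiment": "sim2",
                    "k": k,
                    "replication": rep,
                    "round": t,
                    "mean_openness": o,
                }
                for t, o in traj
            )
    return pd.DataFrame(summary_rows), pd.DataFrame(traj_rows)


def run_sim3(
    config: ExperimentConfig, return_states: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, dict]:
    """Group-formation study.

    All agents share one openness value (swept over ``openness_values``);
    affinities start at 0.5 and evolve by reciprocity and transitivity. At the
    end of each replication the affinity network is thresholded, the best-Q
    partition extracted, and group statistics computed. Returns one row per
    (openness, replication); with ``return_states=True`` also a dict of final
    states keyed by (openness, replication).
    """
    if config.experiment != "sim3" or not config.affinity_dynamics:
        raise ValueError("config is not a sim3 configuration")
    rows = []
    states: dict[tuple[float, int], SimulationState] = {}
    for ci, openness in enumerate(config.openness_values):
        for rep in range(config.replications):
            rng = replication_rng(config.master_seed, ci, rep)
            state, _ = run_replication(config, rng, openness, config.k)
            iu = np.triu_indices(config.grid.n_agents, k=1)
            mean_affinity = float(np.mean(state.affinity[iu]))
            G = build_threshold_graph(state.affinity, config.threshold)
            part = girvan_newman_partition(G)
            stats = group_stats(part, config.grid)
            rows.append(
                {
                    "experiment": "sim3",
                    "openness": openness,
                    "replication": rep,
                    "mean_affinity": mean_affinity,
                    "n_edges": G.number_of_edges(),
                    "modularity": (
                        math.nan if part.modularity is None else part.modularity
                    ),
                    "n_groups_all": stats.n_groups_all,
                    "n_groups_nonsingleton": stats.n_groups_nonsingleton,
                    "whole_network": stats.whole_network_flag,
                    "mean_within_group_distance": (
                        math.nan
                        if stats.mean_within_group_distance is None
                        else stats.mean_within_group_distance
                    ),
                    "n_within_pairs": stats.n_within_pairs,
                }
            )
            if return_states:
                states[(openness, rep)] = state
    df = pd.DataFrame(rows)
    if return_states:
        return df, states
    return df


def aggregate_sim3(summary: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of the group statistics per openness value.

    Whole-network partitions are excluded from the group-count aggregate, and
    replications without any multi-member group contribute nothing to the
    distance aggregate.
    """
    out = []
    for openness, grp in summary.groupby("openness"):
        counted = grp.loc[~grp["whole_network"], "n_groups_nonsingleton"]
        dists = grp["mean_within_group_distance"].dropna()
        aff = grp["mean_affinity"]

        def _se(x):
            return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else math.nan

        out.append(
            {
                "openness": openness,
                "mean_affinity": float(aff.mean()),
                "se_affinity": _se(aff),
                "mean_n_groups": float(counted.mean()) if len(counted) else math.nan,
                "se_n_groups": _se(counted),
                "mean_within_group_distance": (
                    float(dists.mean()) if len(dists) else math.nan
                ),
                "se_within_group_distance": _se(dists),
                "n_replications": len(grp),
            }
        )
    return pd.DataFrame(out)
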