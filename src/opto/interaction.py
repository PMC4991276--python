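"""One round of the game: play decision, Prisoner's Dilemma payoffs, infection.

A sampled pair of agents first decide, each independently, whether to play at
all; the probability rises (falls) with distance for agents of positive
(negative) openness. If both agree, each cooperates with probability equal to
their mutual affinity and the Prisoner's Dilemma payoffs are assigned — with
the twist that the mutual-cooperation reward grows with the spatial distance
between the pair, capturing the greater gains available from trading with
agents who hold complementary resources. Playing with a distant partner also
carries a distance-scaled risk of exotic infection (a pathogen the agent has
no locally evolved immunity to), charged as a single large negative payoff.
Infection of one agent by the other is not modelled, nor is onward spread.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .topology import GridSpec, PairSample

__all__ = [
    "AgentState",
    "PayoffScheme",
    "InfectionParams",
    "RoundRecord",
    "cooperation_reward",
    "pd_payoffs",
    "infection_probability",
    "play_probability",
    "play_round",
]


@dataclass
class AgentState:
    """An agent: its grid index, cell, and openness trait in [-1, 1]."""

    index: int
    position: tuple[int, int]
    openness: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.openness <= 1.0:
            raise ValueError(f"openness must lie in [-1, 1], got {self.openness}")


@dataclass(frozen=True)
class PayoffScheme:
    """Prisoner's Dilemma payoffs with a distance-scaled cooperation reward.

    ``mutual_coop_base`` is the reward for mutual cooperation between adjacent
    agents; it grows linearly with distance up to ``mutual_coop_base + P`` at
    the maximum network distance (the opportunities gradient). All other
    outcomes pay a fixed amount regardless of distance. ``infection_penalty``
    is the one-off payoff for catching an exotic infection during a round.
    """

    mutual_coop_base: float = 1.0
    mutual_defect: float = -1.0
    sucker: float = -3.0
    temptation: float = 3.0
    P: float = 9.0
    infection_penalty: float = -50.0

    def __post_init__(self) -> None:
        if not (self.temptation > self.mutual_coop_base > self.mutual_defect > self.sucker):
            raise ValueError("payoffs must satisfy temptation > reward > punishment > sucker")
        if not self.infection_penalty < self.sucker:
            raise ValueError("infection penalty must be worse than the sucker payoff")

    def max_gain(self) -> float:
        """Largest single-round payoff an agent can receive (any distance)."""
        return max(self.temptation, self.mutual_coop_base + self.P)

    def max_loss(self) -> float:
        """Largest single-round loss magnitude: sucker payoff plus infection."""
        return abs(self.sucker) + abs(self.infection_penalty)


@dataclass(frozen=True)
class InfectionParams:
    """Exotic-infection risk.

    ``k`` is the infection probability when playing a maximally distant
    partner; the risk falls linearly to zero for adjacent neighbours, whose
    pathogens the agent is assumed to already be immune to. When
    ``requires_own_cooperation`` is set, only agents who themselves cooperated
    in the round are exposed; by default exposure attaches to the physical
    interaction regardless of the actions chosen.
    """

    k: float = 0.0
    requires_own_cooperation: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.k <= 1.0:
            raise ValueError(f"k must be a probability in [0, 1], got {self.k}")


@dataclass(frozen=True)
class RoundRecord:
    """Outcome of one sampled round; action/infection fields absent if unplayed."""

    pair: PairSample
    played: bool
    coop_i: Optional[bool] = None
    coop_j: Optional[bool] = None
    payoff_i: float = 0.0
    payoff_j: float = 0.0
    infected_i: bool = False
    infected_j: bool = False
    net_payoff_i: float = 0.0
    net_payoff_j: float = 0.0


def cooperation_reward(d: int, max_d: int, P: float = 9.0, base: float = 1.0) -> float:
    """Mutual-cooperation reward at distance ``d``: base + P*(d-1)/(max_d-1)."""
    if max_d < 2:
        raise ValueError("degenerate network: maximum distance must be at least 2")
    if not 1 <= d <= max_d:
        raise ValueError(f"distance {d} outside [1, {max_d}]")
    return base + P * (d - 1) / (max_d - 1)


def pd_payoffs(
    coop_i: bool, coop_j: bool, d: int, max_d: int, scheme: PayoffScheme
) -> tuple[float, float]:
    """Prisoner's Dilemma payoffs; only mutual cooperation depends on distance."""
    if coop_i and coop_j:
        r = cooperation_reward(d, max_d, scheme.P, scheme.mutual_coop_base)
        return r, r
    if coop_i and not coop_j:
        return scheme.sucker, scheme.temptation
    if coop_j and not coop_i:
        return scheme.temptation, scheme.sucker
    return scheme.mutual_defect, scheme.mutual_defect


def infection_probability(d: int, max_d: int, k: float) -> float:
    """Per-agent exotic-infection probability: k*(d-1)/(max_d-1), zero at d=1."""
    if not 1 <= d <= max_d:
        raise ValueError(f"distance {d} outside [1, {max_d}]")
    if max_d < 2:
        raise ValueError("degenerate network: maximum distance must be at least 2")
    return k * (d - 1) / (max_d - 1)


def play_probability(O: float, d: int, max_d: int) -> float:
    """Probability that an agent with openness ``O`` agrees to play at distance ``d``.

    (1-O)/2 + O*(d-1)/(max_d-1): a fully open agent (O=1) plays a maximally
    distant partner with certainty and an adjacent one never; a fully closed
    agent (O=-1) does the reverse; a neutral agent (O=0) plays anyone with
    probability one half.
    """
    if not -1.0 <= O <= 1.0:
        raise ValueError(f"openness {O} outside [-1, 1]")
    if not 1 <= d <= max_d:
        raise ValueError(f"distance {d} outside [1, {max_d}]")
    if max_d < 2:
        raise ValueError("degenerate network: maximum distance must be at least 2")
    return (1.0 - O) / 2.0 + O * (d - 1) / (max_d - 1)


def play_round(
    agent_i: AgentState,
    agent_j: AgentState,
    affinity_ij: float,
    scheme: PayoffScheme,
    infection: InfectionParams,
    grid: GridSpec,
    rng: np.random.Generator,
    pair: Optional[PairSample] = None,
) -> RoundRecord:
    """Resolve one round between two distinct agents.

    Each agent independently agrees to play; the round proceeds only if both
    do. If played, each cooperates with probability ``affinity_ij``, receives
    the PD payoff, and is independently exposed to exotic infection; the
    infection penalty is added to that agent's net payoff.
    """
    if agent_i.index == agent_j.index:
        raise ValueError("agents must be distinct")
    if not 0.0 <= affinity_ij <= 1.0:
        raise ValueError(f"affinity {affinity_ij} outside [0, 1]")
    if pair is None:
        from .topology import torus_distance

        d = torus_distance(agent_i.position, agent_j.position, grid)
        pair = PairSample(agent_i.index, agent_j.index, d)
    d = pair.distance
    max_d = grid.max_d

    wants_i = rng.random() < play_probability(agent_i.openness, d, max_d)
    wants_j = rng.random() < play_probability(agent_j.openness, d, max_d)
    if not (wants_i and wants_j):
        return RoundRecord(pair=pair, played=False)

    coop_i = rng.random() < affinity_ij
    coop_j = rng.random() < affinity_ij
    pay_i, pay_j = pd_payoffs(coop_i, coop_j, d, max_d, scheme)

    p_inf = infection_probability(d, max_d, infection.k)
    inf_i = rng.random() < p_inf
    inf_j = rng.random() < p_inf
    if infection.requires_own_cooperation:
        inf_i = inf_i and coop_i
        inf_j = inf_j and coop_j

    net_i = pay_i + (scheme.infection_penalty if inf_i else 0.0)
    net_j = pay_j + (scheme.infection_penalty if inf_j else 0.0)
    return RoundRecord(
        pair=pair,
        played=True,
        coop_i=coop_i,
        coop_j=coop_j,
        payoff_i=pay_i,
        payoff_j=pay_j,
        infected_i=inf_i,
        infected_j=inf_j,
        net_payoff_i=net_i,
        net_payoff_j=net_j,
    )
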