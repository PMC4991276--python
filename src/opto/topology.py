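"""Toroidal grid topology and distance-stratified pair sampling.

Agents occupy every cell of a wraparound (toroidal) rectangular grid, one
agent per cell. Distances are city-block (L1) distances measured around the
torus, so the grid has no edges and every agent sees an identical spatial
neighbourhood. Interaction partners are sampled in two stages: first a
distance class is drawn uniformly from all distances realisable on the grid,
then an unordered pair of agents separated by exactly that distance is drawn
uniformly. Because the torus is vertex-transitive this gives every agent the
same long-run probability of being selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "GridSpec",
    "PairSample",
    "torus_distance",
    "max_distance",
    "offsets_by_distance",
    "sample_pair",
    "mean_random_pair_distance",
]


@dataclass(frozen=True)
class GridSpec:
    """A toroidal grid of ``width`` x ``height`` cells, one agent per cell.

    Agents are indexed 0 .. n_agents-1 in row-major order; agent ``a`` sits at
    column ``a % width`` and row ``a // width``.
    """

    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 2 or self.height < 2:
            raise ValueError(
                f"grid must be at least 2x2, got {self.width}x{self.height}"
            )

    @property
    def n_agents(self) -> int:
        return self.width * self.height

    @property
    def max_d(self) -> int:
        return max_distance(self)

    def position(self, agent: int) -> tuple[int, int]:
        """(x, y) cell of an agent index."""
        if not 0 <= agent < self.n_agents:
            raise ValueError(f"agent index {agent} out of range")
        return agent % self.width, agent // self.width

    def agent_at(self, x: int, y: int) -> int:
        if not (0 <= x < self.width and 0 <= y < self.height):
            raise ValueError(f"position ({x}, {y}) outside {self.width}x{self.height} grid")
        return y * self.width + x

    def positions(self) -> np.ndarray:
        """(n_agents, 2) array of (x, y) cells in agent-index order."""
        idx = np.arange(self.n_agents)
        return np.column_stack([idx % self.width, idx // self.width])


@dataclass(frozen=True)
class PairSample:
    """An unordered pair of distinct agents and their torus distance."""

    agent_i: int
    agent_j: int
    distance: int


def torus_distance(a: tuple[int, int], b: tuple[int, int], grid: GridSpec) -> int:
    """City-block distance between two cells, wrapping around both axes."""
    ax, ay = a
    bx, by = b
    if not (0 <= ax < grid.width and 0 <= ay < grid.height):
        raise ValueError(f"position {a} outside grid")
    if not (0 <= bx < grid.width and 0 <= by < grid.height):
        raise ValueError(f"position {b} outside grid")
    dx = abs(ax - bx)
    dy = abs(ay - by)
    return min(dx, grid.width - dx) + min(dy, grid.height - dy)


def max_distance(grid: GridSpec) -> int:
    """Longest city-block distance between any pair of cells on the torus.

    Per axis the wrapped offset cannot exceed floor(n/2); both maxima are
    attained simultaneously, so the overall maximum is their sum.
    """
    return grid.width // 2 + grid.height // 2


@lru_cache(maxsize=None)
def _offset_table(width: int, height: int) -> dict[int, np.ndarray]:
    """All (dx, dy) cell shifts grouped by their wrapped city-block distance.

    Shifts are taken mod (width, height), so for a fixed origin each shift
    reaches a distinct cell and every ordered pair corresponds to exactly one
    shift.
    """
    table: dict[int, list[tuple[int, int]]] = {}
    for dx in range(width):
        for dy in range(height):
            d = min(dx, width - dx) + min(dy, height - dy)
            if d == 0:
                continue
            table.setdefault(d, []).append((dx, dy))
    return {d: np.array(v, dtype=np.int64) for d, v in sorted(table.items())}


def offsets_by_distance(grid: GridSpec) -> dict[int, np.ndarray]:
    """Cell shifts of each realisable distance class on ``grid``."""
    return _offset_table(grid.width, grid.height)


def sample_pair(grid: GridSpec, rng: np.random.Generator) -> PairSample:
    """Draw one interaction pair.

    A distance is drawn uniformly from {1, ..., max_d}; then an unordered pair
    at exactly that distance is drawn uniformly (agent uniform, then a uniform
    shift of that distance — uniform over ordered pairs by vertex-transitivity
    of the torus, hence every agent has equal long-run selection probability).
    """
    offsets = offsets_by_distance(grid)
    d = int(rng.integers(1, grid.max_d + 1))
    shifts = offsets.get(d)
    if shifts is None:  # cannot happen on a torus with max_d as defined
        raise RuntimeError(f"no pair exists at distance {d}")
    i = int(rng.integers(grid.n_agents))
    dx, dy = shifts[int(rng.integers(len(shifts)))]
    xi, yi = i % grid.width, i // grid.width
    j = ((yi + dy) % grid.height) * grid.width + (xi + dx) % grid.width
    return PairSample(agent_i=i, agent_j=int(j), distance=d)


def mean_random_pair_distance(grid: GridSpec, distinct: bool = False) -> float:
    """Expected torus distance between two uniformly random cells.

    With ``distinct=False`` (default) the two cells are drawn independently
    with replacement, the null model for "what would a randomly thrown-together
    group look like"; on an 8x8 grid this is exactly 4. With ``distinct=True``
    self-pairs are excluded, which raises the mean slightly.
    """
    total = 0.0
    for n in (grid.width, grid.height):
        total += sum(min(o, n - o) for o in range(n)) / n
    if distinct:
        n2 = grid.n_agents**2
        total = total * n2 / (n2 - grid.n_agents)
    return total
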