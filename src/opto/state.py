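"""Lossless save/load of simulation states for later re-analysis.

A state file is a single JSON document holding the grid, per-agent openness
and the full affinity matrix. Python's float repr round-trips exactly through
JSON, so a saved state reloads bitwise-identically and community analysis on
it is deterministic.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .experiments import SimulationState
from .topology import GridSpec

__all__ = ["save_state", "load_state", "StateError"]

_FORMAT = "opto-state-v1"


class StateError(ValueError):
    """A state file is corrupt or inconsistent."""


def save_state(state: SimulationState, path: str | Path) -> None:
    """Write grid, openness, affinities and payoff totals as JSON."""
    n = state.grid.n_agents
    doc = {
        "format": _FORMAT,
        "grid": {"width": state.grid.width, "height": state.grid.height},
        "n_agents": n,
        "openness": state.openness.tolist(),
        "affinity": state.affinity.tolist(),
        "total_payoff": state.total_payoff.tolist(),
        "rounds_run": state.rounds_run,
        "rounds_played": state.rounds_played,
    }
    Path(path).write_text(json.dumps(doc))


def load_state(path: str | Path) -> SimulationState:
    """Reload a saved state, verifying shape and symmetry."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != _FORMAT:
        raise StateError(f"not a state file: format={doc.get('format')!r}")
    grid = GridSpec(**doc["grid"])
    n = doc["n_agents"]
    if n != grid.n_agents:
        raise StateError(
            f"agent count {n} does not match {grid.width}x{grid.height} grid"
        )
    openness = np.asarray(doc["openness"], dtype=float)
    affinity = np.asarray(doc["affinity"], dtype=float)
    total_payoff = np.asarray(doc["total_payoff"], dtype=float)
    if openness.shape != (n,) or total_payoff.shape != (n,):
        raise StateError("per-agent array has wrong shape")
    if affinity.shape != (n, n):
        raise StateError("affinity matrix has wrong shape")
    if not np.array_equal(affinity, affinity.T):
        raise StateError("affinity matrix is not symmetric")
    state = SimulationState.initialize(grid, openness)
    state.affinity = affinity
    state.total_payoff = total_payoff
    state.rounds_run = int(doc.get("rounds_run", 0))
    state.rounds_played = int(doc.get("rounds_played", 0))
    return state
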