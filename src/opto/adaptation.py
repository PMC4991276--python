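"""Learning dynamics: openness updates and affinity reciprocity/transitivity.

Openness moves up after positive round payoffs and down after losses, with
adjustments normalised by the largest attainable gain (A) and loss (B) so the
trait stays inside [-1, 1]. Pairwise affinities — the probabilities of
cooperating when a pair plays — rise after mutual cooperation and fall after
mutual defection (reciprocity), and after mutual cooperation the partner with
the weaker opinion of each third party adjusts that opinion (transitivity),
the mechanism through which cliques of mutual cooperators crystallise out of
an initially uniform network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .interaction import PayoffScheme

__all__ = [
    "LearningParams",
    "update_openness",
    "reciprocity_update",
    "transitivity_update",
]

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class LearningParams:
    """Rates and normalisers for the learning rules.

    ``alpha`` scales openness updates; ``A`` and ``B`` normalise positive and
    negative payoffs by the largest single-round gain (1 + P = 10 by default)
    and loss (sucker plus infection penalty, 53 by default). ``beta`` is the
    reciprocity rate and ``delta`` the transitivity rate.
    ``transitivity_condition`` selects whose affinity decides the direction of
    a transitivity adjustment: the adjusting agent's own ("self", default) or
    the stronger (non-adjusting) holder's ("stronger"). The default follows
    the update equations literally; the "stronger" variant implements the
    verbal friend-of-a-friend reading but empirically drives the whole
    network to mutual cooperation at low openness instead of converging near
    the neutral affinity (see docs/methods.md).
    """

    alpha: float = 0.2
    A: float = 10.0
    B: float = 53.0
    beta: float = 0.5
    delta: float = 0.25
    transitivity_condition: str = "self"

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "delta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.A <= 0 or self.B <= 0:
            raise ValueError("normalizers A and B must be positive")
        if self.transitivity_condition not in ("stronger", "self"):
            raise ValueError("transitivity_condition must be 'stronger' or 'self'")

    @classmethod
    def from_scheme(cls, scheme: PayoffScheme, **kwargs) -> "LearningParams":
        """Derive A and B from a payoff scheme (overridable via kwargs)."""
        kwargs.setdefault("A", scheme.max_gain())
        kwargs.setdefault("B", scheme.max_loss())
        return cls(**kwargs)


def update_openness(O: float, net_payoff: float, params: LearningParams) -> float:
    """One openness update from a round's net payoff.

    Gains push openness toward +1 in proportion to payoff/A; losses push it
    down by alpha*(1+O)*(1-O)*|payoff|/B, where the loss enters through its
    magnitude. A zero payoff leaves openness unchanged. The result is clamped
    to [-1, 1] (already bounded when |payoff| does not exceed its normaliser).
    """
    if not -1.0 <= O <= 1.0:
        raise ValueError(f"openness {O} outside [-1, 1]")
    if net_payoff > 0:
        O = O + params.alpha * (1.0 - O) * net_payoff / params.A
    elif net_payoff < 0:
        O = O - params.alpha * (1.0 + O) * (1.0 - O) * (-net_payoff) / params.B
    return min(1.0, max(-1.0, O))


def reciprocity_update(C: float, coop_i: bool, coop_j: bool, beta: float) -> float:
    """Affinity after one played round: up on CC, down on DD, unchanged on CD/DC."""
    if not 0.0 <= C <= 1.0:
        raise ValueError(f"affinity {C} outside [0, 1]")
    if coop_i and coop_j:
        return C + beta * (1.0 - C)
    if not coop_i and not coop_j:
        return C * (1.0 - beta)
    return C


def transitivity_update(
    affinities: np.ndarray,
    i: int,
    j: int,
    delta: float,
    condition: str = "self",
) -> None:
    """Propagate opinions after mutual cooperation between ``i`` and ``j``.

    For every third agent m, whichever of C(i,m), C(j,m) lies nearer the
    neutral value 0.5 is the weaker opinion and is adjusted: upward by
    delta*(1-C) when the deciding affinity exceeds 0.5, downward by delta*C
    when it falls below. With ``condition='self'`` (default) the deciding
    affinity is the adjusting agent's own (the weaker opinion is amplified
    away from 0.5); with ``'stronger'`` it is the stronger holder's (the
    weaker opinion is pulled toward the friend's side). Ties in strength, or a
    deciding affinity of exactly 0.5, leave the entry unchanged. The matrix
    is modified in place, symmetrically.
    """
    if i == j:
        raise ValueError("agents must be distinct")
    n = affinities.shape[0]
    ci = affinities[i].copy()
    cj = affinities[j].copy()
    si = np.abs(ci - 0.5)
    sj = np.abs(cj - 0.5)
    third = np.ones(n, dtype=bool)
    third[i] = third[j] = False

    # opinion strengths within rounding error of each other count as a tie
    diff = si - sj
    i_adjusts = third & (diff < -_TIE_TOL)
    j_adjusts = third & (diff > _TIE_TOL)

    decider_for_i = cj if condition == "stronger" else ci
    decider_for_j = ci if condition == "stronger" else cj

    new_ci = np.where(
        decider_for_i > 0.5,
        ci + delta * (1.0 - ci),
        np.where(decider_for_i < 0.5, ci - delta * ci, ci),
    )
    new_cj = np.where(
        decider_for_j > 0.5,
        cj + delta * (1.0 - cj),
        np.where(decider_for_j < 0.5, cj - delta * cj, cj),
    )

    affinities[i, i_adjusts] = new_ci[i_adjusts]
    affinities[i_adjusts, i] = new_ci[i_adjusts]
    affinities[j, j_adjusts] = new_cj[j_adjusts]
    affinities[j_adjusts, j] = new_cj[j_adjusts]
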