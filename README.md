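# opto — the opportunities–parasites trade-off model

`opto` is an agent-based model of how infectious-disease risk shapes social
network structure. Agents live on a toroidal (wrap-around) grid and play
one-shot prisoner's dilemma games with partners sampled at varying city-block
distances. Interacting with distant partners is economically attractive —
the mutual-cooperation reward grows linearly with distance, standing in for
access to novel resources, ideas, and trading opportunities — but distant
partners are also more likely to carry *exotic* pathogens to which the agent
has no immunity, so infection risk grows with distance too. Each agent's
position on this trade-off is a single trait, **openness** `O ∈ [−1, 1]`:
fully open agents (`O = +1`) seek maximally distant partners, fully closed
agents (`O = −1`) interact only with immediate neighbours.

The package implements three studies on top of this core:

1. **Payoff study** (`sim1`) — openness is frozen; measures how total payoff
   covaries with openness as infection prevalence `k` varies.
2. **Openness-learning study** (`sim2`) — agents adapt their openness after
   each game in proportion to the payoff received.
3. **Group-formation study** (`sim3`) — all agents share one openness value;
   pairwise **affinities** (probabilities of mutual cooperation) evolve by
   reciprocity and transitivity, and the emergent network is partitioned into
   groups by modularity-maximising community detection. The question: do open
   populations form spatially dispersed groups and closed populations
   spatially compact ones?

## Model

Distances are city-block distances on the torus; `D` denotes the maximum
pairwise distance on the grid (`D = ⌊w/2⌋ + ⌊h/2⌋`). For a pair at distance
`d`:

- **Cooperation reward** (each agent, on mutual cooperation):
  `R(d) = 1 + P·(d−1)/(D−1)` with `P = 9`, so rewards run from 1 (adjacent)
  to 10 (maximally distant). The remaining prisoner's-dilemma payoffs are
  fixed and distance-independent: defecting on a cooperator earns +3
  (temptation), cooperating with a defector −3 (sucker), and mutual
  defection −1 each.
- **Infection probability** (each participant, per game):
  `q(d) = k·(d−1)/(D−1)`, zero for adjacent partners; an infection costs a
  flat −50.
- **Play probability** (each agent decides independently; the game happens
  only if both agree): `p(d) = (1−O)/2 + O·(d−1)/(D−1)`.
- **Openness learning** (`sim2`), after a game with net payoff `π`:
  `O ← O + α(1−O)·π/A` if `π > 0`, `O ← O − α(1+O)(1−O)·|π|/B` if `π < 0`,
  with `α = 0.2` and normalisers `A = 10` (largest possible gain) and
  `B = 53` (largest possible loss: sucker payoff plus infection).
- **Reciprocity** (`sim3`), on the pair's affinity `C` (cooperation
  probability, initialised to 0.5): mutual cooperation `C ← C + β(1−C)`,
  mutual defection `C ← C(1−β)`, mixed outcomes unchanged; `β = 0.5`.
- **Transitivity** (`sim3`), after mutual cooperation between `i` and `j`:
  for every third agent `m`, whichever of `C_im`, `C_jm` lies nearer the
  neutral 0.5 is adjusted — up by `δ(1−C)` if it exceeds 0.5, down by `δC`
  if it falls below; `δ = 0.25`. (An alternative direction convention is
  available via `LearningParams(transitivity_condition="stronger")`; see
  `docs/methods.md` for why the literal rule is the default.)

Groups are extracted by thresholding the affinity matrix at `C > 0.5` and
running Girvan–Newman edge-betweenness deletion, keeping the partition with
maximum modularity `Q = Σ_g (e_gg − a_g²)` over the deletion sequence.

## Running the tests

```
python -m pytest tests -q
```

The suite includes `tests/test_acceptance.py`, one test per acceptance
criterion; the simulation-backed criteria use the scaled problem sizes
described in `docs/methods.md` and take ~10–15 minutes in total.
`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes the quantitative acceptance targets (~2 minutes).

## Worked example

```python
from opto import ExperimentConfig, play_probability, run_sim3, aggregate_sim3

for O in (-1.0, 0.0, 1.0):
    print(f"openness {O:+.0f}: p(play, d=1) = {play_probability(O, 1, 8):.3f}, "
          f"p(play, d=8) = {play_probability(O, 8, 8):.3f}")

cfg = ExperimentConfig.sim3(
    rounds=20_000, replications=2,
    openness_values=(-1.0, 1.0), master_seed=42,
)
summary = aggregate_sim3(run_sim3(cfg))
print(summary[["openness", "mean_affinity", "mean_within_group_distance"]]
      .round(3).to_string(index=False))
```

Output:

```
openness -1: p(play, d=1) = 1.000, p(play, d=8) = 0.000
openness +0: p(play, d=1) = 0.500, p(play, d=8) = 0.500
openness +1: p(play, d=1) = 0.000, p(play, d=8) = 1.000
 openness  mean_affinity  mean_within_group_distance
     -1.0          0.496                       3.907
      1.0          0.493                       4.218
```

A fully closed population forms groups that are spatially *compact* (mean
within-group distance below the 4.0 random-grouping baseline of the 8×8
torus), a fully open population groups that are spatially *dispersed*
(above 4.0), while mean affinity is insensitive to openness.

## Command-line interface

The `opto` console script runs each study from a TOML or JSON config file
and writes CSV summaries plus a `run_meta.json` that records everything
needed to reproduce the run:

```
opto sim1 --config examples/sim1.toml --seed 1 --out results/sim1
opto sim2 --config examples/sim2.toml --seed 1 --out results/sim2
opto sim3 --config examples/sim3.toml --seed 1 --out results/sim3   # add --full for the full scale
opto analyze --state results/sim3/state_openness+1_rep0.json        # re-run community detection
```

A minimal config needs only `experiment = "sim1"`; every other field has the
defaults listed in `docs/methods.md`. `sim3` additionally writes each
replication's final state (JSON), the thresholded graph (GraphML and edge-list
CSV), and the partition table.

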