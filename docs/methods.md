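# Methods

## Model

Agents occupy every cell of a `w × h` toroidal grid (one agent per cell).
Distance between agents is city-block distance with wraparound,
`d(a, b) = min(|Δx|, w−|Δx|) + min(|Δy|, h−|Δy|)`; the maximum pairwise
distance is `D = ⌊w/2⌋ + ⌊h/2⌋`. Time advances in rounds. Each round one
pair is sampled by first drawing a distance uniformly from `{1, …, D}` and
then a pair uniformly among pairs at that distance; because the torus is
vertex-transitive, every agent is included with equal probability and every
distance class receives equal sampling weight regardless of its size.

Both agents then independently agree to play with probability

```
p(d) = (1 − O)/2 + O (d − 1)/(D − 1),        O ∈ [−1, 1],
```

and the game happens only on mutual agreement. If played, each cooperates
with probability equal to the pair's affinity `C ∈ [0, 1]` and receives the
prisoner's-dilemma payoff: mutual cooperation `R(d) = 1 + P (d−1)/(D−1)`,
temptation +3, sucker −3, mutual defection −1. Each participant is then
independently infected with probability `q(d) = k (d−1)/(D−1)` at a flat
cost of −50 added to that round's net payoff. Adjacent partners (`d = 1`)
carry exactly zero infection risk by construction.

### Learning rules

- **Openness** (payoff-driven, used by the learning study): after a net
  payoff `π`,
  `O ← O + α (1−O) π/A` when `π > 0` and
  `O ← O − α (1+O)(1−O) |π|/B` when `π < 0`.
  The loss branch uses the *magnitude* of the loss: read with a signed
  negative `π` it would raise openness after a loss, contradicting its
  intended role. Both branches keep `O` in `[−1, 1]` given
  `|π| ≤ A` (gains) and `|π| ≤ B` (losses); the result is clamped anyway.
- **Reciprocity** (affinity, group study): mutual cooperation
  `C ← C + β(1−C)`, mutual defection `C ← C(1−β)`, mixed outcomes no
  change.
- **Transitivity** (group study): after mutual cooperation between `i` and
  `j`, for each third agent `m` the *weaker* of the two opinions `C_im`,
  `C_jm` — the one nearer 0.5 — is adjusted: up by `δ(1−C)` if the deciding
  affinity exceeds 0.5, down by `δC` if below, no change at exactly 0.5 or
  when the two opinions are equally strong.

#### Transitivity direction convention

Whose affinity decides the adjustment direction is ambiguous in the verbal
description of the rule and is exposed as
`LearningParams.transitivity_condition`:

- `"self"` (**default**): the adjusting agent's own affinity decides — the
  literal reading of the update equations. Weak opinions are amplified away
  from neutral; opinions at exactly 0.5 never move by transitivity alone.
- `"stronger"`: the stronger holder's affinity decides — the
  friend-of-a-friend copying reading.

The default was chosen on evidence, not convenience of implementation: every
copy-toward-the-stronger variant we tested gives positive opinions a higher
reproduction rate (only mutually cooperative pairs trigger transitivity, so
positive opinions create more copying events than negative ones) and drives
the whole network toward mutual cooperation at low openness — mean affinity
0.88 at `O = −1` versus 0.39 at `O = +1` after 200,000 cycles — which
contradicts the model's target phenomenology of a mean affinity near 0.5
that is insensitive to openness. The literal rule converges to
0.49–0.51 across the whole openness range.

### Community detection

The final affinity matrix is thresholded at strictly `C > 0.5` into an
undirected graph (isolated agents retained as singleton nodes). Girvan–Newman
edge-betweenness deletion is applied: repeatedly remove the edge with the
highest betweenness (ties broken deterministically by lowest edge index) and
evaluate the modularity `Q = Σ_g (e_gg − a_g²)` of the resulting components
*on the original edge set*; the first (coarsest) partition attaining the
maximum `Q` over the whole deletion sequence is returned. Group statistics
pool within-group city-block distances over all unordered pairs in groups of
at least two members.

Girvan–Newman is a divisive heuristic: its nested partition hierarchy need
not contain the global maximum-`Q` partition, and on dense weakly structured
graphs it often does not (our tests verify instead that the reported `Q`
never exceeds an exhaustive-enumeration bound, matches the exactly
recomputed `Q` of the returned partition, and attains the exhaustive optimum
on graphs with planted community structure).

## Parameters and defaults

| Parameter | Default | Units / range | Meaning |
|---|---|---|---|
| `P` | 9 | payoff units | distance gradient of the cooperation reward (max reward 10) |
| temptation / sucker / mutual defection | +3 / −3 / −1 | payoff units | fixed PD payoffs |
| infection penalty | −50 | payoff units | flat cost of one infection |
| `k` | study-specific | [0, 1] | infection prevalence (slope of risk in distance) |
| `α` | 0.2 | — | openness learning rate |
| `A`, `B` | 10, 53 | payoff units | gain/loss normalisers (max gain; sucker + infection) |
| `β` | 0.5 | — | reciprocity rate |
| `δ` | 0.25 | — | transitivity rate |
| threshold | 0.5 | affinity | edge criterion `C > 0.5` |
| initial affinity | 0.5 | affinity | all pairs neutral at start |

Learning rates are validated on `[0, 1]`; exact zero disables a rule and is
a well-defined fixed point of every update.

## Data generation

The package generates all of its own data: the three studies are the
generators. Openness values in the payoff and learning studies are drawn
uniformly from `[−1, 1]` per replication; the group study assigns one shared
openness per condition. All randomness flows from a single master seed via
`numpy.random.SeedSequence(master_seed, spawn_key=(condition_index,
replication))`, giving every replication an independent, individually
re-runnable `PCG64` stream. Reruns are bit-identical.

## Scaled problem sizes

Full-scale study definitions and the scaled sizes used by the test suite and
the acceptance script (the scaled sizes are this package's own choice, made
for runtime, and every directional claim is tested at the scaled size):

| Study | Grid | Rounds | Replications | Scaled rounds × reps |
|---|---|---|---|---|
| payoff (`sim1`) | 20×20 | 100,000 | 1 per `k` | native size, 10 reps for sign tests |
| learning (`sim2`) | 20×20 | 100,000 | 1 per `k` | native size, 5 reps |
| groups (`sim3`) | 8×8 | 2,000,000 | 50 per openness | 200,000 × 5 |

## Numerical choices

- Opinion-strength comparisons in the transitivity rule use an absolute
  tolerance of `1e-12`: binary floating point makes `|0.7 − 0.5| ≠ 0.2`
  even when two opinions are equally strong by construction, and a strict
  comparison would turn exact ties into spurious adjustments.
- Affinity and openness updates are algebraically bounded; results are
  clamped to their ranges only as a final guard.
- Modularity is accumulated in double precision from integer edge counts;
  tests check it against exact rational arithmetic.
- CSV floats are written with 17 significant digits so that round-trips are
  lossless.

## Limitations

- At the scaled run length the within-group-distance trend across openness
  is weak (condition means roughly 4.0–4.1 around the 8×8 whole-grid mean of
  4.06 over distinct pairs) because, under the default transitivity rule,
  every pair that plays more than a handful of rounds is driven by
  reciprocity to an effectively symmetric coin flip between affinity 0 and 1.
  The pooled rank correlation is positive but small; directional tests, not
  effect sizes, are the supported claims.
- Group *counts* are sensitive to run length, threshold, and the community
  detection heuristic and are not treated as reproducible targets.
- Girvan–Newman cost grows quickly with edge count; the `analyze` command on
  a dense 64-node network takes seconds to about a minute.
- One pair interacts per round (no parallel matching), matching the model
  definition but making wall-clock time linear in rounds (~30 µs/round).
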