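# Methods

## Model

The simulator implements cultural evolution of cooperation in a
group-structured population playing a local public goods game with
altruistic punishment and an optional exit strategy. The population holds
`N` groups of fixed, equal size `n`; state is the per-group count vector of
the four strategies (defector, contributor, punisher, nonparticipant).
Within a group, individuals of the same strategy are exchangeable except
for the per-period contribution error, so counts are sufficient state; the
imitation and mutation stages internally expand to vectorized
per-individual arrays in a documented canonical order, which keeps the
engine fast while allowing an independent agent-level reference
implementation to reproduce trajectories bit-for-bit from the same seed
(see `tests/oracle.py`).

### Stages

Each period applies five stages in a fixed order; every stochastic stage
draws from its own generator spawned from the run seed, so a refactor of
one stage never perturbs another's stream.

1. **Contribution error.** Each cooperator (contributor or punisher)
   contributes with probability `1 − e` and erroneously defects with
   probability `e`; counts of erring cooperators are binomial per group.
   Defectors always defect; nonparticipants abstain.
2. **Punishment and payoffs.** Every punisher fines every *other* group
   member who participated but did not contribute this period, at fine
   `p/n` and punishing cost `k/n` per punisher–target pair. The public
   good pays `b` times the realized contribution fraction, on top of a
   baseline endowment of 1; contributors who actually contributed pay `c`.
   Nonparticipants earn exactly `Ω`, independent of the group, and are
   never fined and never fine. With `e = 0` the class payoffs reduce to
   the fraction forms `1 + bx − c`, `1 + bx − py`, and
   `1 + bx − c − k(1 − x − z)`. Two modeling choices hide in the error
   case: the benefit uses the *realized* contribution fraction (only
   actual contributions produce the good), and an erring punisher still
   punishes the other realized defectors and is fined by the other
   punishers, but never punishes itself — self-punishment has no
   behavioral meaning, and the pairwise accounting keeps the fine/cost
   books balanced (total fines = `(p/k)` × total punishing costs).
3. **Payoff-biased imitation.** Synchronously, every individual draws a
   model — uniformly from its own group excluding itself with probability
   `1 − m`, uniformly from one uniformly chosen other group with
   probability `m` — and adopts the model's strategy with probability
   `w_model/(w_model + w_self)`. All comparisons use pre-update strategies
   and payoffs; asynchronous updating would make outcomes order-dependent.
   Nonparticipants take part fully, as models (at payoff `Ω`) and as
   imitators; imitation is the only channel through which nonparticipation
   spreads beyond mutation. Payoffs are floored at `1e-9` before forming
   the ratio; under the default constants all payoffs are strictly
   positive and the floor is inert (a warning is logged if it ever binds,
   e.g. in extreme fine sweeps).
4. **Group conflict.** Each group independently initiates at most one
   conflict with probability `s` against a uniformly drawn other group;
   conflicts are resolved sequentially in a uniformly random order against
   the current state (simultaneous resolution would make overlapping
   takeovers ill-defined). The initiator wins with probability
   `0.5·(1 + (d_j − d_i))`, where `d_g` is the strategy-based defector
   fraction of group `g`; the loser's count vector is overwritten by a
   copy of the winner's (cultural replacement of the whole group).
5. **Mutation.** Each individual, with probability `μ`, adopts a strategy
   drawn uniformly from the other available strategies — three
   alternatives under voluntary participation, two under compulsory, which
   is also what guarantees a compulsory population never contains a
   nonparticipant. Per-period records are taken after this stage.

Runs start from one all-punisher group and `N − 1` all-defector groups, so
global cooperation starts at `1/N`.

### The conflict-bias choice

The takeover rule deserves its own note because it is the one place where
two natural formulations, identical in the compulsory scenario, diverge
sharply under voluntary participation. Biasing the winner by defector
fractions (`0.5·(1 + (d_j − d_i))`, the rule of the classic
compulsory-participation group-selection models this one extends) makes an
all-nonparticipant group *conflict-neutral*: it neither beats nor loses to
a cooperative group beyond a coin flip, because neither contains
defectors. Biasing by cooperator fractions (`0.5·(1 + (x_i − x_j))`)
instead makes nonparticipant-heavy groups lose to cooperative groups
almost surely. Since `d = 1 − x` whenever nonparticipants are absent, the
two rules coincide exactly in the compulsory scenario and in any voluntary
run without mutation.

The difference matters enormously for the phenomenon the simulator
studies. Under the cooperator rule, group selection purges nonparticipant
groups so efficiently that a high outside payoff (`Ω = 1.05`) never
collapses cooperation in large groups (long-run cooperation stays ≈ 0.78,
above the compulsory baseline) and nonparticipation never exceeds a few
percent. Under the defector rule, exit-dominated groups persist through
conflict, the high outside payoff collapses cooperation (≈ 0.06, with
nonparticipation ≈ 0.8), and the inverted-U in `Ω` emerges — the joint
voluntary-participation/group-selection effect this class of models is
known for. We therefore default to `conflict_bias="defectors"` and expose
`"cooperators"` as an option; the equivalence of the two rules at `z = 0`
is covered by a test.

## Parameters

| name | meaning | default | notes |
|---|---|---|---|
| `N` | number of groups | 128 | |
| `n` | group size | swept 20–120 | sweep default {20, 40, ..., 120} |
| `b` | benefit at full cooperation | 0.5 | payoff units |
| `c` | contribution cost | 0.2 | |
| `p` | fine per punisher on a defector | 0.8 | `p·y` total at punisher fraction `y` |
| `k` | punishing cost per defector | 0.2 | `k·(1−x−z)` total |
| `m` | between-group imitation rate | 0.01 | conduit for strategy diffusion |
| `μ` | mutation rate | 0.01 | uniform over other available strategies |
| `s` | conflict initiation rate | 0.015 | per group per period |
| `e` | erroneous defection rate | 0.02 | cooperators only |
| `Ω` | nonparticipant payoff | swept 0.80–1.30 | grid step 0.05 |
| `periods` / `burn_in` | run length / discarded prefix | 2000 / 1000 | long-run = last 1000 |
| `replicates` | runs per sweep cell | 100 | sweeps at reduced scale use 10 |

The `Ω` sweep spans `[1 − c, 1 + b − c]`, the closed range of possible
contributor payoffs: below it the outside option is never competitive,
above it always. Values outside the range are permitted with a warning.
The grid step 0.05 includes the landmark values 0.80, 0.95, 1.05, 1.30;
the "moderate" profile value 0.925 sits between grid points and is used
directly where profiles at low/moderate/high outside payoffs are compared.

## Randomness and reproducibility

One root seed fully determines every run, sweep and CSV byte. Replicate
seed sequences come from `SeedSequence(root).spawn(replicates)`; sweep
cells key their streams by `(root, scenario, n, round(1000·Ω))` so a cell's
results do not depend on which other cells are swept alongside it. Each
run spawns four stage generators (error, imitation, conflict, mutation).
The canonical draw order per stage — the exact sequence and shapes of
vectorized RNG calls, and the group-major, class-ordered enumeration of
individuals — is documented in `pggsim.dynamics` and shared by the naive
agent-level reference implementation in the test suite, which recomputes
payoffs by explicit pairwise fine/cost accounting and updates one
individual at a time; the two implementations must and do agree exactly
over multi-period runs.

## Summaries and experiments

`long_run_average` averages each behavior frequency over the post-burn-in
periods within each replicate, then across replicates, reporting the s.d.
of per-replicate means; cooperation, defection and nonparticipation means
partition the population. The experiment layer sweeps `(scenario, n, Ω)`
cells into tidy CSV tables, computes voluntary-minus-compulsory difference
tables at a chosen `Ω`, and runs one-parameter sensitivity sweeps over
`m`, `μ` or `p`. Compulsory baseline cells are computed once per `n` and
shared across `Ω` comparisons.

Scaled-down profiles (10 replicates rather than 100, same 2,000 periods)
are the package's default for routine verification; they preserve the
sign, ordering and plateau structure of the full-scale experiments while
keeping a full sweep within minutes on one CPU. Cross-replicate standard
errors are reported alongside all means so that sign claims can be read
against sampling noise.

## What the defaults do and do not show

The default conditions are the study conditions: a single cooperative
seed group, equal group sizes, exogenous fixed `Ω`, and conflict as whole-
group cultural replacement. Passing behavior checks under these
conditions demonstrates the internal logic of the model — the inverted-U
in `Ω` at large `n`, the group-size sign flip, the sensitivity directions
— not claims about any empirical population. Known gaps between this
model family and real settings include: no migration outside imitation,
no group extinction/fission or size heterogeneity, no endogenous outside
payoff, and an imitation rule whose weak payoff sensitivity makes
within-group dynamics nearly neutral drifts at small payoff differences.

At the moderate outside payoff the model reproduces the directional
structure (defection reduced relative to compulsory, cooperation up in
large groups, down in small ones) with a persistent nonparticipant
minority on the order of a few percent of the population under the
default mutation scheme; reported plateau levels of nonparticipation
depend strongly on how mutation feeds the loner strategy and on the
conflict-bias rule, and are the least robust quantity in this model
family (see the acceptance notes in the repository for measured values).

**Founder extinction.** The dynamics are bistable: cooperation either
spreads from the single seeded punisher group to most of the population
within a few hundred periods, or the seed group is destroyed early and
cooperation stays at the mutation floor (~0.05) for the whole run. The
kill mechanism is ordinary conflict noise — an all-defector group takes
over the punisher group with probability `0.5·(1 + d_seed − d_attacker)`
per encounter, which is small (~0.03) but not zero, and standing loner
mutants raise it slightly by lowering the attacker's defector fraction.
In the voluntary scenario at `n = 120` roughly one to three replicates in
ten fail to take off; the compulsory scenario crashes more rarely. Cell
means over 10 replicates therefore mix two modes and carry large
cross-replicate standard deviations (~0.2–0.3) in the affected region
(`Ω ≈ 0.90–1.00`); sign and argmax statements about that region are
correspondingly seed-sensitive at this replicate count. Larger replicate
counts shrink the standard error of a cell mean but do not remove the
mixture shift itself: the long-run mean conditional on takeoff and the
takeoff probability are both reported facts of the model.

## Numerical notes

Counts are exact 64-bit integers; frequencies are double precision.
Degenerate inputs: `periods = 0` returns the initial state; group size
`n ≥ 2` and `N ≥ 2` are enforced so "another member" and "another group"
always exist; a tie in the conflict formula (equal defector fractions)
resolves to a fair coin by construction. The imitation payoff floor and
the validation rules (probabilities in `[0, 1]`, non-negative costs,
`burn_in ≤ periods`) are the only guards; no silent clipping occurs
elsewhere.
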