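# pggsim

Agent-based simulator for studying how **voluntary participation** and
**cultural group selection** jointly shape the evolution of cooperation and
altruistic punishment in public goods games.

## The model

A population of `N = 128` groups of size `n` plays a one-shot public goods
game every period. Four strategies compete:

| strategy | behavior |
|---|---|
| defector | participates, never contributes |
| contributor | contributes at cost `c` |
| punisher | contributes **and** fines every member who failed to contribute |
| nonparticipant (loner) | opts out entirely, earning a fixed outside payoff `Ω` |

"Cooperators" are contributors plus punishers. With `x`, `y`, `z` the group
fractions of cooperators, punishers and nonparticipants, error-free payoffs
are

```
contributor:     1 + b·x − c
defector:        1 + b·x − p·y
punisher:        1 + b·x − c − k·(1 − x − z)
nonparticipant:  Ω
```

with defaults `b = 0.5`, `c = 0.2`, fine `p = 0.8`, punishing cost
`k = 0.2`. Each period runs five stages: (1) each cooperator erroneously
defects with probability `e = 0.02`; (2) punishers fine all realized
defectors; (3) every individual imitates a model — from its own group with
probability `1 − m`, from another group with probability `m = 0.01` —
adopting the model's strategy with probability `w_model / (w_model + w_self)`;
(4) each group starts an intergroup conflict with probability `s = 0.015`,
and the winner, biased toward the group with fewer defectors, culturally
replaces the loser; (5) each individual mutates to a random other strategy
with probability `μ = 0.01`. Runs start from one all-punisher group among
127 all-defector groups. In the *compulsory* scenario the loner strategy is
removed; in the *voluntary* scenario `Ω` is swept over `[1 − c, 1 + b − c]
= [0.80, 1.30]`, the range of possible contributor payoffs.

The headline phenomenon is an **inverted-U**: in large groups (`n ≈ 120`) a
moderate outside payoff (`Ω ≈ 0.95`) raises long-run cooperation above the
compulsory baseline by giving would-be defectors an exit, while a high one
(`Ω ≥ 1.05`) drains participants entirely and collapses cooperation. In
small groups the exit option suppresses defection and cooperation alike.

## A worked example

```python
from pggsim import ParamSet, run_simulation

params = ParamSet(n=60, scenario="voluntary", omega=0.925, periods=2000)
frame = run_simulation(params, seed=7).to_frame()
tail = frame[frame.period >= 1000]
print(f"cooperation      {tail.freq_cooperation.mean():.3f}")
print(f"defection        {tail.freq_defector.mean():.3f}")
print(f"nonparticipation {tail.freq_nonparticipant.mean():.3f}")
```

prints

```
cooperation      0.833
defection        0.139
nonparticipation 0.028
```

cooperation spread from its initial 1/128 ≈ 0.008 to dominate the
population, defection survives as a free-riding minority inside cooperative
groups, and the outside option keeps a small nonparticipant fringe. The
`examples/` directory holds short scripts for each capability (payoff
anatomy, single runs, the inverted-U sweep, group-size difference tables,
sensitivity sweeps), each printing and explaining its numbers.

A thin CLI mirrors the library:

```sh
pggsim run --config config.toml --out out/       # one run -> CSV + metadata
pggsim sweep --group-size 120 --scale ci ...     # (n, Ω) cooperation surface
pggsim diff --omega 0.925 ...                    # voluntary − compulsory table
```

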