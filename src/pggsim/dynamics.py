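"""Stages 3–5 of a period: imitation, group conflict, mutation.

Stage 3 is synchronous payoff-biased imitation: every individual draws a
model — from its own group with probability ``1 - m``, from one uniformly
chosen other group with probability ``m`` — and adopts the model's
strategy with probability ``w_j / (w_j + w_i)``.  All adoptions are
applied simultaneously from the pre-step state.

Stage 4 is cultural group selection: each group initiates a conflict with
probability ``s`` against a uniformly chosen other group; the initiator
takes over with a probability biased by the groups' strategy-based
defector fractions (default) or cooperator fractions — see
:func:`group_conflict_step` and ``ParamSet.conflict_bias``.  The loser's
strategy counts are overwritten by a copy of the winner's.  Conflicts are
resolved sequentially in a uniformly random order against the current
(possibly already-overwritten) state.

Stage 5 is mutation: each individual, with probability ``mu``, replaces
its strategy with one drawn uniformly from the other available strategies
(three alternatives under voluntary participation, two under compulsory).

Canonical draw order
--------------------
Each stochastic stage consumes draws from its own dedicated generator as a
fixed sequence of vectorized calls whose shapes depend only on ``(N, n)``.
Individuals are enumerated group-major; within a group, in behavioral-class
order (defector, contributing contributor, erring contributor, contributing
punisher, erring punisher, nonparticipant) for imitation and in strategy
order for mutation.  The agent-level test oracle consumes the identical
sequence, so both implementations produce bit-identical trajectories from
the same seed.

* imitation: ``random(M)`` mixing, ``integers(0, N-1, M)`` other group,
  ``integers(0, n, M)`` member of other group, ``integers(0, n-1, M)``
  member of own group excluding self, ``random(M)`` adoption, with
  ``M = N * n``;
* conflict: ``random(N)`` initiation, ``integers(0, N-1, N)`` opponent,
  ``permutation(N)`` resolution order, ``random(N)`` winner;
* mutation: ``random(M)`` mutation flags, ``integers(0, n_alt, M)``
  alternative choice.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np

from .params import N_STRATEGIES, ParamSet, Strategy
from .payoffs import (
    CLASS_STRATEGY,
    class_counts,
    payoff_profile,
    realize_contributions,
)
from .state import global_frequencies

logger = logging.getLogger(__name__)

#: Floor applied to payoffs before forming w_j / (w_j + w_i).  Payoffs are
#: strictly positive under the default parameters; the floor only matters
#: in extreme sensitivity sweeps (very large fines).
PAYOFF_FLOOR = 1e-9

# Alternative-strategy lookup: ALT_TABLE[n_alt][strategy][choice] is the
# strategy adopted by a mutant of `strategy` drawing alternative `choice`
# uniformly from the other available strategies (sorted by index).
def _alt_table(available: int) -> np.ndarray:
    table = np.zeros((N_STRATEGIES, available - 1), dtype=np.int64)
    for s in range(N_STRATEGIES):
        alts = [t for t in range(available) if t != s]
        # strategies >= available never occur in that scenario; leave rows
        # for them pointing at the first alternatives (unused).
        table[s, :] = alts[: available - 1]
    return table


_ALT_COMPULSORY = _alt_table(3)
_ALT_VOLUNTARY = _alt_table(4)


class PeriodRecord(NamedTuple):
    """Global strategy frequencies at the end of a period."""

    period: int
    freq_defector: float
    freq_contributor: float
    freq_punisher: float
    freq_nonparticipant: float

    @property
    def freq_cooperation(self) -> float:
        return self.freq_contributor + self.freq_punisher


class StageRNGs(NamedTuple):
    """One generator per stochastic stage, spawned from a run seed.

    Dedicated substreams mean a refactor of one stage never silently
    perturbs the draws of another.
    """

    error: np.random.Generator
    imitation: np.random.Generator
    conflict: np.random.Generator
    mutation: np.random.Generator

    @classmethod
    def from_seed(cls, seed) -> "StageRNGs":
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        return cls(*(np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(4)))


# Static per-individual index arrays, cached per population shape.
_EXPAND_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}


def _expand_arrays(N: int, n: int):
    key = (N, n)
    hit = _EXPAND_CACHE.get(key)
    if hit is None:
        indiv_group = np.repeat(np.arange(N), n)
        pos_in_group = np.tile(np.arange(n), N)
        tiled_classes = np.tile(np.arange(6), N)
        tiled_strategies = np.tile(np.arange(N_STRATEGIES), N)
        hit = (indiv_group, pos_in_group, tiled_classes, tiled_strategies)
        _EXPAND_CACHE[key] = hit
    return hit


def _clamped(w: np.ndarray) -> np.ndarray:
    if (w <= 0).any():
        logger.warning(
            "clamped %d non-positive payoffs to %.0e before imitation",
            int((w <= 0).sum()),
            PAYOFF_FLOOR,
        )
        return np.maximum(w, PAYOFF_FLOOR)
    return w


def imitation_step(
    counts: np.ndarray,
    payoffs: np.ndarray,
    cls_counts: np.ndarray,
    m: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stage 3: synchronous payoff-biased imitation; returns new counts.

    ``payoffs`` and ``cls_counts`` are the ``(N, 6)`` per-class payoff
    profile and class counts of the current period.  Nonparticipants take
    part fully, as models (with payoff omega) and as imitators.
    """
    N, n = counts.shape[0], int(counts.sum(axis=1)[0])
    M = N * n

    # Per-individual expansion in canonical order.
    indiv_group, pos_in_group, tiled_classes, _ = _expand_arrays(N, n)
    indiv_class = np.repeat(tiled_classes, cls_counts.ravel())
    indiv_strategy = CLASS_STRATEGY[indiv_class]
    w_self = _clamped(payoffs[indiv_group, indiv_class])

    u_mix = rng.random(M)
    g_other = rng.integers(0, N - 1, M)
    j_other = rng.integers(0, n, M)
    j_own = rng.integers(0, n - 1, M)
    u_accept = rng.random(M)

    g_other = g_other + (g_other >= indiv_group)  # skip own group
    j_own = j_own + (j_own >= pos_in_group)  # exclude self
    external = u_mix < m
    model_idx = np.where(
        external, g_other * n + j_other, indiv_group * n + j_own
    )
    w_model = w_self[model_idx]
    adopt = u_accept < w_model / (w_model + w_self)
    new_strategy = np.where(adopt, indiv_strategy[model_idx], indiv_strategy)

    return (
        np.bincount(indiv_group * N_STRATEGIES + new_strategy, minlength=N * N_STRATEGIES)
        .reshape(N, N_STRATEGIES)
        .astype(np.int64)
    )


def group_conflict_step(
    counts: np.ndarray,
    s: float,
    rng: np.random.Generator,
    bias: str = "defectors",
) -> np.ndarray:
    """Stage 4: paired group conflicts with cultural takeover.

    With ``bias="defectors"`` the initiating group wins with probability
    ``0.5 * (1 + (d_j - d_i))`` (``d_g`` = strategy-based defector
    fraction); with ``bias="cooperators"`` it wins with probability
    ``0.5 * (1 + (x_i - x_j))`` (``x_g`` = cooperator fraction).  The two
    agree whenever nonparticipants are absent.
    """
    N = counts.shape[0]
    u_init = rng.random(N)
    opponent = rng.integers(0, N - 1, N)
    order = rng.permutation(N)
    u_win = rng.random(N)

    opponent = opponent + (opponent >= np.arange(N))
    counts = counts.copy()
    n = counts.sum(axis=1)
    for g in order:
        if u_init[g] >= s:
            continue
        j = opponent[g]
        if bias == "defectors":
            d_g = counts[g, Strategy.DEFECTOR] / n[g]
            d_j = counts[j, Strategy.DEFECTOR] / n[j]
            p_win = 0.5 * (1.0 + (d_j - d_g))
        else:
            x_g = (counts[g, Strategy.CONTRIBUTOR] + counts[g, Strategy.PUNISHER]) / n[g]
            x_j = (counts[j, Strategy.CONTRIBUTOR] + counts[j, Strategy.PUNISHER]) / n[j]
            p_win = 0.5 * (1.0 + (x_g - x_j))
        if u_win[g] < p_win:
            counts[j] = counts[g]
        else:
            counts[g] = counts[j]
    return counts


def mutation_step(
    counts: np.ndarray, mu: float, scenario_voluntary: bool, rng: np.random.Generator
) -> np.ndarray:
    """Stage 5: uniform mutation over the other available strategies."""
    N = counts.shape[0]
    n = int(counts.sum(axis=1)[0])
    M = N * n
    n_alt = 3 if scenario_voluntary else 2

    indiv_group, _, _, tiled_strategies = _expand_arrays(N, n)
    indiv_strategy = np.repeat(tiled_strategies, counts.ravel())
    u = rng.random(M)
    choice = rng.integers(0, n_alt, M)

    table = _ALT_VOLUNTARY if scenario_voluntary else _ALT_COMPULSORY
    mutated = np.where(u < mu, table[indiv_strategy, choice], indiv_strategy)
    return (
        np.bincount(indiv_group * N_STRATEGIES + mutated, minlength=N * N_STRATEGIES)
        .reshape(N, N_STRATEGIES)
        .astype(np.int64)
    )


def step(
    counts: np.ndarray,
    params: ParamSet,
    rngs: StageRNGs,
    period: int = 0,
) -> tuple[np.ndarray, PeriodRecord]:
    """One full period: error, punishment/payoffs, imitation, conflict, mutation.

    Returns the new state and a :class:`PeriodRecord` of the global
    strategy frequencies *after* all five stages.
    """
    c_err, p_err = realize_contributions(counts, params.e, rngs.error)
    payoffs = payoff_profile(counts, c_err, p_err, params)
    cls = class_counts(counts, c_err, p_err)
    counts = imitation_step(counts, payoffs, cls, params.m, rngs.imitation)
    counts = group_conflict_step(counts, params.s, rngs.conflict, params.conflict_bias)
    counts = mutation_step(counts, params.mu, params.voluntary, rngs.mutation)
    freq = global_frequencies(counts)
    return counts, PeriodRecord(period, *(float(f) for f in freq))
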