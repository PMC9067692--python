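"""Population state: per-group strategy counts and derived fractions.

Within a group, individuals of the same strategy are exchangeable except
for the per-period realized-behavior error, so the persistent state is
count-based: an ``(N, 4)`` integer array of strategy counts per group, in
the canonical strategy order defector, contributor, punisher,
nonparticipant.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .params import N_STRATEGIES, ParamSet, Strategy


class GroupState(NamedTuple):
    """Strategy counts of a single group (convenience view for small cases)."""

    n_D: int
    n_C: int
    n_P: int
    n_Z: int


def init_population(params: ParamSet) -> np.ndarray:
    """Initial population: one all-punisher group, the rest all defectors.

    Returns an ``(N, 4)`` int64 array of per-group strategy counts.  Group 0
    consists entirely of punishers; groups ``1..N-1`` entirely of defectors.
    Cooperation therefore starts at a global frequency of ``1/N``.
    """
    counts = np.zeros((params.N, N_STRATEGIES), dtype=np.int64)
    counts[0, Strategy.PUNISHER] = params.n
    counts[1:, Strategy.DEFECTOR] = params.n
    return counts


def fractions(group) -> tuple[float, float, float]:
    """Per-group fractions ``(x, y, z)``.

    ``x`` is the fraction of cooperators (contributors plus punishers),
    ``y`` the fraction of punishers, ``z`` the fraction of nonparticipants.
    Accepts any length-4 count sequence in canonical strategy order.
    """
    n_D, n_C, n_P, n_Z = (int(v) for v in group)
    n = n_D + n_C + n_P + n_Z
    if n <= 0:
        raise ValueError("group is empty")
    return ((n_C + n_P) / n, n_P / n, n_Z / n)


def cooperator_fraction(counts: np.ndarray) -> np.ndarray:
    """Vector of strategy-based cooperator fractions ``x_g`` per group."""
    n = counts.sum(axis=1)
    return (counts[:, Strategy.CONTRIBUTOR] + counts[:, Strategy.PUNISHER]) / n


def global_frequencies(counts: np.ndarray) -> np.ndarray:
    """Global frequency of each of the four strategies (sums to 1)."""
    total = counts.sum()
    return counts.sum(axis=0) / total


def check_state(counts: np.ndarray, params: ParamSet) -> None:
    """Assert the population-state invariants; raises ``ValueError``.

    Counts must be non-negative, every group must have exactly ``n``
    members, and a compulsory population must contain no nonparticipants.
    """
    counts = np.asarray(counts)
    if counts.shape != (params.N, N_STRATEGIES):
        raise ValueError(
            f"state shape {counts.shape} != ({params.N}, {N_STRATEGIES})"
        )
    if (counts < 0).any():
        raise ValueError("negative strategy count")
    if (counts.sum(axis=1) != params.n).any():
        raise ValueError("group sizes not conserved")
    if not params.voluntary and counts[:, Strategy.NONPARTICIPANT].any():
        raise ValueError("nonparticipants present in a compulsory population")
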