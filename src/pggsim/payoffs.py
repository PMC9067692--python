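"""Stages 1–2 of a period: erroneous defection, punishment, payoffs.

Stage 1 realizes contributions: each cooperator (contributor or punisher)
contributes with probability ``1 - e`` and erroneously defects with
probability ``e``; defectors always defect and nonparticipants abstain.
Stage 2 is punishment: every punisher fines every group member who
defected during stage 1, at cost ``k/n`` per punisher-defector pair and
fine ``p/n`` per pair.  With the pairwise accounting the class totals
reduce, at ``e = 0``, to the fraction form

    contributor:    1 + b*x - c
    defector:       1 + b*x - p*y
    punisher:       1 + b*x - c - k*(1 - x - z)

with ``x`` the cooperator fraction, ``y`` the punisher fraction and ``z``
the nonparticipant fraction of the group (``z = 0`` under compulsory
participation).  The public-good benefit uses the *realized* contribution
fraction, since only realized contributions produce the good.

Behavioral subclasses: payoffs differ within a strategy depending on
whether a cooperator erred, so each group carries six payoff classes per
period, indexed by the ``CL_*`` constants below.
"""

from __future__ import annotations

import numpy as np

from .params import ParamSet, Strategy
from .state import GroupState

# Behavioral-subclass indices for the per-period payoff profile.
CL_DEFECTOR = 0
CL_CONTRIB_OK = 1
CL_CONTRIB_ERR = 2
CL_PUNISH_OK = 3
CL_PUNISH_ERR = 4
CL_NONPARTICIPANT = 5
N_CLASSES = 6

#: Strategy of each behavioral subclass.
CLASS_STRATEGY = np.array(
    [
        Strategy.DEFECTOR,
        Strategy.CONTRIBUTOR,
        Strategy.CONTRIBUTOR,
        Strategy.PUNISHER,
        Strategy.PUNISHER,
        Strategy.NONPARTICIPANT,
    ],
    dtype=np.int64,
)


def realize_contributions(
    counts: np.ndarray, e: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stage 1: draw erroneous defections for every group.

    Returns ``(c_err, p_err)``: per-group counts of contributors and
    punishers who failed to contribute this period, drawn independently as
    ``Binomial(n_C, e)`` and ``Binomial(n_P, e)``.

    Draw order (shared with the agent-level test oracle): one vectorized
    binomial draw for all contributors, then one for all punishers.
    """
    c_err = rng.binomial(counts[:, Strategy.CONTRIBUTOR], e)
    p_err = rng.binomial(counts[:, Strategy.PUNISHER], e)
    return c_err.astype(np.int64), p_err.astype(np.int64)


def class_counts(counts: np.ndarray, c_err: np.ndarray, p_err: np.ndarray) -> np.ndarray:
    """Per-group counts of the six behavioral subclasses, shape ``(N, 6)``."""
    out = np.empty((counts.shape[0], N_CLASSES), dtype=np.int64)
    out[:, CL_DEFECTOR] = counts[:, Strategy.DEFECTOR]
    out[:, CL_CONTRIB_OK] = counts[:, Strategy.CONTRIBUTOR] - c_err
    out[:, CL_CONTRIB_ERR] = c_err
    out[:, CL_PUNISH_OK] = counts[:, Strategy.PUNISHER] - p_err
    out[:, CL_PUNISH_ERR] = p_err
    out[:, CL_NONPARTICIPANT] = counts[:, Strategy.NONPARTICIPANT]
    return out


def payoff_profile(
    counts: np.ndarray,
    c_err: np.ndarray,
    p_err: np.ndarray,
    params: ParamSet,
) -> np.ndarray:
    """Stage 2: payoff of every behavioral subclass in every group.

    Returns an ``(N, 6)`` float array indexed by the ``CL_*`` constants.
    Deterministic given ``(counts, c_err, p_err, params)``.

    With ``A`` the realized contributor count, ``x_hat = A / n`` the
    realized contribution fraction and ``D_hat`` the realized
    participant-defector count:

    * defector and erring cooperator: ``1 + b*x_hat - p*n_P/n`` — fined by
      every (non-erring) punisher;
    * contributing contributor: ``1 + b*x_hat - c``;
    * contributing punisher: ``1 + b*x_hat - c - (k/n)*D_hat``;
    * erring punisher: ``1 + b*x_hat - p*(n_P - 1)/n - (k/n)*(D_hat - 1)``
      — still punishes the *other* realized defectors and is fined by the
      other punishers, but never punishes itself;
    * nonparticipant: ``omega`` exactly, independent of the group.

    Nonparticipants are never punished and never punish.
    """
    counts = np.asarray(counts)
    if not params.voluntary and counts[:, Strategy.NONPARTICIPANT].any():
        raise ValueError("nonparticipants present in a compulsory population")
    n = params.n
    n_P = counts[:, Strategy.PUNISHER]
    a = (counts[:, Strategy.CONTRIBUTOR] - c_err) + (n_P - p_err)
    d_hat = counts[:, Strategy.DEFECTOR] + c_err + p_err
    base = 1.0 + params.b * (a / n)
    fine_full = params.p * n_P / n  # fine on a realized defector who is not a punisher

    w = np.empty((counts.shape[0], N_CLASSES), dtype=np.float64)
    w[:, CL_DEFECTOR] = base - fine_full
    w[:, CL_CONTRIB_OK] = base - params.c
    w[:, CL_CONTRIB_ERR] = base - fine_full
    w[:, CL_PUNISH_OK] = base - params.c - (params.k / n) * d_hat
    # erring punisher: fined by the other n_P - 1 punishers, fines the other
    # D_hat - 1 realized defectors (n_P >= 1 and D_hat >= 1 whenever p_err > 0)
    w[:, CL_PUNISH_ERR] = (
        base - params.p * (n_P - 1) / n - (params.k / n) * (d_hat - 1)
    )
    w[:, CL_NONPARTICIPANT] = params.omega if params.omega is not None else np.nan
    return w


def participant_payoffs(
    group: GroupState | tuple, params: ParamSet, c_err: int = 0, p_err: int = 0
) -> dict[str, float]:
    """Single-group payoff profile as a named mapping (convenience).

    Keys: ``defector``, ``contributor_ok``, ``contributor_err``,
    ``punisher_ok``, ``punisher_err``, ``nonparticipant``.
    """
    counts = np.asarray(group, dtype=np.int64)[None, :]
    prof = payoff_profile(
        counts, np.array([c_err]), np.array([p_err]), params
    )[0]
    return {
        "defector": float(prof[CL_DEFECTOR]),
        "contributor_ok": float(prof[CL_CONTRIB_OK]),
        "contributor_err": float(prof[CL_CONTRIB_ERR]),
        "punisher_ok": float(prof[CL_PUNISH_OK]),
        "punisher_err": float(prof[CL_PUNISH_ERR]),
        "nonparticipant": float(prof[CL_NONPARTICIPANT]),
    }


def contributor_payoff(x: float, params: ParamSet) -> float:
    """Closed-form contributor payoff ``1 + b*x - c`` at cooperator fraction x."""
    return 1.0 + params.b * x - params.c
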