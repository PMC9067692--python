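"""Naive agent-level reference implementation used by the test suite.

Every individual is represented explicitly and every stage is computed
with plain Python loops: payoffs by summing fines and punishing costs over
punisher x realized-defector pairs, imitation one individual at a time,
conflicts one at a time, mutation one individual at a time.  The only
thing shared with the production engine is the canonical draw order
documented in ``pggsim.dynamics`` (the same sequence of vectorized RNG
calls), which is what makes trajectories comparable bit-for-bit.
"""

from __future__ import annotations

import numpy as np

from pggsim.dynamics import PAYOFF_FLOOR, StageRNGs
from pggsim.params import ParamSet, Strategy

D, C, P, Z = (
    Strategy.DEFECTOR,
    Strategy.CONTRIBUTOR,
    Strategy.PUNISHER,
    Strategy.NONPARTICIPANT,
)


def _expand_classes(counts_row, c_err, p_err):
    """Individuals of one group in canonical behavioral-class order.

    Returns a list of (strategy, contributed) pairs.
    """
    n_D, n_C, n_P, n_Z = (int(v) for v in counts_row)
    out = [(D, False)] * n_D
    out += [(C, True)] * (n_C - c_err) + [(C, False)] * c_err
    out += [(P, True)] * (n_P - p_err) + [(P, False)] * p_err
    out += [(Z, False)] * n_Z
    return out


def oracle_payoffs(members, params: ParamSet):
    """Per-individual payoffs of one group by pairwise accounting.

    ``members`` is the list of (strategy, contributed) pairs.  Each
    realized contributor produces 1/n of the public good scaled by b; each
    punisher fines (p/n) every *other* member who participated but did not
    contribute, paying k/n per fined member.
    """
    n = params.n
    a = sum(1 for s, contributed in members if contributed)
    payoffs = []
    for i, (s_i, contrib_i) in enumerate(members):
        if s_i == Z:
            payoffs.append(float(params.omega))
            continue
        w = 1.0 + params.b * a / n
        if contrib_i:
            w -= params.c
        for j, (s_j, contrib_j) in enumerate(members):
            if i == j:
                continue
            # j punishes i if j is a punisher and i participated w/o contributing
            if s_j == P and s_i != Z and not contrib_i:
                w -= params.p / n
            # i pays punishing cost for each realized defector j
            if s_i == P and s_j != Z and not contrib_j:
                w -= params.k / n
        payoffs.append(w)
    return payoffs


def oracle_step(counts: np.ndarray, params: ParamSet, rngs: StageRNGs) -> np.ndarray:
    """One full period of the naive reference model; returns new counts."""
    N, n = params.N, params.n
    M = N * n

    # stage 1 (draw order shared with the engine)
    c_err = rngs.error.binomial(counts[:, C], params.e)
    p_err = rngs.error.binomial(counts[:, P], params.e)

    groups = [
        _expand_classes(counts[g], int(c_err[g]), int(p_err[g])) for g in range(N)
    ]
    # stage 2
    w = [oracle_payoffs(members, params) for members in groups]

    # stage 3: synchronous imitation
    u_mix = rngs.imitation.random(M)
    g_other = rngs.imitation.integers(0, N - 1, M)
    j_other = rngs.imitation.integers(0, n, M)
    j_own = rngs.imitation.integers(0, n - 1, M)
    u_acc = rngs.imitation.random(M)

    new_strats = [[s for s, _ in members] for members in groups]
    for g in range(N):
        for pos in range(n):
            i = g * n + pos
            if u_mix[i] < params.m:
                go = int(g_other[i])
                if go >= g:
                    go += 1
                mg, mj = go, int(j_other[i])
            else:
                jj = int(j_own[i])
                if jj >= pos:
                    jj += 1
                mg, mj = g, jj
            w_i = max(w[g][pos], PAYOFF_FLOOR)
            w_j = max(w[mg][mj], PAYOFF_FLOOR)
            if u_acc[i] < w_j / (w_j + w_i):
                new_strats[g][pos] = groups[mg][mj][0]

    new_counts = np.zeros_like(counts)
    for g in range(N):
        for s in new_strats[g]:
            new_counts[g, s] += 1

    # stage 4: sequential conflicts in random order
    u_init = rngs.conflict.random(N)
    opp = rngs.conflict.integers(0, N - 1, N)
    order = rngs.conflict.permutation(N)
    u_win = rngs.conflict.random(N)
    for g in order:
        if u_init[g] >= params.s:
            continue
        j = int(opp[g])
        if j >= g:
            j += 1
        if params.conflict_bias == "defectors":
            p_win = 0.5 * (1.0 + (new_counts[j, D] - new_counts[g, D]) / n)
        else:
            x_g = (new_counts[g, C] + new_counts[g, P]) / n
            x_j = (new_counts[j, C] + new_counts[j, P]) / n
            p_win = 0.5 * (1.0 + (x_g - x_j))
        if u_win[g] < p_win:
            new_counts[j] = new_counts[g]
        else:
            new_counts[g] = new_counts[j]

    # stage 5: mutation, individuals in strategy order per group
    u_mut = rngs.mutation.random(M)
    n_alt = 3 if params.voluntary else 2
    choice = rngs.mutation.integers(0, n_alt, M)
    available = [D, C, P, Z] if params.voluntary else [D, C, P]
    final = np.zeros_like(counts)
    i = 0
    for g in range(N):
        for s in (D, C, P, Z):
            for _ in range(int(new_counts[g, s])):
                if u_mut[i] < params.mu:
                    alts = [t for t in available if t != s]
                    final[g, alts[int(choice[i])]] += 1
                else:
                    final[g, s] += 1
                i += 1
    return final
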