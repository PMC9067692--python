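"""Payoff anatomy of a single group.

Evaluates the closed-form payoffs of every behavioral class in a group
that is 30% or 50% cooperators, under the default constants (benefit
b=0.5, contribution cost c=0.2, fine p=0.8, punishing cost k=0.2).  The
contributor payoffs at these two compositions, 0.95 and 1.05, are the
anchors used to choose "moderate" and "high" outside payoffs for
nonparticipants.
"""

from pggsim import ParamSet, participant_payoffs

params = ParamSet(n=20, scenario="compulsory", e=0.0)

for coop in (6, 10):  # 30% and 50% of a 20-member group
    group = (20 - coop, coop, 0, 0)  # defectors, contributors, punishers, loners
    w = participant_payoffs(group, params)
    x = coop / 20
    print(f"cooperator fraction x={x:.2f}:")
    print(f"  contributor earns {w['contributor_ok']:.3f}  (1 + b*x - c)")
    print(f"  defector earns    {w['defector']:.3f}  (no punishers in this group)")

lo, hi = params.omega_feasible_range()
print(f"feasible outside payoffs: {lo:.2f} (worthless good) to {hi:.2f} (full cooperation)")
# A loner payoff inside this range competes with contributing at some
# intermediate level of group cooperation; outside it, never or always.
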