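"""Model parameters and the strategy taxonomy.

The population plays a one-shot public goods game each period. Four
strategies exist:

* ``DEFECTOR`` — participates but never contributes.
* ``CONTRIBUTOR`` — contributes to the public good, does not punish.
* ``PUNISHER`` — contributes and fines every group member who failed to
  contribute that period.
* ``NONPARTICIPANT`` — opts out of the game entirely and collects a fixed
  outside payoff ``omega``, neither producing nor consuming the public good.

"Cooperators" means contributors plus punishers.  In the *compulsory*
scenario the nonparticipant strategy is removed from the strategy set, so
its count is zero at all times.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, fields, replace


class Strategy(enum.IntEnum):
    """The four strategies, in canonical index order."""

    DEFECTOR = 0
    CONTRIBUTOR = 1
    PUNISHER = 2
    NONPARTICIPANT = 3


#: Number of strategies (array axis length for per-group counts).
N_STRATEGIES = 4

#: Scenario names.
COMPULSORY = "compulsory"
VOLUNTARY = "voluntary"
SCENARIOS = (COMPULSORY, VOLUNTARY)


class ParamError(ValueError):
    """Invalid model parameter; the message names the offending field."""


@dataclass(frozen=True)
class ParamSet:
    """All model constants plus run-control settings.

    Payoff units are dimensionless fitness: a lone participant in a group
    with no cooperators and no punishers earns the baseline 1.

    Parameters
    ----------
    N : int
        Number of groups (default 128).
    n : int
        Group size; every group has exactly ``n`` members.
    b : float
        Public good benefit to each participant if everyone cooperates;
        the realized benefit is ``b`` times the fraction of contributors.
    c : float
        Individual cost of contributing.
    p : float
        Fine received from *each* punisher by a member who defected
        (total fine ``p * y`` at punisher fraction ``y``).
    k : float
        Cost paid by a punisher for *each* defector it fines
        (total cost ``k`` times the defector fraction).
    m : float
        Between-group mixing rate: probability that an imitation model is
        drawn from another group instead of one's own.
    mu : float
        Mutation rate: per-individual probability of switching to a
        uniformly drawn alternative strategy each period.
    s : float
        Group-pairing rate: per-group probability of initiating an
        intergroup conflict each period.
    e : float
        Erroneous defection rate: probability that a cooperator fails to
        contribute in a given period.
    omega : float or None
        Nonparticipants' fixed outside payoff.  Required in the voluntary
        scenario; ignored (and may be None) in the compulsory scenario.
    scenario : str
        ``"voluntary"`` or ``"compulsory"``.
    conflict_bias : str
        Group-level statistic biasing conflict outcomes.  ``"defectors"``
        (default): group *i* takes over group *j* with probability
        ``0.5 * (1 + (d_j - d_i))`` where ``d_g`` is the defector fraction,
        the rule of the compulsory-participation lineage this model extends.
        ``"cooperators"``: ``0.5 * (1 + (x_i - x_j))`` with ``x_g`` the
        cooperator fraction.  The two coincide whenever no nonparticipants
        exist (``d = 1 - x``); under voluntary participation they differ in
        how nonparticipant-heavy groups fare in conflict (neutral under the
        defector rule, nearly always losing under the cooperator rule),
        which strongly affects whether nonparticipation can persist.
    periods : int
        Number of periods per run.
    burn_in : int
        Periods discarded before long-run averaging.
    replicates : int
        Number of replicate runs for sweeps.
    seed : int
        Root seed for sweep-level replicate spawning.
    """

    N: int = 128
    n: int = 20
    b: float = 0.5
    c: float = 0.2
    p: float = 0.8
    k: float = 0.2
    m: float = 0.01
    mu: float = 0.01
    s: float = 0.015
    e: float = 0.02
    omega: float | None = None
    scenario: str = VOLUNTARY
    conflict_bias: str = "defectors"
    periods: int = 2000
    burn_in: int = 1000
    replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        validate_params(self)

    @property
    def voluntary(self) -> bool:
        return self.scenario == VOLUNTARY

    @property
    def n_individuals(self) -> int:
        return self.N * self.n

    def omega_feasible_range(self) -> tuple[float, float]:
        """Feasible range of the outside payoff.

        A contributor earns between ``1 - c`` (no cooperators) and
        ``1 + b - c`` (full cooperation); an outside option below or above
        that range is never, respectively always, competitive with
        contributing.
        """
        return (1.0 - self.c, 1.0 + self.b - self.c)

    def with_overrides(self, **kwargs) -> "ParamSet":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)


def validate_params(params: ParamSet) -> None:
    """Raise :class:`ParamError` naming the first offending field."""
    if not isinstance(params.N, int) or params.N < 2:
        raise ParamError(f"N must be an integer >= 2, got {params.N!r}")
    if not isinstance(params.n, int) or params.n < 2:
        raise ParamError(f"n must be an integer >= 2, got {params.n!r}")
    for name in ("b", "c", "p", "k"):
        v = getattr(params, name)
        if not math.isfinite(v) or v < 0:
            raise ParamError(f"{name} must be a finite non-negative number, got {v!r}")
    for name in ("m", "mu", "s", "e"):
        v = getattr(params, name)
        if not (0.0 <= v <= 1.0):
            raise ParamError(f"{name} must be a probability in [0, 1], got {v!r}")
    if params.scenario not in SCENARIOS:
        raise ParamError(
            f"scenario must be one of {SCENARIOS}, got {params.scenario!r}"
        )
    if params.conflict_bias not in ("defectors", "cooperators"):
        raise ParamError(
            "conflict_bias must be 'defectors' or 'cooperators', "
            f"got {params.conflict_bias!r}"
        )
    if params.voluntary:
        if params.omega is None:
            raise ParamError("omega is required in the voluntary scenario")
        if not math.isfinite(params.omega):
            raise ParamError(f"omega must be finite, got {params.omega!r}")
        lo, hi = params.omega_feasible_range()
        if not (lo <= params.omega <= hi):
            warnings.warn(
                f"omega={params.omega} lies outside the feasible contributor "
                f"payoff range [{lo}, {hi}]; the run proceeds but the outside "
                "option is then never/always competitive",
                stacklevel=3,
            )
    if params.periods < 0:
        raise ParamError(f"periods must be >= 0, got {params.periods!r}")
    if not (0 <= params.burn_in <= params.periods):
        raise ParamError(
            f"burn_in must satisfy 0 <= burn_in <= periods, got {params.burn_in!r}"
        )
    if params.replicates < 1:
        raise ParamError(f"replicates must be >= 1, got {params.replicates!r}")


#: Default sweep grids: the six group sizes and the outside-payoff grid in
#: steps of 0.05 spanning the feasible contributor-payoff range.
DEFAULT_N_GRID = (20, 40, 60, 80, 100, 120)
DEFAULT_OMEGA_GRID = tuple(round(0.80 + 0.05 * i, 2) for i in range(11))

PARAM_FIELD_NAMES = tuple(f.name for f in fields(ParamSet))
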