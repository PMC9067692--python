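"""Batch experiments: sweeps over group size, outside payoff, and
sensitivity parameters, plus voluntary-minus-compulsory difference tables.

Every experiment is a pure function of its grid and root seed; re-running
reproduces the output exactly.  Compulsory baseline cells depend on
neither ``omega`` nor the scenario-specific mutation support, so each
``(scenario=compulsory, n)`` cell is computed once and shared across all
omega comparisons within a sweep.  Each cell's replicate seeds are
derived from ``(root_seed, cell key)`` so adding cells never reshuffles
the seeds of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .params import (
    COMPULSORY,
    DEFAULT_N_GRID,
    DEFAULT_OMEGA_GRID,
    VOLUNTARY,
    ParamSet,
)
from .simulate import long_run_average, replicate_seeds, run_simulation

#: The three outside-payoff landmarks used in behavior-profile comparisons:
#: low, moderate, high.
PROFILE_OMEGAS = (0.80, 0.925, 1.05)


@dataclass(frozen=True)
class SweepGrid:
    """A sweep: which cells to run and at what scale.

    ``base`` carries the model constants and run-control settings shared
    by all cells; ``scenarios``, ``n_values`` and ``omega_values`` define
    the cells.  Compulsory cells ignore ``omega_values`` and appear once
    per ``n`` with omega reported as NaN ("N/A").
    """

    scenarios: tuple[str, ...] = (COMPULSORY, VOLUNTARY)
    n_values: tuple[int, ...] = DEFAULT_N_GRID
    omega_values: tuple[float, ...] = DEFAULT_OMEGA_GRID
    base: ParamSet = field(
        default_factory=lambda: ParamSet(scenario=COMPULSORY, omega=None)
    )

    def cells(self) -> list[ParamSet]:
        out = []
        for n in self.n_values:
            if COMPULSORY in self.scenarios:
                out.append(replace(self.base, scenario=COMPULSORY, omega=None, n=n))
            if VOLUNTARY in self.scenarios:
                for omega in self.omega_values:
                    out.append(
                        replace(self.base, scenario=VOLUNTARY, omega=omega, n=n)
                    )
        return out


def _cell_seed(root_seed: int, params: ParamSet) -> np.random.SeedSequence:
    """Deterministic seed sequence for one sweep cell.

    Keyed by scenario, group size and the omega grid index (in hundredths
    of a payoff unit) so every cell gets an independent stream regardless
    of sweep composition.
    """
    omega_key = 0 if params.omega is None else int(round(params.omega * 1000))
    scen_key = 0 if params.scenario == COMPULSORY else 1
    return np.random.SeedSequence([root_seed, scen_key, params.n, omega_key])


def run_cell(params: ParamSet, root_seed: int) -> pd.DataFrame:
    """Run one sweep cell (all replicates) and summarize it."""
    seeds = _cell_seed(root_seed, params).spawn(params.replicates)
    results = [run_simulation(params, ss) for ss in seeds]
    return long_run_average(results)


def run_sweep(grid: SweepGrid, root_seed: int, progress=None) -> pd.DataFrame:
    """Run every cell of a grid; returns one tidy summary row per cell."""
    rows = []
    for cell in grid.cells():
        rows.append(run_cell(cell, root_seed))
        if progress is not None:
            progress(cell)
    table = pd.concat(rows, ignore_index=True)
    for name in ("m", "mu", "p"):
        table[name] = getattr(grid.base, name)
    return table


def cooperation_sweep(grid: SweepGrid, root_seed: int, progress=None) -> pd.DataFrame:
    """Long-run cooperation over the (n, omega) surface plus compulsory baselines.

    The central experiment: for each group size, sweep the outside payoff
    omega across the voluntary scenario and compare against the matched
    compulsory baseline.  An empty omega grid yields a compulsory-only
    baseline table.
    """
    if not grid.omega_values:
        grid = replace(grid, scenarios=(COMPULSORY,))
    return run_sweep(grid, root_seed, progress=progress)


def behavior_profiles(
    grid: SweepGrid | None = None,
    root_seed: int = 0,
    progress=None,
) -> pd.DataFrame:
    """Cooperation, defection and nonparticipation at the three omega landmarks.

    Defaults to omega in ``(0.80, 0.925, 1.05)`` — the low, moderate and
    high outside payoffs — plus the compulsory baseline, across the
    default group sizes.
    """
    if grid is None:
        grid = SweepGrid(omega_values=PROFILE_OMEGAS)
    return run_sweep(grid, root_seed, progress=progress)


def scenario_differences(
    summary: pd.DataFrame | None = None,
    grid: SweepGrid | None = None,
    root_seed: int = 0,
    omega: float = 0.925,
) -> pd.DataFrame:
    """Voluntary-minus-compulsory frequency differences per behavior and n.

    For each group size, subtracts the compulsory long-run mean of each
    behavior from the voluntary mean at the given omega (default: the
    moderate outside payoff 0.925).  Either pass a summary table already
    containing the matched cells, or a grid to run.
    """
    if summary is None:
        if grid is None:
            grid = SweepGrid(n_values=(20, 60, 120), omega_values=(omega,))
        summary = run_sweep(grid, root_seed)
    vol = summary[
        (summary["scenario"] == VOLUNTARY) & np.isclose(summary["omega"], omega)
    ].set_index("n")
    comp = summary[summary["scenario"] == COMPULSORY].set_index("n")
    missing = set(vol.index) ^ set(comp.index)
    if missing or vol.empty:
        raise ValueError(
            f"unmatched scenario cells for omega={omega}: group sizes {sorted(missing)}"
        )
    rows = []
    for n in vol.index:
        rows.append(
            {
                "n": n,
                "omega": omega,
                "delta_cooperation": vol.loc[n, "freq_cooperation_mean"]
                - comp.loc[n, "freq_cooperation_mean"],
                "delta_defection": vol.loc[n, "freq_defection_mean"]
                - comp.loc[n, "freq_defection_mean"],
                "delta_nonparticipation": vol.loc[n, "freq_nonparticipation_mean"]
                - comp.loc[n, "freq_nonparticipation_mean"],
            }
        )
    return pd.DataFrame(rows)


def sensitivity_sweep(
    parameter: str,
    values: tuple[float, ...],
    base: ParamSet,
    root_seed: int = 0,
    progress=None,
) -> pd.DataFrame:
    """Sweep exactly one of the rates ``m``, ``mu`` or the fine ``p``.

    All other parameters stay at ``base``; when ``p`` is varied to 0 the
    caller typically also sets ``k=0`` in ``base`` to remove punishment
    entirely.  Returns one summary row per value, indexed by the varied
    parameter.
    """
    if parameter not in ("m", "mu", "p"):
        raise ValueError(
            f"sensitivity parameter must be one of 'm', 'mu', 'p', got {parameter!r}"
        )
    rows = []
    for i, v in enumerate(values):
        cell = replace(base, **{parameter: v})
        seeds = np.random.SeedSequence(
            [root_seed, 97, i, cell.n]
        ).spawn(cell.replicates)
        results = [run_simulation(cell, ss) for ss in seeds]
        row = long_run_average(results)
        row[parameter] = v
        rows.append(row)
        if progress is not None:
            progress(cell)
    table = pd.concat(rows, ignore_index=True)
    table["varied"] = parameter
    return table
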