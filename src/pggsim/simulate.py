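"""Run orchestration: initialize, iterate periods, aggregate replicates.

A run is deterministic given its seed.  Replicate seeds for sweeps are
derived from the root seed through a NumPy seed-sequence spawner
(``SeedSequence(root).spawn(replicates)``), so sweeps are reproducible
and can be parallelized by replicate without changing results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import PeriodRecord, StageRNGs, step
from .params import ParamSet, Strategy
from .state import init_population

#: Column order of the per-period time-series frame.
RUN_COLUMNS = (
    "period",
    "freq_defector",
    "freq_contributor",
    "freq_punisher",
    "freq_nonparticipant",
    "freq_cooperation",
)


@dataclass(frozen=True)
class RunResult:
    """Per-period global strategy frequencies of a single run."""

    params: ParamSet
    seed: int
    frequencies: np.ndarray  # shape (periods, 4), strategy order
    final_counts: np.ndarray  # shape (N, 4)

    def __post_init__(self) -> None:
        if self.frequencies.shape != (self.params.periods, 4):
            raise ValueError("frequency record length must equal params.periods")

    def to_frame(self) -> pd.DataFrame:
        """Time series as a tidy DataFrame (one row per period)."""
        f = self.frequencies
        return pd.DataFrame(
            {
                "period": np.arange(len(f)),
                "freq_defector": f[:, Strategy.DEFECTOR],
                "freq_contributor": f[:, Strategy.CONTRIBUTOR],
                "freq_punisher": f[:, Strategy.PUNISHER],
                "freq_nonparticipant": f[:, Strategy.NONPARTICIPANT],
                "freq_cooperation": f[:, Strategy.CONTRIBUTOR] + f[:, Strategy.PUNISHER],
            }
        )

    def records(self) -> list[PeriodRecord]:
        return [PeriodRecord(t, *row) for t, row in enumerate(self.frequencies)]


def run_simulation(params: ParamSet, seed) -> RunResult:
    """Run one simulation of ``params.periods`` periods.

    ``seed`` may be an integer or a ``numpy.random.SeedSequence``.  The
    population starts from one all-punisher group among all-defector
    groups; each period applies the five stages in order.
    """
    rngs = StageRNGs.from_seed(seed)
    counts = init_population(params)
    freqs = np.empty((params.periods, 4), dtype=np.float64)
    for t in range(params.periods):
        counts, rec = step(counts, params, rngs, period=t)
        freqs[t] = rec[1:5]
    seed_label = seed if isinstance(seed, (int, np.integer)) else -1
    return RunResult(params=params, seed=int(seed_label), frequencies=freqs, final_counts=counts)


def replicate_seeds(root_seed: int, replicates: int) -> list[np.random.SeedSequence]:
    """Deterministic per-replicate seed sequences from a root seed."""
    return np.random.SeedSequence(root_seed).spawn(replicates)


def run_replicates(params: ParamSet, root_seed: int | None = None) -> list[RunResult]:
    """Run ``params.replicates`` independent replicates."""
    root = params.seed if root_seed is None else root_seed
    return [
        run_simulation(params, ss)
        for ss in replicate_seeds(root, params.replicates)
    ]


def long_run_average(
    results: list[RunResult], burn_in: int | None = None
) -> pd.DataFrame:
    """Long-run mean behavior frequencies over replicates.

    Averages each frequency over periods ``(burn_in, periods]`` within
    each replicate, then across replicates; dispersion is the standard
    deviation of per-replicate means.  All results must share one
    parameter set.  Returns a single-row DataFrame with columns
    ``scenario, n, omega, replicates`` and
    ``freq_{cooperation,defection,nonparticipation}_{mean,sd}``.
    """
    if not results:
        raise ValueError("no results to average")
    params = results[0].params
    if any(r.params != params for r in results[1:]):
        raise ValueError("results come from different parameter sets")
    if burn_in is None:
        burn_in = params.burn_in
    if burn_in >= params.periods:
        raise ValueError("burn_in must be smaller than periods")

    per_rep = np.array(
        [r.frequencies[burn_in:].mean(axis=0) for r in results]
    )  # (replicates, 4)
    coop = per_rep[:, Strategy.CONTRIBUTOR] + per_rep[:, Strategy.PUNISHER]
    defe = per_rep[:, Strategy.DEFECTOR]
    nonp = per_rep[:, Strategy.NONPARTICIPANT]
    return pd.DataFrame(
        {
            "scenario": [params.scenario],
            "n": [params.n],
            "omega": [params.omega if params.voluntary else np.nan],
            "replicates": [len(results)],
            "freq_cooperation_mean": [coop.mean()],
            "freq_cooperation_sd": [coop.std(ddof=1) if len(coop) > 1 else 0.0],
            "freq_defection_mean": [defe.mean()],
            "freq_defection_sd": [defe.std(ddof=1) if len(defe) > 1 else 0.0],
            "freq_nonparticipation_mean": [nonp.mean()],
            "freq_nonparticipation_sd": [nonp.std(ddof=1) if len(nonp) > 1 else 0.0],
        }
    )


def summarize_cell(params: ParamSet, root_seed: int | None = None) -> pd.DataFrame:
    """Run replicates for one parameter cell and return its long-run summary."""
    return long_run_average(run_replicates(params, root_seed))
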