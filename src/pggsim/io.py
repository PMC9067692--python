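"""Configuration loading and result serialization.

Configs are TOML documents mapping ParamSet field names to values; unknown
keys are rejected.  All defaults follow the model's default parameter
table, except ``n`` and (for voluntary runs) ``omega``, which must be
given explicitly because they are the swept quantities.

Results are written as UTF-8 CSV with a mandatory header row plus a
sidecar JSON metadata file carrying the full parameter set, the seed and
the software version, sufficient to reproduce the run exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from pathlib import Path

import pandas as pd

from . import __version__
from .params import PARAM_FIELD_NAMES, COMPULSORY, ParamError, ParamSet
from .simulate import RunResult

logger = logging.getLogger(__name__)


def load_config(path: str | Path) -> ParamSet:
    """Load and validate a parameter configuration from a TOML file.

    Raises :class:`ParamError` naming the field for unknown keys,
    out-of-range values, or a missing required field; ``FileNotFoundError``
    for a missing file.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return params_from_mapping(raw, source=str(path))


def params_from_mapping(raw: dict, source: str = "config") -> ParamSet:
    """Build a validated ParamSet from a plain mapping of field values."""
    unknown = set(raw) - set(PARAM_FIELD_NAMES)
    if unknown:
        raise ParamError(f"{source}: unknown key(s) {sorted(unknown)}")
    if "n" not in raw:
        raise ParamError(f"{source}: 'n' must be set explicitly (it has no default)")
    scenario = raw.get("scenario", ParamSet.scenario)
    if scenario == COMPULSORY and raw.get("omega") is not None:
        logger.info(
            "%s: omega=%s is inert under compulsory participation", source, raw["omega"]
        )
        raw = {**raw, "omega": None}
    elif scenario != COMPULSORY and "omega" not in raw:
        raise ParamError(
            f"{source}: 'omega' must be set explicitly for a voluntary run"
        )
    for key, value in raw.items():
        if key in ("N", "n", "periods", "burn_in", "replicates", "seed"):
            if not isinstance(value, int):
                raise ParamError(f"{source}: {key} must be an integer, got {value!r}")
    return ParamSet(**raw)


def _metadata(params: ParamSet, seed: int | None) -> dict:
    meta = dataclasses.asdict(params)
    meta["root_seed"] = params.seed if seed is None else seed
    meta["software"] = f"pggsim {__version__}"
    return meta


def write_run_result(result: RunResult, out_dir: str | Path, stem: str = "run") -> list[Path]:
    """Write a run's time series as CSV plus metadata JSON; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    meta_path = out_dir / f"{stem}.meta.json"
    result.to_frame().to_csv(csv_path, index=False)
    meta_path.write_text(json.dumps(_metadata(result.params, result.seed), indent=2))
    return [csv_path, meta_path]


def write_table(
    table: pd.DataFrame,
    out_dir: str | Path,
    stem: str,
    params: ParamSet | None = None,
    seed: int | None = None,
) -> list[Path]:
    """Write a summary/difference table as CSV plus metadata JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    table.to_csv(csv_path, index=False)
    paths = [csv_path]
    if params is not None:
        meta_path = out_dir / f"{stem}.meta.json"
        meta_path.write_text(json.dumps(_metadata(params, seed), indent=2))
        paths.append(meta_path)
    return paths


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_table` (lossless round-trip)."""
    return pd.read_csv(path)
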