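"""CSV/JSON/YAML interchange with fixed, validated headers.

CSV is the single tabular format.  Headers are exact: a file whose header
does not match raises :class:`FormatError` naming the expected header, so a
mis-exported file fails loudly rather than silently misaligning columns.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .growth import estimate_volume
from .opchar import ScenarioGrid
from .simulate import SimConfig

VOLUME_HEADER = ["animal_id", "batch_id", "group", "day", "volume_mm3"]
VOLUME_WL_HEADER = ["animal_id", "batch_id", "group", "day",
                    "width_mm", "length_mm"]
RATE_HEADER = ["animal_id", "batch_id", "group", "rate"]
FIT_HEADER = ["animal_id", "batch_id", "group", "intercept_a", "rate_b",
              "n_points", "residual_sd"]


class FormatError(ValueError):
    """A file does not match its required header or schema."""


def _check_header(path: Path, columns: list[str],
                  expected: list[str], alt: list[str] | None = None) -> str:
    if columns == expected:
        return "primary"
    if alt is not None and columns == alt:
        return "alt"
    msg = f"{path}: expected header {','.join(expected)}"
    if alt is not None:
        msg += f" (or {','.join(alt)})"
    msg += f"; found {','.join(columns)}"
    raise FormatError(msg)


def read_volume_csv(path: str | Path) -> pd.DataFrame:
    """Read a long-format volume table; width/length files are converted."""
    path = Path(path)
    df = pd.read_csv(path)
    kind = _check_header(path, list(df.columns), VOLUME_HEADER,
                         VOLUME_WL_HEADER)
    if kind == "alt":
        df["volume_mm3"] = estimate_volume(
            df.pop("width_mm").to_numpy(), df.pop("length_mm").to_numpy()
        )
        df = df[VOLUME_HEADER]
    return df


def read_rate_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _check_header(path, list(df.columns), RATE_HEADER)
    return df


def write_rate_csv(data: pd.DataFrame, path: str | Path) -> None:
    data[RATE_HEADER].to_csv(path, index=False)


def write_fit_csv(fits: pd.DataFrame, path: str | Path) -> None:
    fits[FIT_HEADER].to_csv(path, index=False)


def write_results_json(results: dict[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
        fh.write("\n")


_GRID_KEYS = {"batch_sd_props", "gris", "gri_sd_props", "n_per_batch",
              "n_batches_values", "n_reps", "n_repeats", "alpha"}


def load_sim_config(path: str | Path,
                    seed: int | None = None) -> SimConfig:
    """Load a flat-key YAML simulation config; ``seed`` overrides the file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a mapping of keys")
    if seed is not None:
        raw["seed"] = seed
    return SimConfig.from_dict(raw)


def load_scenario_grid(path: str | Path,
                       seed: int | None = None) -> ScenarioGrid:
    """Load a grid config: SimConfig keys plus swept-axis/replication keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a mapping of keys")
    grid_kwargs: dict[str, Any] = {}
    base_kwargs: dict[str, Any] = {}
    sim_keys = {f.name for f in dataclasses.fields(SimConfig)}
    for key, value in raw.items():
        if key in _GRID_KEYS:
            grid_kwargs[key] = tuple(value) if isinstance(value, list) else value
        elif key in sim_keys:
            base_kwargs[key] = value
        else:
            raise FormatError(f"{path}: unknown config key {key!r}")
    if seed is not None:
        base_kwargs["seed"] = seed
    return ScenarioGrid(base=SimConfig(**base_kwargs), **grid_kwargs)


def dump_config(obj: SimConfig | ScenarioGrid, path: str | Path) -> None:
    if isinstance(obj, SimConfig):
        payload: dict[str, Any] = obj.to_dict()
    else:
        payload = dict(obj.base.to_dict())
        for key in _GRID_KEYS:
            value = getattr(obj, key)
            if value is not None:
                payload[key] = list(value) if isinstance(value, tuple) else value
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
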