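"""Deterministic miniature datasets exercising every code path.

These stand in for study raw data (which is not shipped): small synthetic
volume series, rate tables and grid configs that hit the happy paths and
each documented error path (late measurements beyond the day cap, readings
under the volume floor, animals with too few timepoints, empty
batch-by-group cells, null vs effect grids).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .io import RATE_HEADER, VOLUME_HEADER, dump_config
from .opchar import ScenarioGrid
from .simulate import SimConfig, simulate_experiment

KINDS = ("volumes", "rates", "null-grid", "effect-grid")


def _volumes_fixture(rng: np.random.Generator) -> pd.DataFrame:
    rows = []

    def series(animal, batch, group, a, b, days, noise_sd=0.0):
        for d in days:
            vol = 10 ** (a + b * d + rng.normal(0.0, noise_sd))
            rows.append((animal, batch, group, d, round(vol, 4)))

    # clean exponential growers (slopes recoverable exactly)
    series("A01", "B1", "control", 2.0, 0.10, [0, 3, 6, 9, 12])
    series("A02", "B1", "treated", 2.0, 0.07, [0, 3, 6, 9, 12])
    series("A03", "B2", "control", 2.1, 0.12, [0, 3, 6, 9])
    # noisy grower
    series("A04", "B2", "treated", 2.0, 0.08, [0, 3, 6, 9, 12], noise_sd=0.05)
    # measured beyond the day-30 cap: the day-33 point must be dropped
    series("A05", "B1", "control", 2.0, 0.09, [0, 6, 12, 33])
    # starts below the 50 mm3 floor: a 30 mm3 reading enters as 50 mm3
    rows.append(("A06", "B2", "treated", 0, 30.0))
    series("A06", "B2", "treated", np.log10(60.0), 0.10, [3, 6, 9])
    # too few usable points: only 2 measurements (error path)
    series("A07", "B1", "treated", 2.0, 0.10, [0, 3])
    return pd.DataFrame(rows, columns=VOLUME_HEADER)


def _rates_fixture() -> pd.DataFrame:
    cfg = SimConfig(n_batches=3, n_control_per_batch=4, n_treated_per_batch=4,
                    gri=0.3, seed=20260901)
    return simulate_experiment(cfg)


def make_fixtures(kind: str, out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write the fixture files for ``kind`` into ``out_dir``; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    written: list[Path] = []

    if kind == "volumes":
        path = out_dir / "volumes.csv"
        _volumes_fixture(rng).to_csv(path, index=False)
        written.append(path)
    elif kind == "rates":
        path = out_dir / "rates.csv"
        df = _rates_fixture()
        df.to_csv(path, index=False)
        written.append(path)
        # drop one whole batch-by-group cell: analyze_fixed must refuse it
        broken = df[~((df["batch_id"] == "B2") & (df["group"] == "treated"))]
        path = out_dir / "rates_missing_cell.csv"
        broken[RATE_HEADER].to_csv(path, index=False)
        written.append(path)
    elif kind == "null-grid":
        path = out_dir / "null_grid.yaml"
        grid = ScenarioGrid(
            base=SimConfig(baseline_mean=0.105, baseline_sd=0.026, seed=seed),
            batch_sd_props=(0.05, 0.20, 0.50),
            gris=(0.0,),
            n_reps=200,
            n_repeats=1,
        )
        dump_config(grid, path)
        written.append(path)
    elif kind == "effect-grid":
        path = out_dir / "effect_grid.yaml"
        grid = ScenarioGrid(
            base=SimConfig(baseline_mean=0.105, baseline_sd=0.026, seed=seed),
            batch_sd_props=(0.20,),
            gris=(0.3,),
            gri_sd_props=(0.1,),
            n_reps=200,
            n_repeats=1,
        )
        dump_config(grid, path)
        written.append(path)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {KINDS}")
    return written
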