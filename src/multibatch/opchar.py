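"""Monte-Carlo operating characteristics of the four analysis methods.

The engine sweeps a grid of simulation scenarios (batch-effect scale,
inhibition, effect heterogeneity, group size, number of batches), simulates
``n_reps`` experiments per cell (optionally repeated ``n_repeats`` times with
fresh streams), analyses each with the requested methods and tallies
rejection rates at a significance threshold.  Under a null grid (no
inhibition) the rejection rate is the false positive rate; under an effect
grid its complement is the false negative rate (1 - power).

Every replicate draws its seed from the root seed plus its (cell, repeat,
replicate) coordinates, so results are independent of execution order and
any single replicate can be replayed in isolation.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Any, Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .estimators import _ANALYZERS
from .simulate import SimConfig, simulate_experiment

logger = logging.getLogger(__name__)

ALL_METHODS = ("pooled", "fixed", "random", "meta")

_SEED_MASK = 0x7FFFFFFF  # child seeds stay below 2**31


def child_seed(root_seed: int, *key: int) -> int:
    """Deterministic, collision-resistant child seed for a replicate."""
    ss = np.random.SeedSequence(entropy=root_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0]) & _SEED_MASK


@dataclasses.dataclass(frozen=True)
class ScenarioGrid:
    """A sweep of simulation scenarios around a base configuration.

    Axes left as None stay at the base config's value.  ``n_reps`` replicates
    per cell are run ``n_repeats`` independent times (defaults 2000 x 3), and
    rejection is judged at ``alpha`` (two-sided p below the threshold).
    """

    base: SimConfig = dataclasses.field(default_factory=SimConfig)
    batch_sd_props: tuple[float, ...] | None = None
    gris: tuple[float, ...] | None = None
    gri_sd_props: tuple[float, ...] | None = None
    n_per_batch: tuple[int, ...] | None = None
    n_batches_values: tuple[int, ...] | None = None
    n_reps: int = 2000
    n_repeats: int = 3
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")

    def axis(self, name: str) -> tuple:
        value = getattr(self, _AXES[name])
        if value is not None:
            return tuple(value)
        if name == "n_per_batch":
            return (self.base.n_control_per_batch,)
        if name == "n_batches":
            return (self.base.n_batches,)
        return (getattr(self.base, name),)

    def cells(self) -> list[dict[str, Any]]:
        axes = [self.axis(name) for name in _AXES]
        return [
            dict(zip(_AXES, values))
            for values in itertools.product(*axes)
        ]

    def cell_config(self, cell: dict[str, Any], seed: int) -> SimConfig:
        return dataclasses.replace(
            self.base,
            batch_sd_prop=cell["batch_sd_prop"],
            gri=cell["gri"],
            gri_sd_prop=cell["gri_sd_prop"],
            n_control_per_batch=int(cell["n_per_batch"]),
            n_treated_per_batch=int(cell["n_per_batch"]),
            n_batches=int(cell["n_batches"]),
            seed=seed,
        )


# cell-axis name -> ScenarioGrid field holding the sweep
_AXES = {
    "batch_sd_prop": "batch_sd_props",
    "gri": "gris",
    "gri_sd_prop": "gri_sd_props",
    "n_per_batch": "n_per_batch",
    "n_batches": "n_batches_values",
}

CELL_COLUMNS = list(_AXES)


def _run_grid(
    grid: ScenarioGrid,
    methods: Sequence[str],
    progress: Callable[[int, int], None] | None = None,
) -> pd.DataFrame:
    """Rejection counts per cell x method; shared data across methods."""
    for m in methods:
        if m not in _ANALYZERS:
            raise ValueError(f"unknown method {m!r}")
    cells = grid.cells()
    rows: list[dict[str, Any]] = []
    total = len(cells)
    for ci, cell in enumerate(cells):
        rejections = {m: 0 for m in methods}
        failures = {m: 0 for m in methods}
        for rep_set in range(grid.n_repeats):
            for r in range(grid.n_reps):
                seed = child_seed(grid.base.seed, ci, rep_set, r)
                data = simulate_experiment(grid.cell_config(cell, seed))
                for m in methods:
                    result = _ANALYZERS[m](data)
                    if not result.converged:
                        # non-converged fits count as non-significant
                        failures[m] += 1
                        continue
                    if result.p_value < grid.alpha:
                        rejections[m] += 1
        nobs = grid.n_reps * grid.n_repeats
        for m in methods:
            lo, hi = proportion_confint(
                rejections[m], nobs, alpha=0.05, method="wilson"
            )
            rows.append(
                {
                    **cell,
                    "method": m,
                    "rejection_rate": rejections[m] / nobs,
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "n_reps": nobs,
                    "n_failures": failures[m],
                }
            )
        if progress is not None:
            progress(ci + 1, total)
        logger.info("cell %d/%d done (%s)", ci + 1, total, cell)
    return pd.DataFrame(rows)


def estimate_fpr(
    grid: ScenarioGrid, methods: Sequence[str] = ALL_METHODS
) -> pd.DataFrame:
    """False positive rate per cell x method on a null (gri = 0) grid."""
    if any(g != 0 for g in grid.axis("gri")):
        raise ValueError(
            "false-positive grids must have gri = 0 in every cell; "
            "use estimate_fnr for effect grids"
        )
    out = _run_grid(grid, methods)
    out = out.rename(columns={"rejection_rate": "rate"})
    return out[["method", *CELL_COLUMNS, "rate", "ci_low", "ci_high",
                "n_reps", "n_failures"]]


def estimate_fnr(
    grid: ScenarioGrid, methods: Sequence[str] = ALL_METHODS
) -> pd.DataFrame:
    """False negative rate (1 - power) per cell x method; needs gri > 0."""
    if any(g <= 0 for g in grid.axis("gri")):
        raise ValueError(
            "false-negative grids must have gri > 0 in every cell; "
            "use estimate_fpr for null grids"
        )
    out = _run_grid(grid, methods)
    out["rate"] = 1.0 - out["rejection_rate"]
    out["ci_low"], out["ci_high"] = 1.0 - out["ci_high"], 1.0 - out["ci_low"]
    return out[["method", *CELL_COLUMNS, "rate", "ci_low", "ci_high",
                "n_reps", "n_failures"]]


def design_power_grid(
    grid: ScenarioGrid, method: str = "random"
) -> pd.DataFrame:
    """FNR over the (n_batches, n_per_group) design grid for one method."""
    out = estimate_fnr(grid, methods=[method])
    out = out.rename(columns={"n_per_batch": "n_per_group", "rate": "fnr"})
    return out[["method", "n_batches", "n_per_group", "batch_sd_prop", "gri",
                "gri_sd_prop", "fnr", "ci_low", "ci_high", "n_reps",
                "n_failures"]]


def _t_test_power(n: int, d: float, alpha: float) -> float:
    """Exact power of the two-sided two-sample t-test at n per group."""
    df = 2 * n - 2
    if df < 1:
        return 0.0
    ncp = d * np.sqrt(n / 2.0)
    tcrit = stats.t.isf(alpha / 2.0, df)
    upper = stats.nct.sf(tcrit, df, ncp)
    lower = stats.nct.cdf(-tcrit, df, ncp)
    # deep-tail evaluations can underflow to nan; those terms are negligible
    terms = [0.0 if not np.isfinite(t) else float(t) for t in (upper, lower)]
    return float(min(max(sum(terms), 0.0), 1.0))


def one_batch_sample_size(
    baseline_mean: float,
    baseline_sd: float,
    gri: float,
    power_target: float = 0.8,
    alpha: float = 0.05,
    n_max: int = 1000,
) -> int:
    """Smallest per-group n for a single-batch two-group t-test design.

    The detectable effect is ``gri * baseline_mean`` against animal SD
    ``baseline_sd`` (standardised effect d = gri * mean / sd); power is the
    exact noncentral-t power of the two-sided test at ``alpha``.
    """
    if gri <= 0:
        raise ValueError("gri must be > 0 for a power calculation")
    if baseline_sd <= 0:
        raise ValueError("baseline_sd must be > 0")
    d = gri * baseline_mean / baseline_sd
    for n in range(2, n_max + 1):
        if _t_test_power(n, d, alpha) >= power_target:
            return n
    raise ValueError(
        f"power target {power_target} not reachable within n <= {n_max} "
        "per group"
    )


def animal_budget(n_batches: int, n_per_group: int, n_groups: int = 2) -> int:
    """Total animals in a multi-batch design."""
    for name, v in (("n_batches", n_batches), ("n_per_group", n_per_group),
                    ("n_groups", n_groups)):
        if not isinstance(v, (int, np.integer)) or v < 1:
            raise ValueError(f"{name} must be a positive integer, got {v!r}")
    return int(n_batches * n_per_group * n_groups)


def replicate_budget(one_batch_n_total: int, n_replicates: int = 3) -> int:
    """Total animals when a one-batch experiment is replicated n times."""
    for name, v in (("one_batch_n_total", one_batch_n_total),
                    ("n_replicates", n_replicates)):
        if not isinstance(v, (int, np.integer)) or v < 1:
            raise ValueError(f"{name} must be a positive integer, got {v!r}")
    return int(one_batch_n_total * n_replicates)


def percent_saving(multibatch_total: int, replicated_total: int) -> int:
    """Animal saving of the multi-batch design, to the nearest percent."""
    if replicated_total <= 0:
        raise ValueError("replicated_total must be positive")
    return int(round((replicated_total - multibatch_total)
                     / replicated_total * 100.0))


#: default design-comparison rows: syngeneic model name, multi-batch design
#: (batches, per group per batch), and the replicated one-batch per-experiment
#: total from historical power runs.
DEFAULT_DESIGNS: tuple[dict[str, Any], ...] = (
    {"model": "4T1", "n_batches": 3, "n_per_group": 3, "n_groups": 2,
     "one_batch_total": 6},
    {"model": "CT26WT", "n_batches": 3, "n_per_group": 3, "n_groups": 2,
     "one_batch_total": 14},
    {"model": "MC38", "n_batches": 3, "n_per_group": 6, "n_groups": 2,
     "one_batch_total": 28},
)


def design_table(
    designs: Iterable[dict[str, Any]] = DEFAULT_DESIGNS,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Animal-budget comparison: multi-batch vs replicated one-batch."""
    rows = []
    for d in designs:
        multi = animal_budget(d["n_batches"], d["n_per_group"],
                              d.get("n_groups", 2))
        # one_batch_total is the whole-experiment count (all groups)
        replicated = replicate_budget(d["one_batch_total"], n_replicates)
        rows.append(
            {
                "model": d.get("model", ""),
                "n_batches": d["n_batches"],
                "n_per_group": d["n_per_group"],
                "multibatch_total": multi,
                "one_batch_total_per_exp": d["one_batch_total"],
                "replicated_total": replicated,
                "percent_saving": percent_saving(multi, replicated),
            }
        )
    return pd.DataFrame(rows)
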