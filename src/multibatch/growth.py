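"""Per-animal tumour growth-rate estimation from calliper time series.

Tumour volume is obtained from calliper width/length with the standard
ellipsoid approximation ``volume = width**2 * length / 2`` and each animal's
series is reduced to a single summary measure: the slope of an ordinary
least-squares fit of ``log10(volume)`` on day, i.e. the exponential growth
rate on the log10 scale.  Two conventions protect the fit from artefacts of
small or late tumours: volumes below a floor (default 50 mm3, roughly the
calliper detection limit) are clamped to the floor before the log transform,
and measurements after a day cap (default day 30) are dropped so that
late-study plateau/regression dynamics do not leak into the rate.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_DAY_CAP = 30.0
DEFAULT_VOLUME_FLOOR = 50.0
MIN_POINTS = 3

# residual SDs below this are treated as exact collinearity (pure float noise)
_RESID_TOL = 1e-12


class MeasurementError(ValueError):
    """A calliper measurement violates basic validity (negative size/day)."""


class InsufficientDataError(ValueError):
    """Too few usable timepoints to fit slope + intercept + residual."""


@dataclasses.dataclass(frozen=True)
class VolumeRecord:
    """One calliper-derived volume of one animal on one study day."""

    animal_id: str
    batch_id: str
    group: str
    day: float
    volume: float  # mm3

    def __post_init__(self) -> None:
        if not math.isfinite(self.day) or self.day < 0:
            raise MeasurementError(
                f"day must be finite and >= 0, got {self.day!r} "
                f"(animal {self.animal_id!r})"
            )
        if not math.isfinite(self.volume) or self.volume < 0:
            raise MeasurementError(
                f"volume must be finite and >= 0 mm3, got {self.volume!r} "
                f"(animal {self.animal_id!r}, day {self.day})"
            )


@dataclasses.dataclass(frozen=True)
class GrowthFit:
    """Intercept/slope summary of one animal's log-linear growth curve.

    ``intercept_a`` is log10 volume (mm3) at day 0 and ``rate_b`` is the
    growth rate in log10 mm3 per day.  ``degenerate`` marks fits where every
    volume sat at the floor, so the zero slope carries no growth information.
    """

    animal_id: str
    batch_id: str
    group: str
    intercept_a: float
    rate_b: float
    n_points: int
    residual_sd: float
    degenerate: bool = False


def estimate_volume(width, length):
    """Ellipsoid tumour volume (mm3) from calliper width and length (mm).

    Accepts scalars or arrays; negative inputs are rejected.
    """
    w = np.asarray(width, dtype=float)
    ln = np.asarray(length, dtype=float)
    if np.any(w < 0) or np.any(ln < 0):
        raise MeasurementError("calliper width/length must be >= 0 mm")
    if np.any(~np.isfinite(w)) or np.any(~np.isfinite(ln)):
        raise MeasurementError("calliper width/length must be finite")
    vol = w * w * ln / 2.0
    if np.isscalar(width) and np.isscalar(length):
        return float(vol)
    return vol


def fit_growth_rate(
    records: Sequence[VolumeRecord] | Iterable[VolumeRecord],
    day_cap: float = DEFAULT_DAY_CAP,
    volume_floor: float = DEFAULT_VOLUME_FLOOR,
) -> GrowthFit:
    """OLS fit of log10(volume) on day for a single animal.

    Only measurements up to ``day_cap`` enter the fit; volumes below
    ``volume_floor`` are replaced by the floor before taking log10.  At least
    three eligible timepoints are required (slope + intercept + one residual
    degree of freedom).
    """
    records = list(records)
    if not records:
        raise InsufficientDataError("no volume records supplied")
    ids = {r.animal_id for r in records}
    if len(ids) != 1:
        raise ValueError(f"records span multiple animals: {sorted(ids)}")
    days_all = [r.day for r in records]
    if len(set(days_all)) != len(days_all):
        raise ValueError(
            f"duplicate measurement days for animal {records[0].animal_id!r}"
        )

    kept = [r for r in records if r.day <= day_cap]
    if len(kept) < MIN_POINTS:
        raise InsufficientDataError(
            f"animal {records[0].animal_id!r}: {len(kept)} usable points "
            f"(day <= {day_cap}); need >= {MIN_POINTS}"
        )

    d = np.array([r.day for r in kept], dtype=float)
    v = np.array([r.volume for r in kept], dtype=float)
    y = np.log10(np.maximum(v, volume_floor))
    degenerate = bool(np.all(v <= volume_floor))

    if np.all(y == y[0]):  # e.g. every volume clamped to the floor
        slope, intercept = 0.0, float(y[0])
    else:
        slope, intercept = np.polyfit(d, y, 1)
    resid = y - (intercept + slope * d)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (len(d) - 2)))
    if residual_sd < _RESID_TOL:
        residual_sd = 0.0

    first = kept[0]
    return GrowthFit(
        animal_id=first.animal_id,
        batch_id=first.batch_id,
        group=first.group,
        intercept_a=float(intercept),
        rate_b=float(slope),
        n_points=len(kept),
        residual_sd=residual_sd,
        degenerate=degenerate,
    )


def fit_growth_table(
    volumes: pd.DataFrame,
    day_cap: float = DEFAULT_DAY_CAP,
    volume_floor: float = DEFAULT_VOLUME_FLOOR,
) -> pd.DataFrame:
    """Fit every animal in a long-format volume table.

    ``volumes`` needs columns animal_id, batch_id, group, day, volume_mm3.
    Returns one row per animal with the GrowthFit fields.
    """
    required = ["animal_id", "batch_id", "group", "day", "volume_mm3"]
    missing = [c for c in required if c not in volumes.columns]
    if missing:
        raise ValueError(f"volume table missing columns: {missing}")
    fits = []
    for animal_id, sub in volumes.groupby("animal_id", sort=True):
        recs = [
            VolumeRecord(
                animal_id=str(animal_id),
                batch_id=str(row.batch_id),
                group=str(row.group),
                day=float(row.day),
                volume=float(row.volume_mm3),
            )
            for row in sub.itertuples()
        ]
        fit = fit_growth_rate(recs, day_cap=day_cap, volume_floor=volume_floor)
        fits.append(dataclasses.asdict(fit))
    out = pd.DataFrame(fits)
    return out[
        [
            "animal_id",
            "batch_id",
            "group",
            "intercept_a",
            "rate_b",
            "n_points",
            "residual_sd",
            "degenerate",
        ]
    ]
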