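"""Age-based scaling factors for the phantom's body regions.

Growth from infant to adult is non-uniform: the head is roughly a quarter
of stature at birth but only a seventh by adulthood.  The model captures
this with per-region, per-direction size tables S(d, r, a) at seven
discrete ages A = {0.1, 1, 3, 5, 10, 15, 18} years.  The discrete scaling
factor is the ratio of the size at age a to the size of the 18-year-old
generic phantom,

    F_dis(d, r, a) = S(d, r, a) / S(d, r, 18),

and the continuous factor F_cont(d, r, a) linearly interpolates F_dis
between the bracketing discrete ages.  Growth is assumed to stop at 18:
ages above 18 use the age-18 factors (all exactly 1).  Ages are resolved
to the nearest tenth of a year; the smallest supported age is 0.1 y
(1 month), the youngest tabulated age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phantom_model import BodyRegionId, Direction, GenericPhantom

__all__ = [
    "DISCRETE_AGES",
    "GrowthTable",
    "ScalingFactorSet",
    "discrete_factor",
    "continuous_factor",
    "compute_factors",
    "snap_age",
]

#: The tabulated ages (years); 0.1 y is one month.
DISCRETE_AGES: tuple[float, ...] = (0.1, 1.0, 3.0, 5.0, 10.0, 15.0, 18.0)

GENERIC_AGE = 18.0


def snap_age(age: float) -> float:
    """Resolve an age to the nearest tenth of a year (warning if snapped);
    reject ages below 0.1 y."""
    snapped = round(float(age) * 10.0) / 10.0
    if snapped < 0.1:
        raise ValueError(
            f"age {age} is below the minimum supported age of 0.1 years"
        )
    if abs(snapped - age) > 1e-9:
        warnings.warn(
            f"age {age} snapped to nearest tenth of a year: {snapped}",
            stacklevel=3,
        )
    return snapped


class GrowthTable:
    """Body-region size S(d, r, a) in cm per direction, region and
    discrete age.

    The table must be complete (3 directions x 6 regions x 7 ages = 126
    positive entries) and non-decreasing in age for every (d, r) pair.
    When validated against a phantom, the age-18 column must equal the
    generic phantom's extents so that F_dis(d, r, 18) = 1 exactly.
    """

    def __init__(self, entries: dict[tuple[Direction, BodyRegionId, float], float]):
        self.entries = {
            (Direction(d), BodyRegionId(r), float(a)): float(s)
            for (d, r, a), s in entries.items()
        }
        self._check_complete()

    def _check_complete(self) -> None:
        problems = []
        for d in Direction:
            for r in BodyRegionId:
                for a in DISCRETE_AGES:
                    s = self.entries.get((d, r, a))
                    if s is None:
                        problems.append(f"missing entry ({d.value},{r.value},{a})")
                    elif not (s > 0 and np.isfinite(s)):
                        problems.append(
                            f"non-positive size ({d.value},{r.value},{a}) = {s}"
                        )
        if problems:
            raise ValueError("growth table incomplete:\n  " + "\n  ".join(problems))

    def size(self, d: Direction, r: BodyRegionId, a: float) -> float:
        return self.entries[(Direction(d), BodyRegionId(r), float(a))]

    def sizes_over_age(self, d: Direction, r: BodyRegionId) -> np.ndarray:
        return np.array([self.size(d, r, a) for a in DISCRETE_AGES])

    def validate(self, phantom: GenericPhantom | None = None) -> None:
        """Check monotone growth and, given a phantom, that the age-18
        sizes equal the generic extents."""
        problems = []
        for d in Direction:
            for r in BodyRegionId:
                s = self.sizes_over_age(d, r)
                if np.any(np.diff(s) < 0):
                    problems.append(
                        f"sizes not non-decreasing in age for "
                        f"({d.value},{r.value}): {s.tolist()}"
                    )
        if phantom is not None:
            for d in Direction:
                for r in BodyRegionId:
                    ext = phantom.extent(d, r)
                    s18 = self.size(d, r, 18.0)
                    if abs(s18 - ext) > 1e-9:
                        problems.append(
                            f"S({d.value},{r.value},18)={s18} != generic "
                            f"extent {ext}"
                        )
        if problems:
            raise ValueError("growth table invalid:\n  " + "\n  ".join(problems))

    # -- CSV I/O ------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"direction": d.value, "region": r.value, "age_years": a,
             "size_cm": self.size(d, r, a)}
            for d in Direction for r in BodyRegionId for a in DISCRETE_AGES
        ]
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "GrowthTable":
        df = pd.read_csv(path)
        required = {"direction", "region", "age_years", "size_cm"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"growth table CSV missing columns: {sorted(missing)}")
        entries = {
            (Direction(row.direction), BodyRegionId(row.region),
             float(row.age_years)): float(row.size_cm)
            for row in df.itertuples()
        }
        return cls(entries)


@dataclass
class ScalingFactorSet:
    """Continuous scaling factors for one query age.

    ``factors`` maps (direction, region) to the dimensionless F_cont;
    ``interval`` records the bracketing discrete ages used.
    """

    age: float
    factors: dict[tuple[Direction, BodyRegionId], float]
    interval: tuple[float, float]

    def __getitem__(self, key: tuple[Direction, BodyRegionId]) -> float:
        d, r = key
        return self.factors[(Direction(d), BodyRegionId(r))]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"direction": d.value, "region": r.value, "f_cont": f}
            for (d, r), f in self.factors.items()
        ]
        return pd.DataFrame(rows)


def discrete_factor(table: GrowthTable, d: Direction, r: BodyRegionId,
                    a: float) -> float:
    """F_dis(d, r, a) = S(d, r, a) / S(d, r, 18) for a tabulated age."""
    a = float(a)
    if a not in DISCRETE_AGES:
        raise ValueError(
            f"age {a} is not a tabulated discrete age {DISCRETE_AGES}; "
            "use continuous_factor for intermediate ages"
        )
    return table.size(d, r, a) / table.size(d, r, GENERIC_AGE)


def continuous_factor(table: GrowthTable, d: Direction, r: BodyRegionId,
                      a: float) -> float:
    """F_cont(d, r, a): piecewise-linear interpolation of the discrete
    factors over the age intervals [0.1,1), [1,3), [3,5), [5,10),
    [10,15), [15,18).

    Ages at a knot return the discrete factor exactly; ages above 18
    clamp to the age-18 value (growth stops at 18, factor 1).
    """
    a = snap_age(a)
    if a >= GENERIC_AGE:
        return discrete_factor(table, d, r, GENERIC_AGE)
    ages = np.asarray(DISCRETE_AGES)
    i = int(np.searchsorted(ages, a, side="right")) - 1
    a_lo, a_hi = DISCRETE_AGES[i], DISCRETE_AGES[i + 1]
    if a == a_lo:
        return discrete_factor(table, d, r, a_lo)
    f_lo = discrete_factor(table, d, r, a_lo)
    f_hi = discrete_factor(table, d, r, a_hi)
    return f_lo + (a - a_lo) / (a_hi - a_lo) * (f_hi - f_lo)


def compute_factors(table: GrowthTable, age: float) -> ScalingFactorSet:
    """Evaluate F_cont for every (direction, region) at one age."""
    a = snap_age(age)
    clamped = min(a, GENERIC_AGE)
    ages = np.asarray(DISCRETE_AGES)
    if clamped >= GENERIC_AGE:
        interval = (GENERIC_AGE, GENERIC_AGE)
    else:
        i = int(np.searchsorted(ages, clamped, side="right")) - 1
        interval = (DISCRETE_AGES[i], DISCRETE_AGES[i + 1])
    factors = {
        (d, r): continuous_factor(table, d, r, a)
        for d in Direction for r in BodyRegionId
    }
    return ScalingFactorSet(age=a, factors=factors, interval=interval)
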