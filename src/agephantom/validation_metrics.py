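"""Geometric validation metrics for scaled phantoms.

Covers the comparisons used to validate a phantom pipeline end to end:

* percent difference between a reference value F (ground truth) and a
  candidate value D, in either sign convention,
* the normalized mean square distance (NMSD) between corresponding
  organ points of two phantom representations, reported in mm as the
  root-mean-square point distance,
* stature comparison against 50th-percentile population height tables
  (WHO for infants, CDC averages of male/female for older children),
* organ mass as the product of an ICRU-46-style reference density and
  the voxelized volume of the organ's convex hull, with sex-averaging
  and part-summing of reference masses before differencing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .phantom_model import OrganGrid

__all__ = [
    "ComparisonRecord",
    "MassReport",
    "percent_difference",
    "nmsd",
    "compare_heights",
    "hull_volume",
    "voxelized_hull_volume",
    "organ_mass",
    "reference_mass_table",
    "compare_masses",
]


@dataclass
class ComparisonRecord:
    """One reference-vs-candidate comparison.

    ``convention`` is ``"eq7"`` for (F - D) / F or ``"signed-candidate"``
    for (D - F) / F; the two differ only in sign.
    """

    label: str
    reference: float
    candidate: float
    percent_difference: float
    convention: str = "eq7"


def percent_difference(F: float, D: float, convention: str = "eq7") -> float:
    """Percent difference between a reference F and a candidate D.

    ``"eq7"`` returns (F - D) / F * 100; ``"signed-candidate"`` returns
    (D - F) / F * 100 (the sign convention used when quoting the
    candidate's deviation from the reference).
    """
    if F == 0:
        raise ZeroDivisionError(
            "percent difference undefined for reference value 0"
        )
    if convention == "eq7":
        return (F - D) / F * 100.0
    if convention == "signed-candidate":
        return (D - F) / F * 100.0
    raise ValueError(f"unknown convention {convention!r}")


def nmsd(organ_F: OrganGrid | np.ndarray,
         organ_D: OrganGrid | np.ndarray) -> float:
    """Normalized mean square distance between two ordered point sets,
    reported as the root-mean-square inter-point distance (mm).

    Points are paired by index: both point sets must derive from the
    same organ grid so that ordering is shared.  The mean squared
    distance has units mm^2; the square root is taken so the result is
    a length in mm (0 iff the sets are identical).
    """
    a = organ_F.points if isinstance(organ_F, OrganGrid) else np.asarray(organ_F, float)
    b = organ_D.points if isinstance(organ_D, OrganGrid) else np.asarray(organ_D, float)
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    if a.shape != b.shape:
        raise ValueError(f"point count mismatch: {a.shape} vs {b.shape}")
    if a.shape[0] == 0:
        raise ValueError("NMSD undefined for empty point sets")
    sq = np.sum((a - b) ** 2, axis=1)
    return float(np.sqrt(sq.mean()))


def compare_heights(phantom_heights: Mapping[float, float],
                    reference: Mapping[float, float] | pd.DataFrame,
                    ) -> list[ComparisonRecord]:
    """Absolute percent difference of phantom stature vs a reference
    height table, per age (reference as F).

    ``reference`` maps age (years) to height (cm), or is a DataFrame
    with ``age`` and ``height_cm`` columns.
    """
    if isinstance(reference, pd.DataFrame):
        reference = dict(zip(reference["age"].astype(float),
                             reference["height_cm"].astype(float)))
    missing = [a for a in phantom_heights if float(a) not in reference]
    if missing:
        raise KeyError(
            f"reference height table missing age(s): {sorted(missing)}"
        )
    records = []
    for age, h in phantom_heights.items():
        ref = reference[float(age)]
        pd_val = abs(percent_difference(ref, h, "eq7"))
        records.append(
            ComparisonRecord(label=f"height@{age}y", reference=ref,
                             candidate=h, percent_difference=pd_val)
        )
    return records


# ---------------------------------------------------------------------
# Organ mass via voxelized convex-hull volume
# ---------------------------------------------------------------------

def hull_volume(points_mm: np.ndarray) -> float:
    """Analytic convex-hull volume in mm^3."""
    return float(ConvexHull(np.asarray(points_mm, float)).volume)


def voxelized_hull_volume(points_mm: np.ndarray, voxel_mm: float) -> float:
    """Convex-hull volume estimated by counting voxel centres inside
    the hull (mm^3).

    The voxel grid is anchored at the hull bounding box minimum with
    centres at min + (i + 1/2) * voxel.  For convex bodies the estimate
    converges to the analytic volume as the voxel shrinks.
    """
    if voxel_mm <= 0:
        raise ValueError("voxel size must be positive")
    pts = np.asarray(points_mm, float)
    hull = ConvexHull(pts)
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    n = np.maximum(np.ceil((hi - lo) / voxel_mm).astype(int), 1)
    axes = [lo[k] + (np.arange(n[k]) + 0.5) * voxel_mm for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    # hull.equations: A @ p + b <= 0 inside
    A = hull.equations[:, :3]
    b = hull.equations[:, 3]
    inside = np.all(centers @ A.T + b <= 1e-9, axis=1)
    return float(inside.sum()) * voxel_mm ** 3


def organ_mass(organ: OrganGrid | np.ndarray, density_g_cm3: float,
               voxel_mm: float = 1.0) -> float:
    """Organ mass in grams: reference tissue density times the voxelized
    convex-hull volume of the organ's point grid (points in mm).

    Raises for non-contourable organs (no 3-D hull, so mass undefined)
    and for non-positive densities.
    """
    if density_g_cm3 <= 0:
        raise ValueError("density must be positive")
    if isinstance(organ, OrganGrid):
        if not organ.contourable:
            raise ValueError(
                f"organ {organ.name!r} with {organ.n_points} point(s) has "
                "no contoured volume; mass undefined"
            )
        pts = organ.points
    else:
        pts = np.asarray(organ, float)
    vol_cm3 = voxelized_hull_volume(pts, voxel_mm) / 1000.0
    return density_g_cm3 * vol_cm3


@dataclass
class MassReport:
    """Phantom organ mass vs a reference phantom's mass at one age."""

    organ: str
    phantom_mass_g: float
    reference_mass_g: float | None
    difference_g: float | None  # phantom - reference
    source: str = ""


def reference_mass_table(reference: pd.DataFrame, age: float) -> dict[str, float]:
    """Collapse a per-sex, per-part reference mass table to one mass per
    organ at one age: parts are summed within each sex, then the sexes
    are averaged.

    ``reference`` columns: organ, age, sex, part, mass_g.  Rows whose
    sex or part does not apply may hold any placeholder (e.g. "both" /
    "whole").
    """
    df = reference[np.isclose(reference["age"].astype(float), age)]
    out: dict[str, float] = {}
    for organ, grp in df.groupby("organ"):
        per_sex = grp.groupby("sex")["mass_g"].sum()
        out[str(organ)] = float(per_sex.mean())
    return out


def compare_masses(phantom_masses: Mapping[str, float],
                   reference: pd.DataFrame, age: float,
                   source: str = "reference") -> list[MassReport]:
    """Difference phantom organ masses against a reference table.

    Reference masses are sex-averaged and part-summed first; the
    difference is phantom minus reference.  Organs missing from the
    reference are reported with a null reference rather than failing.
    """
    ref = reference_mass_table(reference, age)
    reports = []
    for organ, m in phantom_masses.items():
        r = ref.get(organ)
        reports.append(
            MassReport(
                organ=organ,
                phantom_mass_g=float(m),
                reference_mass_g=r,
                difference_g=(float(m) - r) if r is not None else None,
                source=source,
            )
        )
    return reports
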