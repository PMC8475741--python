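"""Domain model for the generic age-18 reference phantom.

The phantom is a stylized, gender-neutral adult body built from
axis-aligned cuboids, one per body region (upper head, lower head, neck,
trunk, legs, plus two mirrored arm cuboids flanking the trunk), with
organs represented as grids of points inside those regions.  The phantom
frame uses centimetres with +x running toward the patient's left, +y
running superior to inferior (the head sits at small y, starting at
y = 1 cm), and +z running anterior to posterior.  The body is symmetric
about the x = 0 plane.

A JSON reader/writer (schema ``agephantom-phantom/1``) persists phantom
definitions, and :func:`generate_fixture_phantom` builds a deterministic
synthetic phantom plus a matching growth table so that every downstream
computation can be exercised without proprietary anatomical data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "Direction",
    "BodyRegionId",
    "CHAIN_ORDER",
    "Point3",
    "BodyRegion",
    "OrganGrid",
    "GenericPhantom",
    "PhantomValidationError",
    "read_phantom_definition",
    "write_phantom_definition",
    "generate_fixture_phantom",
    "GENERIC_AGE",
    "Y_ORIGIN_CM",
]

GENERIC_AGE = 18.0
Y_ORIGIN_CM = 1.0

SCHEMA_ID = "agephantom-phantom/1"


class Direction(str, Enum):
    """Anatomical scaling direction: left-right (x), superior-inferior (y),
    anterior-posterior (z)."""

    X = "x"
    Y = "y"
    Z = "z"

    @property
    def axis(self) -> int:
        return {"x": 0, "y": 1, "z": 2}[self.value]


class BodyRegionId(str, Enum):
    """The six scalable body regions."""

    UH = "uh"  # upper head
    LH = "lh"  # lower head
    N = "n"    # neck
    TR = "tr"  # trunk
    AR = "ar"  # arms
    LG = "lg"  # legs


#: Superior-to-inferior ordering of the contiguous region chain.  Arms sit
#: outside the chain: they flank the trunk and share its y-span.
CHAIN_ORDER: tuple[BodyRegionId, ...] = (
    BodyRegionId.UH,
    BodyRegionId.LH,
    BodyRegionId.N,
    BodyRegionId.TR,
    BodyRegionId.LG,
)


@dataclass(frozen=True)
class Point3:
    """A point in the phantom frame (cm)."""

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


class PhantomValidationError(ValueError):
    """Raised when a phantom definition violates a structural invariant.

    ``violations`` lists every problem found, not just the first.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "phantom definition invalid:\n  - " + "\n  - ".join(self.violations)
        )


@dataclass
class BodyRegion:
    """An axis-aligned cuboid bounding one body region.

    ``corners`` is an (8, 3) array; each coordinate axis must take exactly
    two distinct values across the eight corners.  Derived boundaries:
    ``y_sbr``/``y_ibr`` are the superior/inferior y-bounds (y grows
    superior to inferior, so y_sbr < y_ibr), ``z_abr`` the anterior
    z-bound, and ``l_x``/``l_y``/``l_z`` the edge lengths.
    """

    id: BodyRegionId
    corners: np.ndarray

    def __post_init__(self) -> None:
        self.corners = np.asarray(self.corners, dtype=float)
        if self.corners.shape != (8, 3):
            raise PhantomValidationError(
                [f"region {self.id.value}: expected 8 corner points, "
                 f"got shape {self.corners.shape}"]
            )

    def is_cuboid(self) -> bool:
        return all(len(np.unique(self.corners[:, ax])) == 2 for ax in range(3))

    # -- derived boundaries (cm) -------------------------------------
    @property
    def y_sbr(self) -> float:
        return float(self.corners[:, 1].min())

    @property
    def y_ibr(self) -> float:
        return float(self.corners[:, 1].max())

    @property
    def z_abr(self) -> float:
        return float(self.corners[:, 2].min())

    @property
    def l_x(self) -> float:
        return float(self.corners[:, 0].max() - self.corners[:, 0].min())

    @property
    def l_y(self) -> float:
        return float(self.y_ibr - self.y_sbr)

    @property
    def l_z(self) -> float:
        return float(self.corners[:, 2].max() - self.z_abr)

    def extent(self, d: Direction) -> float:
        return {Direction.X: self.l_x, Direction.Y: self.l_y,
                Direction.Z: self.l_z}[d]

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Boolean mask: which points lie inside/on the cuboid."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        lo = self.corners.min(axis=0) - tol
        hi = self.corners.max(axis=0) + tol
        return np.all((pts >= lo) & (pts <= hi), axis=1)

    @staticmethod
    def from_bounds(id: BodyRegionId, lo: Iterable[float],
                    hi: Iterable[float]) -> "BodyRegion":
        lo = np.asarray(list(lo), dtype=float)
        hi = np.asarray(list(hi), dtype=float)
        corners = np.array(
            [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1])
             for z in (lo[2], hi[2])]
        )
        return BodyRegion(id=id, corners=corners)


@dataclass
class OrganGrid:
    """An organ represented as a grid of points inside one body region.

    The region assignment is explicit (stored in the file) rather than
    inferred by containment, because a grid straddling a region boundary
    would be ambiguous.  Organs with fewer than four non-coplanar points
    cannot be turned into a closed contour stack and are flagged
    non-contourable.
    """

    name: str
    region: BodyRegionId
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise PhantomValidationError(
                [f"organ {self.name}: points must be an (N, 3) array"]
            )

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    @property
    def contourable(self) -> bool:
        """True when the point set spans three dimensions (N >= 4,
        non-coplanar), i.e. a 3-D convex hull exists."""
        if self.n_points < 4:
            return False
        centered = self.points - self.points.mean(axis=0)
        return int(np.linalg.matrix_rank(centered, tol=1e-9)) == 3


@dataclass
class GenericPhantom:
    """The age-18 reference geometry.

    ``regions`` holds the contiguous superior-to-inferior chain
    (uh, lh, n, tr, lg); ``arms`` holds the two mirrored arm cuboids,
    which share the trunk's y-span but do not participate in the
    y-contiguity chain.
    """

    regions: dict[BodyRegionId, BodyRegion]
    arms: list[BodyRegion]
    organs: list[OrganGrid]
    generic_age: float = GENERIC_AGE
    y_origin: float = Y_ORIGIN_CM

    def region_for(self, rid: BodyRegionId) -> BodyRegion:
        if rid is BodyRegionId.AR:
            return self.arms[0]
        return self.regions[rid]

    def all_regions(self) -> list[BodyRegion]:
        return [self.regions[r] for r in CHAIN_ORDER] + list(self.arms)

    def total_height(self) -> float:
        """Stature in cm: sum of chain-region y extents."""
        return float(sum(self.regions[r].l_y for r in CHAIN_ORDER))

    def extent(self, d: Direction, r: BodyRegionId) -> float:
        return self.region_for(r).extent(d)

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        """Check every structural invariant; raise PhantomValidationError
        listing all violations."""
        v: list[str] = []
        missing = [r.value for r in CHAIN_ORDER if r not in self.regions]
        if missing:
            raise PhantomValidationError(
                [f"missing chain region(s): {', '.join(missing)}"]
            )
        for reg in self.all_regions():
            if not reg.is_cuboid():
                v.append(
                    f"region {reg.id.value}: corners do not form an "
                    "axis-aligned cuboid"
                )
            if reg.l_x <= 0 or reg.l_y <= 0 or reg.l_z <= 0:
                v.append(f"region {reg.id.value}: degenerate (zero) extent")
        # contiguity of the y chain
        for a, b in zip(CHAIN_ORDER[:-1], CHAIN_ORDER[1:]):
            ra, rb = self.regions[a], self.regions[b]
            if ra.y_ibr != rb.y_sbr:
                v.append(
                    f"regions not contiguous: {a.value}.y_ibr="
                    f"{ra.y_ibr!r} != {b.value}.y_sbr={rb.y_sbr!r}"
                )
        # head starts at y = y_origin
        uh = self.regions[BodyRegionId.UH]
        if uh.y_sbr != self.y_origin:
            v.append(
                f"superior boundary of uh must be y={self.y_origin}, "
                f"got {uh.y_sbr!r}"
            )
        # x-symmetry of the full corner set
        corners = np.vstack([r.corners for r in self.all_regions()])
        mirrored = corners * np.array([-1.0, 1.0, 1.0])
        cs = {tuple(c) for c in np.round(corners, 9)}
        ms = {tuple(c) for c in np.round(mirrored, 9)}
        if cs != ms:
            v.append("corner set is not symmetric about the x=0 plane")
        if len(self.arms) != 2:
            v.append(f"expected 2 arm cuboids, got {len(self.arms)}")
        # organs inside their regions
        for org in self.organs:
            try:
                reg = self.region_for(org.region)
            except KeyError:
                v.append(f"organ {org.name}: unknown region {org.region}")
                continue
            inside = reg.contains(org.points)
            if not inside.all():
                n_out = int((~inside).sum())
                v.append(
                    f"organ {org.name}: {n_out} point(s) outside region "
                    f"{org.region.value}"
                )
        if v:
            raise PhantomValidationError(v)


# ---------------------------------------------------------------------
# JSON serialization (schema agephantom-phantom/1)
# ---------------------------------------------------------------------

def _fmt(x: float) -> float:
    # round-trip exactly: json floats are written with repr, which is the
    # shortest string recovering the identical double
    return float(x)


def _phantom_to_dict(ph: GenericPhantom) -> dict:
    def region_obj(reg: BodyRegion) -> dict:
        return {
            "id": reg.id.value,
            "corners": [[_fmt(c) for c in row] for row in reg.corners],
        }

    return {
        "schema": SCHEMA_ID,
        "generic_age": ph.generic_age,
        "y_origin": ph.y_origin,
        "regions": [region_obj(ph.regions[r]) for r in CHAIN_ORDER],
        "arms": [region_obj(a) for a in ph.arms],
        "organs": [
            {
                "name": o.name,
                "region": o.region.value,
                "points": [[_fmt(c) for c in row] for row in o.points],
            }
            for o in ph.organs
        ],
    }


def write_phantom_definition(phantom: GenericPhantom, path: str | Path) -> None:
    """Write a phantom definition as JSON (lengths in cm).

    The file round-trips losslessly: reading it back yields bit-identical
    coordinates, and write-read-write is byte-idempotent.
    """
    phantom.validate()
    text = json.dumps(_phantom_to_dict(phantom), indent=1)
    Path(path).write_text(text + "\n")


def read_phantom_definition(path: str | Path) -> GenericPhantom:
    """Read and validate a phantom definition JSON file."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise PhantomValidationError([f"malformed JSON: {e}"]) from e
    if not isinstance(doc, dict) or doc.get("schema") != SCHEMA_ID:
        raise PhantomValidationError(
            [f"field 'schema': expected {SCHEMA_ID!r}, got "
             f"{doc.get('schema') if isinstance(doc, dict) else type(doc)!r}"]
        )
    errors: list[str] = []

    def parse_region(obj: dict, where: str) -> BodyRegion | None:
        try:
            rid = BodyRegionId(obj["id"])
            corners = np.asarray(obj["corners"], dtype=float)
            return BodyRegion(id=rid, corners=corners)
        except (KeyError, ValueError, TypeError, PhantomValidationError) as e:
            msg = e.violations[0] if isinstance(e, PhantomValidationError) else e
            errors.append(f"{where}: {msg}")
            return None

    regions: dict[BodyRegionId, BodyRegion] = {}
    for i, obj in enumerate(doc.get("regions", [])):
        reg = parse_region(obj, f"regions[{i}]")
        if reg is not None:
            regions[reg.id] = reg
    arms = [
        a for i, obj in enumerate(doc.get("arms", []))
        if (a := parse_region(obj, f"arms[{i}]")) is not None
    ]
    organs: list[OrganGrid] = []
    for i, obj in enumerate(doc.get("organs", [])):
        try:
            organs.append(
                OrganGrid(
                    name=str(obj["name"]),
                    region=BodyRegionId(obj["region"]),
                    points=np.asarray(obj["points"], dtype=float),
                )
            )
        except (KeyError, ValueError, TypeError, PhantomValidationError) as e:
            errors.append(f"organs[{i}]: {e}")
    if errors:
        raise PhantomValidationError(errors)
    ph = GenericPhantom(
        regions=regions,
        arms=arms,
        organs=organs,
        generic_age=float(doc.get("generic_age", GENERIC_AGE)),
        y_origin=float(doc.get("y_origin", Y_ORIGIN_CM)),
    )
    ph.validate()
    return ph


# ---------------------------------------------------------------------
# Deterministic synthetic fixture
# ---------------------------------------------------------------------

# Adult (age-18) region extents in cm.  The head (uh+lh) is exactly 1/7 of
# the 176 cm stature; widths/depths are typical adult values.
_HEAD_Y = 176.0 / 7.0          # 25.142857... cm
_UH_Y = 13.0
_LH_Y = _HEAD_Y - _UH_Y
_N_Y = 8.0
_TR_Y = 62.0
_LG_Y = 176.0 - _HEAD_Y - _N_Y - _TR_Y

_ADULT_XZ = {
    # region: (l_x, l_z) cm
    BodyRegionId.UH: (15.6, 20.0),
    BodyRegionId.LH: (15.6, 20.0),
    BodyRegionId.N: (11.4, 11.4),
    BodyRegionId.TR: (34.0, 22.0),
    BodyRegionId.AR: (9.0, 11.0),   # one arm cuboid
    BodyRegionId.LG: (32.0, 22.0),
}

# Growth-table knots.  Stature targets track WHO/CDC-like 50th-percentile
# heights; the head fraction is 1/4 of stature at 0.1 y, falling to 1/7 at
# 18 y.  All columns are monotone non-decreasing in age.
_KNOT_AGES = (0.1, 1.0, 3.0, 5.0, 10.0, 15.0, 18.0)
_STATURE = (55.0, 75.0, 95.0, 109.0, 138.0, 167.0, 176.0)
_HEAD_Y_BY_AGE = (13.75, 16.5, 18.5, 20.0, 22.5, 24.5, _HEAD_Y)
_N_Y_BY_AGE = (2.5, 3.4, 4.4, 5.0, 6.3, 7.5, _N_Y)
_TR_Y_BY_AGE = (20.0, 27.0, 33.0, 37.0, 46.5, 56.0, _TR_Y)
_LG_Y_BY_AGE = tuple(
    s - h - n - t
    for s, h, n, t in zip(_STATURE, _HEAD_Y_BY_AGE, _N_Y_BY_AGE, _TR_Y_BY_AGE)
)

# Fractional width/depth growth curves (relative to the adult size) per
# region; heads approach adult size early, trunks and limbs late.
_WIDTH_CURVES = {
    BodyRegionId.UH: {
        Direction.X: (0.62, 0.74, 0.82, 0.86, 0.92, 0.97, 1.0),
        Direction.Z: (0.60, 0.73, 0.81, 0.85, 0.91, 0.97, 1.0),
    },
    BodyRegionId.N: {
        Direction.X: (0.45, 0.55, 0.63, 0.68, 0.80, 0.93, 1.0),
        Direction.Z: (0.46, 0.56, 0.64, 0.69, 0.80, 0.93, 1.0),
    },
    BodyRegionId.TR: {
        Direction.X: (0.32, 0.42, 0.50, 0.56, 0.70, 0.90, 1.0),
        Direction.Z: (0.35, 0.44, 0.52, 0.58, 0.71, 0.90, 1.0),
    },
    BodyRegionId.AR: {
        Direction.X: (0.30, 0.40, 0.48, 0.54, 0.68, 0.89, 1.0),
        Direction.Z: (0.31, 0.41, 0.49, 0.55, 0.68, 0.89, 1.0),
    },
    BodyRegionId.LG: {
        Direction.X: (0.30, 0.40, 0.48, 0.54, 0.68, 0.89, 1.0),
        Direction.Z: (0.32, 0.41, 0.49, 0.55, 0.69, 0.89, 1.0),
    },
}
_WIDTH_CURVES[BodyRegionId.LH] = _WIDTH_CURVES[BodyRegionId.UH]


def _fixture_regions() -> tuple[dict[BodyRegionId, BodyRegion], list[BodyRegion]]:
    regions: dict[BodyRegionId, BodyRegion] = {}
    y = Y_ORIGIN_CM
    for rid, ly in zip(
        CHAIN_ORDER, (_UH_Y, _LH_Y, _N_Y, _TR_Y, _LG_Y)
    ):
        lx, lz = _ADULT_XZ[rid]
        regions[rid] = BodyRegion.from_bounds(
            rid, lo=(-lx / 2.0, y, 0.0), hi=(lx / 2.0, y + ly, lz)
        )
        y = y + ly
    tr = regions[BodyRegionId.TR]
    ax, az = _ADULT_XZ[BodyRegionId.AR]
    z_mid = (tr.z_abr + tr.z_abr + tr.l_z) / 2.0
    # arms flank the trunk, sharing its y-span
    arm_r = BodyRegion.from_bounds(
        BodyRegionId.AR,
        lo=(-tr.l_x / 2.0 - ax, tr.y_sbr, z_mid - az / 2.0),
        hi=(-tr.l_x / 2.0, tr.y_ibr, z_mid + az / 2.0),
    )
    arm_l = BodyRegion.from_bounds(
        BodyRegionId.AR,
        lo=(tr.l_x / 2.0, tr.y_sbr, z_mid - az / 2.0),
        hi=(tr.l_x / 2.0 + ax, tr.y_ibr, z_mid + az / 2.0),
    )
    return regions, [arm_l, arm_r]


def _grid_in_box(lo: np.ndarray, hi: np.ndarray, shape: tuple[int, int, int],
                 n_keep: int | None = None) -> np.ndarray:
    """Evenly spaced point grid filling the box, optionally thinned to
    exactly n_keep points (deterministic stride-style thinning)."""
    axes = [
        np.linspace(lo[k], hi[k], shape[k]) if shape[k] > 1
        else np.array([(lo[k] + hi[k]) / 2.0])
        for k in range(3)
    ]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    if n_keep is not None and n_keep < len(pts):
        idx = np.round(np.linspace(0, len(pts) - 1, n_keep)).astype(int)
        pts = pts[idx]
    return pts


# organ name -> (region, fractional box inside region, grid shape, n_keep)
# boxes as (lo_frac, hi_frac) of the region extents
_ORGAN_SPECS: list[tuple[str, BodyRegionId, tuple, tuple, tuple[int, int, int], int | None]] = [
    # -- brain group (upper head) --
    ("Frontal_Lobe_R", BodyRegionId.UH, (0.15, 0.15, 0.10), (0.45, 0.55, 0.40), (3, 3, 3), None),
    ("Frontal_Lobe_L", BodyRegionId.UH, (0.55, 0.15, 0.10), (0.85, 0.55, 0.40), (3, 3, 3), None),
    ("Temporal_Lobe_R", BodyRegionId.UH, (0.10, 0.45, 0.30), (0.35, 0.80, 0.60), (3, 3, 3), None),
    ("Temporal_Lobe_L", BodyRegionId.UH, (0.65, 0.45, 0.30), (0.90, 0.80, 0.60), (3, 3, 3), None),
    ("Parietal_Lobe_R", BodyRegionId.UH, (0.20, 0.10, 0.40), (0.48, 0.45, 0.70), (3, 3, 3), None),
    ("Parietal_Lobe_L", BodyRegionId.UH, (0.52, 0.10, 0.40), (0.80, 0.45, 0.70), (3, 3, 3), None),
    ("Cerebellum", BodyRegionId.UH, (0.30, 0.60, 0.60), (0.70, 0.90, 0.90), (3, 3, 3), None),
    ("Occipital_Lobes", BodyRegionId.UH, (0.25, 0.20, 0.65), (0.75, 0.55, 0.92), (4, 3, 3), None),
    ("Inner_Brain", BodyRegionId.UH, (0.35, 0.30, 0.30), (0.65, 0.65, 0.60), (3, 3, 3), None),
    # -- pituitary: single-point organ (non-contourable by design) --
    ("Pituitary", BodyRegionId.LH, (0.50, 0.10, 0.40), (0.50, 0.10, 0.40), (1, 1, 1), None),
    # -- thyroid (neck) --
    ("Thyroid_Lobe_R", BodyRegionId.N, (0.20, 0.35, 0.15), (0.42, 0.75, 0.40), (2, 3, 2), None),
    ("Thyroid_Lobe_L", BodyRegionId.N, (0.58, 0.35, 0.15), (0.80, 0.75, 0.40), (2, 3, 2), None),
    # -- trunk organs --
    ("Heart", BodyRegionId.TR, (0.40, 0.18, 0.25), (0.68, 0.38, 0.60), (4, 4, 4), 55),
    ("Liver", BodyRegionId.TR, (0.10, 0.30, 0.20), (0.48, 0.52, 0.70), (5, 4, 5), None),
    ("Lung_R", BodyRegionId.TR, (0.12, 0.08, 0.20), (0.40, 0.40, 0.75), (4, 5, 4), None),
    ("Lung_L", BodyRegionId.TR, (0.60, 0.08, 0.20), (0.88, 0.40, 0.75), (4, 5, 4), None),
    ("Stomach", BodyRegionId.TR, (0.55, 0.38, 0.25), (0.80, 0.55, 0.60), (4, 3, 4), None),
    ("Pancreas", BodyRegionId.TR, (0.38, 0.44, 0.35), (0.66, 0.52, 0.60), (4, 2, 3), None),
    ("Kidney_R", BodyRegionId.TR, (0.22, 0.48, 0.55), (0.40, 0.64, 0.80), (3, 3, 2), 15),
    ("Kidney_L", BodyRegionId.TR, (0.60, 0.48, 0.55), (0.78, 0.64, 0.80), (3, 3, 2), 15),
]


def generate_fixture_phantom(seed: int):
    """Build the deterministic synthetic phantom and its growth table.

    The phantom is a 176 cm adult whose head is exactly one seventh of
    the stature; the growth table shrinks it so the head is one quarter
    of stature at age 0.1 y.  All nine organ groups are present, with
    the kidneys carrying exactly 15 points each and the pituitary a
    single point, to exercise the low-resolution (non-contourable)
    export path.  Organ grid placement is jittered by ``seed``; region
    geometry and the growth table are seed-independent.

    Returns ``(GenericPhantom, GrowthTable)``.
    """
    from .growth_scaling import GrowthTable  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    regions, arms = _fixture_regions()

    organs: list[OrganGrid] = []
    for name, rid, lof, hif, shape, n_keep in _ORGAN_SPECS:
        reg = regions[rid]
        lo_reg = reg.corners.min(axis=0)
        ext = reg.corners.max(axis=0) - lo_reg
        lo = lo_reg + np.asarray(lof) * ext
        hi = lo_reg + np.asarray(hif) * ext
        # seeded jitter of the grid placement, kept inside the region
        jitter = rng.uniform(-0.02, 0.02, size=3) * ext
        span = hi - lo
        lo = np.clip(lo + jitter, lo_reg, lo_reg + ext - span)
        hi = lo + span
        organs.append(
            OrganGrid(name=name, region=rid,
                      points=_grid_in_box(lo, hi, shape, n_keep))
        )

    phantom = GenericPhantom(regions=regions, arms=arms, organs=organs)
    phantom.validate()

    # growth table: y sizes from the stature decomposition, x/z sizes from
    # the width curves applied to the adult extents
    head_split_uh = _UH_Y / _HEAD_Y
    entries: dict[tuple[Direction, BodyRegionId, float], float] = {}
    for i, a in enumerate(_KNOT_AGES):
        y_sizes = {
            BodyRegionId.UH: _HEAD_Y_BY_AGE[i] * head_split_uh,
            BodyRegionId.LH: _HEAD_Y_BY_AGE[i] * (1.0 - head_split_uh),
            BodyRegionId.N: _N_Y_BY_AGE[i],
            BodyRegionId.TR: _TR_Y_BY_AGE[i],
            BodyRegionId.AR: _TR_Y_BY_AGE[i],  # arms track the trunk y-span
            BodyRegionId.LG: _LG_Y_BY_AGE[i],
        }
        for rid in BodyRegionId:
            reg = phantom.region_for(rid)
            entries[(Direction.Y, rid, a)] = y_sizes[rid]
            for d in (Direction.X, Direction.Z):
                entries[(d, rid, a)] = (
                    reg.extent(d) * _WIDTH_CURVES[rid][d][i]
                )
    # pin the age-18 column to the exact generic extents so F_dis(., 18) = 1
    for rid in BodyRegionId:
        reg = phantom.region_for(rid)
        for d in Direction:
            entries[(d, rid, 18.0)] = reg.extent(d)

    table = GrowthTable(entries)
    table.validate(phantom)
    return phantom, table
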