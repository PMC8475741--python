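"""Age-scaling coordinate transforms and DICOM reorientation.

Each point of the generic phantom is mapped to the target age with an
axis-separable affine transform driven by the continuous scaling factors:

* x (left-right): the phantom is symmetric about x = 0, so
  ``x_t = x * F_cont(x, r, a)``.
* y (superior-inferior): regions must stay contiguous as they scale, so
  the transformed y is a telescoping sum of fully scaled region lengths
  for every region superior to the point's region, plus the scaled
  in-region offset.  The transformed phantom is re-based at y_t = 0 at
  the top of the upper head (the 1 cm generic origin vanishes).
* z (anterior-posterior): each region's anterior face sits at a different
  depth, so the in-region offset is scaled and shifted by
  ``z_shift = (l_head,z * F(z, uh, a) - l_r,z * F(z, r, a)) / 2``,
  which centres every region's depth extent on the head's mid-plane.

Arms scale with their own factors and are re-attached at the trunk's
transformed superior boundary.

The scaled phantom lives in the phantom frame (cm); ``reorient_to_dicom``
applies the rigid map to the DICOM patient frame (mm, LPS, head-first
supine): L = 10x, P = 10z, S = -10y.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .growth_scaling import GrowthTable, ScalingFactorSet, compute_factors
from .phantom_model import (
    CHAIN_ORDER,
    BodyRegion,
    BodyRegionId,
    Direction,
    GenericPhantom,
    OrganGrid,
)

__all__ = [
    "TransformContext",
    "ScaledPhantom",
    "transform_x",
    "transform_y",
    "transform_z",
    "scale_phantom",
    "reorient_to_dicom",
    "reorient_to_phantom",
    "phantom_height",
]


@dataclass
class TransformContext:
    """Cached per-region geometry and factors for one target age.

    ``y_offset[r]`` is the transformed y of region r's superior boundary
    (the telescoping partial sum of scaled lengths); ``z_shift[r]``
    centres region depths on the reference head's mid-plane.
    ``head_region`` selects which region supplies l_head,z (upper head
    by default).
    """

    phantom: GenericPhantom
    factors: ScalingFactorSet
    head_region: BodyRegionId = BodyRegionId.UH
    y_sbr: dict[BodyRegionId, float] = field(init=False)
    y_ibr: dict[BodyRegionId, float] = field(init=False)
    z_abr: dict[BodyRegionId, float] = field(init=False)
    l_y: dict[BodyRegionId, float] = field(init=False)
    l_z: dict[BodyRegionId, float] = field(init=False)
    y_offset: dict[BodyRegionId, float] = field(init=False)
    z_shift: dict[BodyRegionId, float] = field(init=False)

    def __post_init__(self) -> None:
        ph = self.phantom
        self.y_sbr, self.y_ibr, self.z_abr = {}, {}, {}
        self.l_y, self.l_z = {}, {}
        for rid in BodyRegionId:
            reg = ph.region_for(rid)
            self.y_sbr[rid] = reg.y_sbr
            self.y_ibr[rid] = reg.y_ibr
            self.z_abr[rid] = reg.z_abr
            self.l_y[rid] = reg.l_y
            self.l_z[rid] = reg.l_z
        # telescoping y offsets down the chain
        self.y_offset = {}
        acc = 0.0
        for rid in CHAIN_ORDER:
            self.y_offset[rid] = acc
            acc = acc + self.l_y[rid] * self.factors[(Direction.Y, rid)]
        # arms re-attach at the trunk's transformed superior boundary
        self.y_offset[BodyRegionId.AR] = self.y_offset[BodyRegionId.TR]
        # z shifts centre every region on the head's scaled mid-plane
        l_head_z = self.l_z[self.head_region]
        f_head_z = self.factors[(Direction.Z, self.head_region)]
        self.z_shift = {
            rid: (l_head_z * f_head_z
                  - self.l_z[rid] * self.factors[(Direction.Z, rid)]) / 2.0
            for rid in BodyRegionId
        }

    @classmethod
    def create(cls, phantom: GenericPhantom, table: GrowthTable, age: float,
               head_region: BodyRegionId = BodyRegionId.UH) -> "TransformContext":
        return cls(phantom=phantom, factors=compute_factors(table, age),
                   head_region=head_region)


def transform_x(x: float, r: BodyRegionId, ctx: TransformContext) -> float:
    """Scale a left-right coordinate about the symmetry plane x = 0."""
    return x * ctx.factors[(Direction.X, r)]


def transform_y(y: float, r: BodyRegionId, ctx: TransformContext) -> float:
    """Map a superior-inferior coordinate: scaled lengths of all regions
    superior to r, plus the scaled in-region offset."""
    r = BodyRegionId(r)
    if not (ctx.y_sbr[r] - 1e-9 <= y <= ctx.y_ibr[r] + 1e-9):
        raise ValueError(
            f"y={y} outside region {r.value} bounds "
            f"[{ctx.y_sbr[r]}, {ctx.y_ibr[r]}]"
        )
    return ctx.y_offset[r] + (y - ctx.y_sbr[r]) * ctx.factors[(Direction.Y, r)]


def transform_z(z: float, r: BodyRegionId, ctx: TransformContext) -> float:
    """Map an anterior-posterior coordinate: scaled offset from the
    region's anterior boundary plus the centring shift."""
    r = BodyRegionId(r)
    z_post = ctx.z_abr[r] + ctx.l_z[r]
    if not (ctx.z_abr[r] - 1e-9 <= z <= z_post + 1e-9):
        raise ValueError(
            f"z={z} outside region {r.value} extent "
            f"[{ctx.z_abr[r]}, {z_post}]"
        )
    return (z - ctx.z_abr[r]) * ctx.factors[(Direction.Z, r)] + ctx.z_shift[r]


def _transform_points(pts: np.ndarray, r: BodyRegionId,
                      ctx: TransformContext) -> np.ndarray:
    """Vectorized per-region affine map of an (N, 3) point array."""
    fx = ctx.factors[(Direction.X, r)]
    fy = ctx.factors[(Direction.Y, r)]
    fz = ctx.factors[(Direction.Z, r)]
    out = np.empty_like(pts, dtype=float)
    out[:, 0] = pts[:, 0] * fx
    out[:, 1] = ctx.y_offset[r] + (pts[:, 1] - ctx.y_sbr[r]) * fy
    out[:, 2] = (pts[:, 2] - ctx.z_abr[r]) * fz + ctx.z_shift[r]
    return out


@dataclass
class ScaledPhantom:
    """The phantom transformed to a target age.

    ``frame`` is ``"phantom"`` (cm, y superior-to-inferior) straight out
    of :func:`scale_phantom`, or ``"dicom"`` (mm, LPS, head-first supine)
    after :func:`reorient_to_dicom`.
    """

    age: float
    regions: dict[BodyRegionId, BodyRegion]
    arms: list[BodyRegion]
    organs: list[OrganGrid]
    frame: str = "phantom"
    factors: ScalingFactorSet | None = None

    def region_for(self, rid: BodyRegionId) -> BodyRegion:
        if rid is BodyRegionId.AR:
            return self.arms[0]
        return self.regions[rid]

    def all_regions(self) -> list[BodyRegion]:
        return [self.regions[r] for r in CHAIN_ORDER] + list(self.arms)

    def chain_regions(self) -> list[BodyRegion]:
        return [self.regions[r] for r in CHAIN_ORDER]


def scale_phantom(phantom: GenericPhantom, table: GrowthTable, age: float,
                  head_region: BodyRegionId = BodyRegionId.UH) -> ScaledPhantom:
    """Transform every region corner and organ point to the target age.

    At age 18 all factors are exactly 1 and the phantom is merely
    re-based (y origin to 0, z extents centred on the head mid-plane).
    """
    ctx = TransformContext.create(phantom, table, age, head_region)
    regions = {
        rid: BodyRegion(
            id=rid,
            corners=_transform_points(phantom.regions[rid].corners, rid, ctx),
        )
        for rid in CHAIN_ORDER
    }
    arms = [
        BodyRegion(id=BodyRegionId.AR,
                   corners=_transform_points(a.corners, BodyRegionId.AR, ctx))
        for a in phantom.arms
    ]
    organs = []
    for org in phantom.organs:
        try:
            pts = _transform_points(org.points, org.region, ctx)
        except ValueError as e:  # pragma: no cover - defensive
            raise ValueError(f"organ {org.name}: {e}") from e
        organs.append(OrganGrid(name=org.name, region=org.region, points=pts))
    return ScaledPhantom(age=ctx.factors.age, regions=regions, arms=arms,
                         organs=organs, frame="phantom", factors=ctx.factors)


# ---------------------------------------------------------------------
# DICOM patient frame (head-first supine)
# ---------------------------------------------------------------------

# Phantom frame (cm): +x left, +y superior->inferior, +z anterior->posterior.
# DICOM LPS (mm):     L = 10x, P = 10z, S = -10y.  This is a rotation
# (det +1) composed with the cm->mm dilation; the head (small y) maps to
# the largest S, i.e. head-first supine.

def _map_to_dicom(pts: np.ndarray) -> np.ndarray:
    out = np.empty_like(pts, dtype=float)
    out[:, 0] = pts[:, 0] * 10.0
    out[:, 1] = pts[:, 2] * 10.0
    out[:, 2] = -pts[:, 1] * 10.0
    return out


def _map_to_phantom(pts: np.ndarray) -> np.ndarray:
    out = np.empty_like(pts, dtype=float)
    out[:, 0] = pts[:, 0] / 10.0
    out[:, 1] = -pts[:, 2] / 10.0
    out[:, 2] = pts[:, 1] / 10.0
    return out


def _remap(sp: ScaledPhantom, fn, frame: str) -> ScaledPhantom:
    regions = {
        rid: BodyRegion(id=rid, corners=fn(reg.corners))
        for rid, reg in sp.regions.items()
    }
    arms = [BodyRegion(id=a.id, corners=fn(a.corners)) for a in sp.arms]
    organs = [
        OrganGrid(name=o.name, region=o.region, points=fn(o.points))
        for o in sp.organs
    ]
    return ScaledPhantom(age=sp.age, regions=regions, arms=arms,
                         organs=organs, frame=frame, factors=sp.factors)


def reorient_to_dicom(sp: ScaledPhantom) -> ScaledPhantom:
    """Rigidly reorient a phantom-frame phantom into the DICOM patient
    frame (mm, LPS), head-first supine."""
    if sp.frame != "phantom":
        raise ValueError(f"phantom already in frame {sp.frame!r}")
    return _remap(sp, _map_to_dicom, "dicom")


def reorient_to_phantom(sp: ScaledPhantom) -> ScaledPhantom:
    """Inverse of :func:`reorient_to_dicom`."""
    if sp.frame != "dicom":
        raise ValueError(f"phantom is in frame {sp.frame!r}, not 'dicom'")
    return _remap(sp, _map_to_phantom, "phantom")


def phantom_height(sp: ScaledPhantom) -> float:
    """Stature of the scaled phantom in cm: the span of the contiguous
    region chain along the superior-inferior axis."""
    if sp.frame == "phantom":
        ys = np.concatenate([r.corners[:, 1] for r in sp.chain_regions()])
        return float(ys.max() - ys.min())
    ss = np.concatenate([r.corners[:, 2] for r in sp.chain_regions()])
    return float((ss.max() - ss.min()) / 10.0)
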