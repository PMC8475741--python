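"""DICOM export: box ROIs, convex-hull organ contours, RT Structure Set
and an optional synthetic CT series.

Body-region cuboids become stacks of rectangular closed planar contours
("box ROIs"); organ point grids become the axial cross-sections of their
3-D convex hull.  Contours live on a common axial slice grid: slices sit
at S = origin + (k + 1/2) * spacing and a structure occupies every slice
whose position falls in its half-open S-extent [S_min, S_max), which
makes contour counts deterministic.

Organs whose point grid does not span three dimensions (fewer than four
non-coplanar points, e.g. a single-point pituitary) cannot be contoured;
they are exported as POINT ROIs rather than silently dropped, preserving
their use for point-dose lookup.

The RT Structure Set is written as a standard Part 10 file (SOP class
1.2.840.10008.5.1.4.1.1.481.3) with coordinates serialized as decimal
strings at 0.001 mm resolution, and can be read back losslessly to that
resolution.  The synthetic CT series hosts the structures in a TPS: the
phantom is water-equivalent by construction, so voxels inside any body
region get 0 HU and everything else -1000 HU (air).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .geometry_transform import ScaledPhantom
from .phantom_model import CHAIN_ORDER, BodyRegion, BodyRegionId, OrganGrid

__all__ = [
    "PlanarContour",
    "Roi",
    "RoiSet",
    "NonContourableOrgan",
    "slice_positions",
    "box_roi",
    "hull_contours",
    "build_roi_set",
    "write_rtstruct",
    "read_rtstruct",
    "write_synthetic_ct",
    "CTSeriesInfo",
]

RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"
CT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.2"

#: Default axial slice spacing (mm); typical pediatric CT slice thickness.
DEFAULT_SLICE_SPACING_MM = 2.5

_HU_WATER = 0
_HU_AIR = -1000

# fixed timestamps keep output files reproducible
_CONTENT_DATE = "20200101"
_CONTENT_TIME = "120000"


class NonContourableOrgan(ValueError):
    """Raised when an organ's point grid cannot form a 3-D convex hull."""

    def __init__(self, organ_name: str, n_points: int):
        self.organ_name = organ_name
        self.n_points = n_points
        super().__init__(
            f"organ {organ_name!r} with {n_points} point(s) has no 3-D "
            "convex hull (needs >= 4 non-coplanar points); export it as a "
            "POINT ROI instead"
        )


@dataclass
class PlanarContour:
    """A closed planar polygon on one axial slice.

    ``position`` is the S coordinate (mm); ``vertices`` an (N, 2) array
    of (L, P) mm pairs, N >= 3, counter-clockwise (positive shoelace
    area in the L-P plane), first vertex not repeated.
    """

    position: float
    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array")
        if len(self.vertices) < 3:
            raise ValueError("a planar contour needs at least 3 vertices")
        if _shoelace(self.vertices) < 0:
            self.vertices = self.vertices[::-1].copy()

    @property
    def area(self) -> float:
        return abs(_shoelace(self.vertices))

    def points3d(self) -> np.ndarray:
        """(N, 3) LPS mm vertex array."""
        n = len(self.vertices)
        return np.column_stack(
            [self.vertices, np.full(n, self.position)]
        )


def _shoelace(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(
        np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    )


@dataclass
class Roi:
    """One named structure: either a contour stack or a single point."""

    name: str
    kind: str  # "body-region" | "organ"
    contours: list[PlanarContour] = field(default_factory=list)
    point: np.ndarray | None = None  # LPS mm, for non-contourable organs
    color: tuple[int, int, int] = (255, 0, 0)

    @property
    def is_point(self) -> bool:
        return self.point is not None


@dataclass
class RoiSet:
    """All structures sharing one frame of reference and slice grid."""

    rois: list[Roi]
    frame_of_reference_uid: str
    slice_spacing: float = DEFAULT_SLICE_SPACING_MM

    def names(self) -> list[str]:
        return [r.name for r in self.rois]

    def get(self, name: str) -> Roi:
        for r in self.rois:
            if r.name == name:
                return r
        raise KeyError(name)


# ---------------------------------------------------------------------
# Slicing
# ---------------------------------------------------------------------

def slice_positions(s_min: float, s_max: float, spacing: float,
                    origin: float | None = None) -> np.ndarray:
    """Axial slice S positions covering [s_min, s_max) on the pinned
    half-open grid: S = origin + (k + 1/2) * spacing."""
    if spacing <= 0:
        raise ValueError("slice spacing must be positive")
    if origin is None:
        origin = s_min
    k_lo = int(np.ceil((s_min - origin) / spacing - 0.5 - 1e-12))
    out = []
    k = k_lo
    while True:
        s = origin + (k + 0.5) * spacing
        if s >= s_max - 1e-12:
            break
        if s >= s_min - 1e-12:
            out.append(s)
        k += 1
    return np.asarray(out)


def box_roi(region: BodyRegion, slice_spacing: float,
            origin: float | None = None) -> list[PlanarContour]:
    """Rectangular contours of a DICOM-frame cuboid, one per slice
    intersecting its S-extent; each rectangle is the exact L-P
    cross-section."""
    lo = region.corners.min(axis=0)
    hi = region.corners.max(axis=0)
    if np.any(hi - lo <= 0):
        raise ValueError(
            f"region {region.id.value}: degenerate (zero-extent) cuboid"
        )
    rect = np.array(
        [[lo[0], lo[1]], [hi[0], lo[1]], [hi[0], hi[1]], [lo[0], hi[1]]]
    )
    return [
        PlanarContour(position=float(s), vertices=rect.copy())
        for s in slice_positions(lo[2], hi[2], slice_spacing, origin)
    ]


def _hull_plane_section(points: np.ndarray, hull, s: float,
                        tol: float = 1e-9) -> np.ndarray | None:
    """Intersect a convex hull with the plane S = s; return (N, 2)
    CCW-orderable (L, P) vertices or None for an empty/tangent section."""
    verts = points[hull.vertices]
    section: list[np.ndarray] = []
    # hull vertices lying (nearly) on the plane
    on_plane = np.abs(verts[:, 2] - s) <= tol
    section.extend(verts[on_plane][:, :2])
    # edge crossings
    edges = set()
    for simplex in hull.simplices:
        for i in range(3):
            a, b = simplex[i], simplex[(i + 1) % 3]
            edges.add((min(a, b), max(a, b)))
    for a, b in edges:
        pa, pb = points[a], points[b]
        da, db = pa[2] - s, pb[2] - s
        if da * db < 0:
            t = da / (da - db)
            p = pa + t * (pb - pa)
            section.append(p[:2])
    if not section:
        return None
    pts = np.unique(np.round(np.vstack(section), 9), axis=0)
    if len(pts) < 3:
        return None
    center = pts.mean(axis=0)
    order = np.argsort(np.arctan2(pts[:, 1] - center[1], pts[:, 0] - center[0]))
    poly = pts[order]
    if abs(_shoelace(poly)) < 1e-9:
        return None
    return poly


def hull_contours(organ: OrganGrid, slice_spacing: float,
                  origin: float | None = None) -> list[PlanarContour]:
    """Axial contours of the organ's 3-D convex hull.

    Raises :class:`NonContourableOrgan` for grids with fewer than four
    non-coplanar points.  Tangent slices with zero cross-section area
    produce no contour.
    """
    from scipy.spatial import ConvexHull, QhullError

    if not organ.contourable:
        raise NonContourableOrgan(organ.name, organ.n_points)
    pts = organ.points
    try:
        hull = ConvexHull(pts)
    except QhullError as e:  # degenerate despite the rank check
        raise NonContourableOrgan(organ.name, organ.n_points) from e
    s_lo = float(pts[:, 2].min())
    s_hi = float(pts[:, 2].max())
    contours = []
    for s in slice_positions(s_lo, s_hi, slice_spacing, origin):
        poly = _hull_plane_section(pts, hull, float(s))
        if poly is not None:
            contours.append(PlanarContour(position=float(s), vertices=poly))
    return contours


_REGION_NAMES = {
    BodyRegionId.UH: "UpperHead",
    BodyRegionId.LH: "LowerHead",
    BodyRegionId.N: "Neck",
    BodyRegionId.TR: "Trunk",
    BodyRegionId.LG: "Legs",
}

_PALETTE = [
    (255, 80, 80), (80, 160, 255), (80, 220, 120), (250, 190, 60),
    (200, 100, 240), (90, 220, 220), (240, 120, 180), (160, 160, 90),
]


def build_roi_set(phantom: ScaledPhantom, slice_spacing: float =
                  DEFAULT_SLICE_SPACING_MM,
                  name_prefix: str = "") -> tuple[RoiSet, list[str]]:
    """Convert a DICOM-frame scaled phantom into an RoiSet on one common
    slice grid.

    Returns the RoiSet plus a list of warnings (non-contourable organs
    exported as POINT ROIs).
    """
    if phantom.frame != "dicom":
        raise ValueError("phantom must be in the DICOM frame; call "
                         "reorient_to_dicom first")
    all_s = np.concatenate(
        [r.corners[:, 2] for r in phantom.all_regions()]
    )
    origin = float(all_s.min())
    rois: list[Roi] = []
    notes: list[str] = []
    for i, rid in enumerate(CHAIN_ORDER):
        reg = phantom.regions[rid]
        rois.append(
            Roi(name=name_prefix + _REGION_NAMES[rid], kind="body-region",
                contours=box_roi(reg, slice_spacing, origin),
                color=_PALETTE[i % len(_PALETTE)])
        )
    for j, arm in enumerate(phantom.arms):
        rois.append(
            Roi(name=name_prefix + f"Arm_{'LR'[j % 2]}", kind="body-region",
                contours=box_roi(arm, slice_spacing, origin),
                color=_PALETTE[(len(CHAIN_ORDER) + j) % len(_PALETTE)])
        )
    for k, org in enumerate(phantom.organs):
        color = _PALETTE[k % len(_PALETTE)]
        try:
            contours = hull_contours(org, slice_spacing, origin)
        except NonContourableOrgan:
            centroid = org.points.mean(axis=0)
            notes.append(
                f"organ {org.name}: {org.n_points} point(s) cannot form a "
                "contoured volume; exported as POINT ROI"
            )
            warnings.warn(notes[-1], stacklevel=2)
            rois.append(Roi(name=name_prefix + org.name, kind="organ",
                            point=centroid, color=color))
            continue
        rois.append(Roi(name=name_prefix + org.name, kind="organ",
                        contours=contours, color=color))
    return (
        RoiSet(rois=rois, frame_of_reference_uid=generate_uid(),
               slice_spacing=slice_spacing),
        notes,
    )


# ---------------------------------------------------------------------
# RT Structure Set read/write
# ---------------------------------------------------------------------

def _ds(v: float) -> str:
    # decimal string at 0.001 mm resolution
    return f"{v:.3f}"


def _uid(entropy: list[str] | None, *extra: str) -> str:
    if entropy is None:
        return generate_uid()
    return generate_uid(entropy_srcs=list(entropy) + list(extra))


def write_rtstruct(rois: RoiSet, path: str | Path,
                   metadata: dict | None = None,
                   ct_series: "CTSeriesInfo | None" = None) -> Path:
    """Write an RT Structure Set Part 10 file.

    ``metadata`` may carry ``patient_name``, ``patient_id``, ``age_years``
    and ``uid_entropy`` (a list of strings making all generated UIDs
    deterministic).  If ``ct_series`` is given, its frame of reference and
    study are referenced so a TPS associates the structures with the
    images.
    """
    if not rois.rois:
        raise ValueError("cannot write an RT Structure Set with no ROIs")
    md = dict(metadata or {})
    entropy = md.get("uid_entropy")
    for_uid = (ct_series.frame_of_reference_uid if ct_series is not None
               else rois.frame_of_reference_uid)
    if not for_uid:
        raise ValueError("missing frame of reference UID")

    sop_uid = _uid(entropy, "rtstruct-sop")
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTSTRUCT_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SpecificCharacterSet = "ISO_IR 192"
    ds.SOPClassUID = RTSTRUCT_SOP_CLASS
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "RTSTRUCT"
    ds.Manufacturer = "agephantom"
    ds.PatientName = md.get("patient_name", "Phantom^AgeScalable")
    ds.PatientID = md.get("patient_id", "AGEPHANTOM")
    ds.PatientBirthDate = ""
    ds.PatientSex = "O"
    if "age_years" in md:
        ds.PatientAge = f"{min(int(round(md['age_years'])), 999):03d}Y"
    ds.StudyInstanceUID = (ct_series.study_instance_uid if ct_series
                           else _uid(entropy, "study"))
    ds.SeriesInstanceUID = _uid(entropy, "rtstruct-series")
    ds.StudyID = "1"
    ds.SeriesNumber = 1
    ds.StudyDate = _CONTENT_DATE
    ds.StudyTime = _CONTENT_TIME
    ds.ReferringPhysicianName = ""
    ds.AccessionNumber = ""
    ds.StructureSetLabel = md.get("label", "AgePhantom")
    ds.StructureSetDate = _CONTENT_DATE
    ds.StructureSetTime = _CONTENT_TIME
    ds.ApprovalStatus = "UNAPPROVED"
    ds.InstanceCreationDate = _CONTENT_DATE
    ds.InstanceCreationTime = _CONTENT_TIME

    ref_for = Dataset()
    ref_for.FrameOfReferenceUID = for_uid
    if ct_series is not None:
        ref_study = Dataset()
        ref_study.ReferencedSOPClassUID = "1.2.840.10008.3.1.2.3.1"
        ref_study.ReferencedSOPInstanceUID = ct_series.study_instance_uid
        ref_series = Dataset()
        ref_series.SeriesInstanceUID = ct_series.series_instance_uid
        cis = []
        for sop in ct_series.sop_instance_uids:
            ci = Dataset()
            ci.ReferencedSOPClassUID = CT_SOP_CLASS
            ci.ReferencedSOPInstanceUID = sop
            cis.append(ci)
        ref_series.ContourImageSequence = cis
        ref_study.RTReferencedSeriesSequence = [ref_series]
        ref_for.RTReferencedStudySequence = [ref_study]
    ds.ReferencedFrameOfReferenceSequence = [ref_for]

    ssr_seq, rc_seq, obs_seq = [], [], []
    for num, roi in enumerate(rois.rois, start=1):
        ssr = Dataset()
        ssr.ROINumber = num
        ssr.ReferencedFrameOfReferenceUID = for_uid
        ssr.ROIName = roi.name
        ssr.ROIGenerationAlgorithm = "AUTOMATIC"
        ssr_seq.append(ssr)

        rc = Dataset()
        rc.ROIDisplayColor = list(roi.color)
        rc.ReferencedROINumber = num
        contour_items = []
        if roi.is_point:
            c = Dataset()
            c.ContourGeometricType = "POINT"
            c.NumberOfContourPoints = 1
            c.ContourData = [_ds(v) for v in roi.point]
            contour_items.append(c)
        else:
            for pc in roi.contours:
                c = Dataset()
                c.ContourGeometricType = "CLOSED_PLANAR"
                c.NumberOfContourPoints = len(pc.vertices)
                c.ContourData = [
                    _ds(v) for v in pc.points3d().ravel()
                ]
                contour_items.append(c)
        rc.ContourSequence = contour_items
        rc_seq.append(rc)

        obs = Dataset()
        obs.ObservationNumber = num
        obs.ReferencedROINumber = num
        obs.ROIObservationLabel = roi.name
        obs.RTROIInterpretedType = (
            "ORGAN" if roi.kind == "organ" else "EXTERNAL"
        )
        obs.ROIInterpreter = ""
        obs_seq.append(obs)

    ds.StructureSetROISequence = ssr_seq
    ds.ROIContourSequence = rc_seq
    ds.RTROIObservationsSequence = obs_seq

    path = Path(path)
    ds.save_as(path, enforce_file_format=True)
    return path


def read_rtstruct(path: str | Path) -> RoiSet:
    """Read an RT Structure Set back into an RoiSet (mm, LPS)."""
    ds = pydicom.dcmread(path)
    if ds.SOPClassUID != RTSTRUCT_SOP_CLASS:
        raise ValueError(f"{path} is not an RT Structure Set")
    for_uid = ds.ReferencedFrameOfReferenceSequence[0].FrameOfReferenceUID
    names = {int(s.ROINumber): str(s.ROIName)
             for s in ds.StructureSetROISequence}
    kinds = {}
    for obs in getattr(ds, "RTROIObservationsSequence", []):
        kinds[int(obs.ReferencedROINumber)] = (
            "organ" if str(obs.RTROIInterpretedType) == "ORGAN"
            else "body-region"
        )
    rois = []
    for rc in ds.ROIContourSequence:
        num = int(rc.ReferencedROINumber)
        color = tuple(int(c) for c in getattr(rc, "ROIDisplayColor",
                                              (255, 0, 0)))
        contours: list[PlanarContour] = []
        point = None
        for c in getattr(rc, "ContourSequence", []):
            data = np.asarray([float(v) for v in c.ContourData])
            pts = data.reshape(-1, 3)
            if str(c.ContourGeometricType) == "POINT":
                point = pts[0]
            else:
                contours.append(
                    PlanarContour(position=float(pts[0, 2]),
                                  vertices=pts[:, :2])
                )
        rois.append(Roi(name=names[num], kind=kinds.get(num, "organ"),
                        contours=contours, point=point, color=color))
    return RoiSet(rois=rois, frame_of_reference_uid=str(for_uid))


# ---------------------------------------------------------------------
# Synthetic CT series
# ---------------------------------------------------------------------

@dataclass
class CTSeriesInfo:
    """Identifiers and geometry of a written synthetic CT series."""

    study_instance_uid: str
    series_instance_uid: str
    frame_of_reference_uid: str
    sop_instance_uids: list[str]
    paths: list[Path]
    shape: tuple[int, int, int]  # (n_slices, rows, cols)


def write_synthetic_ct(phantom: ScaledPhantom, voxel: tuple[float, float, float],
                       out_dir: str | Path, margin_mm: float = 10.0,
                       metadata: dict | None = None,
                       memory_budget_mb: float = 512.0) -> CTSeriesInfo:
    """Write an axial synthetic CT series hosting the phantom.

    ``voxel`` is (L, P, S) spacing in mm.  Voxels whose centre lies in
    any body-region cuboid get 0 HU (water); everything else -1000 HU.
    """
    if phantom.frame != "dicom":
        raise ValueError("phantom must be in the DICOM frame")
    vx, vy, vz = (float(v) for v in voxel)
    if min(vx, vy, vz) <= 0:
        raise ValueError("voxel sizes must be positive")
    md = dict(metadata or {})
    entropy = md.get("uid_entropy")

    corners = np.vstack([r.corners for r in phantom.all_regions()])
    lo = corners.min(axis=0) - margin_mm
    hi = corners.max(axis=0) + margin_mm
    nx = int(np.ceil((hi[0] - lo[0]) / vx))
    ny = int(np.ceil((hi[1] - lo[1]) / vy))
    nz = int(np.ceil((hi[2] - lo[2]) / vz))
    need_mb = nx * ny * nz * 2 / 1e6
    if need_mb > memory_budget_mb:
        raise MemoryError(
            f"synthetic CT grid {nx}x{ny}x{nz} needs ~{need_mb:.0f} MB "
            f"(budget {memory_budget_mb:.0f} MB); use coarser voxels"
        )

    ls = lo[0] + (np.arange(nx) + 0.5) * vx
    ps = lo[1] + (np.arange(ny) + 0.5) * vy
    ss = lo[2] + (np.arange(nz) + 0.5) * vz
    gl, gp = np.meshgrid(ls, ps)  # (ny, nx): rows along P, cols along L

    boxes = [(r.corners.min(axis=0), r.corners.max(axis=0))
             for r in phantom.all_regions()]

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    study_uid = _uid(entropy, "study")
    series_uid = _uid(entropy, "ct-series")
    for_uid = md.get("frame_of_reference_uid") or _uid(entropy, "for")
    sop_uids, paths = [], []

    for k in range(nz):
        s = ss[k]
        img = np.full((ny, nx), _HU_AIR, dtype=np.int16)
        for blo, bhi in boxes:
            if not (blo[2] <= s <= bhi[2]):
                continue
            mask = ((gl >= blo[0]) & (gl <= bhi[0])
                    & (gp >= blo[1]) & (gp <= bhi[1]))
            img[mask] = _HU_WATER

        sop = _uid(entropy, f"ct-{k}")
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CT_SOP_CLASS
        meta.MediaStorageSOPInstanceUID = sop
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset("", {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SpecificCharacterSet = "ISO_IR 192"
        ds.SOPClassUID = CT_SOP_CLASS
        ds.SOPInstanceUID = sop
        ds.Modality = "CT"
        ds.Manufacturer = "agephantom"
        ds.PatientName = md.get("patient_name", "Phantom^AgeScalable")
        ds.PatientID = md.get("patient_id", "AGEPHANTOM")
        ds.PatientBirthDate = ""
        ds.PatientSex = "O"
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = for_uid
        ds.PositionReferenceIndicator = ""
        ds.StudyID = "1"
        ds.SeriesNumber = 2
        ds.InstanceNumber = k + 1
        ds.StudyDate = _CONTENT_DATE
        ds.StudyTime = _CONTENT_TIME
        ds.ReferringPhysicianName = ""
        ds.AccessionNumber = ""
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [_ds(ls[0]), _ds(ps[0]), _ds(s)]
        ds.SliceLocation = _ds(s)
        ds.SliceThickness = _ds(vz)
        ds.PixelSpacing = [_ds(vy), _ds(vx)]  # row (P), column (L)
        ds.Rows = ny
        ds.Columns = nx
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.RescaleIntercept = "0"
        ds.RescaleSlope = "1"
        ds.RescaleType = "HU"
        ds.ImageType = ["DERIVED", "PRIMARY", "AXIAL"]
        ds.PixelData = img.tobytes()
        p = out_dir / f"ct_{k + 1:04d}.dcm"
        ds.save_as(p, enforce_file_format=True)
        sop_uids.append(sop)
        paths.append(p)

    return CTSeriesInfo(
        study_instance_uid=study_uid,
        series_instance_uid=series_uid,
        frame_of_reference_uid=for_uid,
        sop_instance_uids=sop_uids,
        paths=paths,
        shape=(nz, ny, nx),
    )
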