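"""Position of the active contact relative to the segmented GPi.

Where a stimulating contact sits *inside* the internal pallidum matters
more than its absolute stereotactic coordinates: the motor territory is
the posteroventral portion of the structure, and pallidal size and pose
vary between patients.  This module formalizes the boundary-point
construction used to normalize the contact position:

* In the axial (AC-PC) plane through the active contact, **A** and **P**
  are the most anterior and most posterior points of the structure.
* **M** and **L** are the medial and lateral boundary crossings of the
  lateral-axis line through the contact in that plane.
* **V** and **D** are the ventral and dorsal crossings of the
  vertical-axis line through the contact.

Projecting the contact C orthogonally onto each boundary segment gives
three dimensionless indices::

    AP-index = |A S_ap| / |A P|     (> 0.5 means posterior)
    ML-index = |M S_ml| / |M L|
    VD-index = |V S_vd| / |V D|     (< 0.5 means ventral)

Boundary crossings are localized with sub-voxel linear interpolation
along rays sampled at 0.1 mm.  Indices are reported as signed projection
parameters and left unclamped: a value outside [0, 1] flags a contact
beyond the structure's span on that axis instead of being silently
truncated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple

import nibabel as nib
import numpy as np

from .coords import StereotacticFrame

__all__ = [
    "ContactOutsideStructureError",
    "DegenerateBoundaryError",
    "SegmentationMask",
    "GpiBoundaryFix",
    "IndexTriple",
    "boundary_points",
    "indices",
    "locate_contact",
    "classify_contact",
    "ContactLocation",
]

#: Step (mm) for ray sampling when localizing boundary crossings.
RAY_STEP_MM = 0.1


class ContactOutsideStructureError(ValueError):
    """The contact does not lie within the structure's extent."""


class DegenerateBoundaryError(ValueError):
    """A boundary segment has zero length."""


@dataclass(frozen=True)
class SegmentationMask:
    """Boolean voxel mask with a voxel-to-world affine (mm).

    Voxel indices are 0-based; a voxel is foreground where the array is
    True.  ``label`` names the structure (e.g. ``"GPi"``).
    """

    data: np.ndarray
    affine: np.ndarray
    label: str = "GPi"

    def __post_init__(self) -> None:
        data = np.asarray(self.data).astype(bool)
        affine = np.asarray(self.affine, dtype=float)
        if data.ndim != 3:
            raise ValueError("mask must be a 3D array")
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if not data.any():
            raise ValueError("mask has no foreground voxels")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)

    @classmethod
    def from_nifti(cls, path, label: str = "GPi") -> "SegmentationMask":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj) > 0.5, img.affine, label=label)

    def to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), self.affine), str(path))

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_diagonal(self) -> float:
        """Length (mm) of a voxel's space diagonal."""
        return float(np.linalg.norm(self.voxel_sizes))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Nearest-voxel foreground test for (..., 3) world-mm points."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        inv = np.linalg.inv(self.affine)
        vox = pts @ inv[:3, :3].T + inv[:3, 3]
        idx = np.rint(vox).astype(int)
        inside = np.all((idx >= 0) & (idx < np.array(self.data.shape)), axis=1)
        out = np.zeros(len(pts), dtype=bool)
        if inside.any():
            ii = idx[inside]
            out[inside] = self.data[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out[0] if single else out

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned world bounding box of the foreground voxels."""
        ijk = np.argwhere(self.data).astype(float)
        corners = []
        for off in np.ndindex(2, 2, 2):
            corners.append(ijk + (np.array(off) - 0.5))
        allc = np.concatenate(corners, axis=0)
        world = allc @ self.affine[:3, :3].T + self.affine[:3, 3]
        return world.min(axis=0), world.max(axis=0)


class IndexTriple(NamedTuple):
    ap_index: float
    ml_index: float
    vd_index: float


@dataclass(frozen=True)
class GpiBoundaryFix:
    """Six boundary points at the active-contact level plus the indices.

    Points are world mm.  ``S_*`` are the orthogonal projections of the
    contact onto the corresponding boundary segment; they and the index
    values are filled by :func:`indices`.
    """

    A: np.ndarray
    P: np.ndarray
    M: np.ndarray
    L: np.ndarray
    V: np.ndarray
    D: np.ndarray
    contact: np.ndarray
    S_ap: np.ndarray | None = None
    S_ml: np.ndarray | None = None
    S_vd: np.ndarray | None = None
    ap_index: float | None = None
    ml_index: float | None = None
    vd_index: float | None = None


def _run_crossings(t: np.ndarray, fg: np.ndarray) -> list[tuple[float, float]]:
    """Contiguous foreground runs as (t_entry, t_exit) with sub-step
    linear interpolation of the binary transition."""
    if not fg.any():
        return []
    padded = np.concatenate([[False], fg, [False]])
    d = np.diff(padded.astype(int))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0] - 1
    runs = []
    for s, e in zip(starts, ends):
        t_in = t[s] if s == 0 else 0.5 * (t[s - 1] + t[s])
        t_out = t[e] if e == len(t) - 1 else 0.5 * (t[e] + t[e + 1])
        runs.append((float(t_in), float(t_out)))
    return runs


def _select_run(runs: list[tuple[float, float]], t0: float) -> tuple[float, float]:
    """The run containing parameter ``t0``, else the nearest run."""
    for r in runs:
        if r[0] <= t0 <= r[1]:
            return r
    return min(runs, key=lambda r: min(abs(t0 - r[0]), abs(t0 - r[1])))


def _line_crossings(
    mask: SegmentationMask, origin: np.ndarray, direction: np.ndarray,
    t_lo: float, t_hi: float, t0: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Entry/exit points of the mask along ``origin + t*direction``."""
    t = np.arange(t_lo, t_hi + RAY_STEP_MM, RAY_STEP_MM)
    pts = origin[None, :] + t[:, None] * direction[None, :]
    fg = mask.contains(pts)
    runs = _run_crossings(t, fg)
    if not runs:
        raise ContactOutsideStructureError(
            f"no {mask.label} crossing on the line through the contact"
        )
    t_in, t_out = _select_run(runs, t0)
    return origin + t_in * direction, origin + t_out * direction


def boundary_points(
    gpi: SegmentationMask, frame: StereotacticFrame, contact
) -> GpiBoundaryFix:
    """Extract A, P, M, L, V, D at the active-contact level.

    A and P are the anterior/posterior extremes of the structure in the
    frame's axial plane through the contact; M/L and V/D are boundary
    crossings of the lateral and vertical axis-aligned lines through the
    contact.  Raises :class:`ContactOutsideStructureError` when the
    contact lies outside the structure's extent at that level.
    """
    contact = np.asarray(contact, dtype=float)
    lat_ax, ant_ax, vert_ax = frame.axes
    lo, hi = gpi.world_bounds()
    corners = np.array(
        [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])]
    )
    rel = corners - frame.mcp
    lat_rng = rel @ lat_ax
    ap_rng = rel @ ant_ax
    vert_rng = rel @ vert_ax
    margin = gpi.voxel_diagonal

    c_rel = contact - frame.mcp
    c_lat, c_ap, c_vert = c_rel @ lat_ax, c_rel @ ant_ax, c_rel @ vert_ax
    if not (vert_rng.min() - margin <= c_vert <= vert_rng.max() + margin):
        raise ContactOutsideStructureError(
            "contact lies outside the structure's axial slab"
        )

    # A/P: scan the axial plane on a grid of lateral offsets, keeping the
    # interpolated anterior-most and posterior-most crossings.
    plane_origin = frame.mcp + c_vert * vert_ax
    lat_grid = np.arange(lat_rng.min() - margin, lat_rng.max() + margin, RAY_STEP_MM)
    t = np.arange(ap_rng.min() - margin, ap_rng.max() + margin, RAY_STEP_MM)
    pts = (
        plane_origin[None, None, :]
        + lat_grid[:, None, None] * lat_ax[None, None, :]
        + t[None, :, None] * ant_ax[None, None, :]
    )
    fg = mask_fg = gpi.contains(pts.reshape(-1, 3)).reshape(len(lat_grid), len(t))
    if not mask_fg.any():
        raise ContactOutsideStructureError("empty mask slice at the contact level")
    a_cands: list[tuple[float, float]] = []  # (lateral offset, anterior crossing)
    p_cands: list[tuple[float, float]] = []
    for i in np.nonzero(fg.any(axis=1))[0]:
        for t_in, t_out in _run_crossings(t, fg[i]):
            a_cands.append((float(lat_grid[i]), t_out))
            p_cands.append((float(lat_grid[i]), t_in))
    # The extreme is flat in the lateral direction near the pole of a
    # smooth structure, so a single argmax line is laterally unstable on
    # a voxelized mask.  Average the lateral position over all crossings
    # within half a voxel of the extreme; keep the extreme AP value.
    band = 0.5 * float(gpi.voxel_sizes.min())
    best_a = max(c[1] for c in a_cands)
    lat_a = float(np.mean([c[0] for c in a_cands if c[1] >= best_a - band]))
    A = plane_origin + lat_a * lat_ax + best_a * ant_ax
    best_p = min(c[1] for c in p_cands)
    lat_p = float(np.mean([c[0] for c in p_cands if c[1] <= best_p + band]))
    P = plane_origin + lat_p * lat_ax + best_p * ant_ax

    # M/L: lateral line through the contact in the axial plane.
    ml_origin = plane_origin + c_ap * ant_ax
    e1, e2 = _line_crossings(
        gpi, ml_origin, lat_ax, lat_rng.min() - margin, lat_rng.max() + margin, c_lat
    )
    # medial = closer to the midsagittal plane (smaller |lateral coordinate|)
    if abs((e1 - frame.mcp) @ lat_ax) <= abs((e2 - frame.mcp) @ lat_ax):
        M, L = e1, e2
    else:
        M, L = e2, e1

    # V/D: vertical line through the contact.
    vd_origin = frame.mcp + c_lat * lat_ax + c_ap * ant_ax
    V, D = _line_crossings(
        gpi, vd_origin, vert_ax, vert_rng.min() - margin, vert_rng.max() + margin, c_vert
    )

    return GpiBoundaryFix(A=A, P=P, M=M, L=L, V=V, D=D, contact=contact)


def _projection_parameter(origin: np.ndarray, end: np.ndarray, point: np.ndarray) -> tuple[float, np.ndarray]:
    seg = end - origin
    L2 = float(seg @ seg)
    if L2 < 1e-18:
        raise DegenerateBoundaryError("boundary segment has zero length")
    tau = float((point - origin) @ seg) / L2
    return tau, origin + tau * seg


def indices(fix: GpiBoundaryFix) -> GpiBoundaryFix:
    """Project the contact onto each boundary segment and compute the
    AP-, ML- and VD-indices.

    Each index is the signed fraction of the segment from its first
    endpoint (A, M, V respectively) to the orthogonal projection of the
    contact; 0.5 is the segment midpoint.
    """
    ap, S_ap = _projection_parameter(fix.A, fix.P, fix.contact)
    ml, S_ml = _projection_parameter(fix.M, fix.L, fix.contact)
    vd, S_vd = _projection_parameter(fix.V, fix.D, fix.contact)
    return replace(
        fix, S_ap=S_ap, S_ml=S_ml, S_vd=S_vd,
        ap_index=ap, ml_index=ml, vd_index=vd,
    )


def locate_contact(
    gpi: SegmentationMask, frame: StereotacticFrame, contact
) -> GpiBoundaryFix:
    """Boundary extraction plus index computation in one call."""
    return indices(boundary_points(gpi, frame, contact))


# ---------------------------------------------------------------------------
# contact classification


@dataclass(frozen=True)
class ContactLocation:
    """Anatomical label of a contact plus the distances behind it."""

    label: str
    distance_to_gpi: float          # 0 when inside
    distance_to_gpi_boundary: float  # depth when inside
    distance_to_gpe: float | None
    distance_to_ic: float | None
    reachable_labels: tuple[str, ...]


def _distance_to_voxels(mask: SegmentationMask, point: np.ndarray, which: np.ndarray) -> float:
    """World-mm distance from ``point`` to the union of voxel cubes whose
    indices are the rows of ``which``.  Exact for rigid (rotation+scale)
    affines."""
    if len(which) == 0:
        return np.inf
    inv = np.linalg.inv(mask.affine)
    pv = inv[:3, :3] @ point + inv[:3, 3]
    gap = np.maximum(np.abs(pv[None, :] - which) - 0.5, 0.0)
    return float(np.min(np.linalg.norm(gap * mask.voxel_sizes[None, :], axis=1)))


def _distance_to_mask(mask: SegmentationMask | None, point: np.ndarray) -> float | None:
    if mask is None:
        return None
    return _distance_to_voxels(mask, point, np.argwhere(mask.data).astype(float))


def _depth_inside(mask: SegmentationMask, point: np.ndarray) -> float:
    """Distance from an inside point to the nearest background voxel
    (including the implicit background beyond the array)."""
    bg = np.argwhere(~mask.data).astype(float)
    d = _distance_to_voxels(mask, point, bg)
    # background outside the array bounds
    inv = np.linalg.inv(mask.affine)
    pv = inv[:3, :3] @ point + inv[:3, 3]
    shape = np.array(mask.data.shape, dtype=float)
    edge = np.min(np.concatenate([(pv + 0.5), (shape - 0.5 - pv)]))
    edge_mm = edge * float(mask.voxel_sizes.min())
    return float(min(d, edge_mm))


def classify_contact(
    contact,
    gpi: SegmentationMask,
    gpe: SegmentationMask | None = None,
    ic: SegmentationMask | None = None,
    delta: float = 0.65,
) -> ContactLocation:
    """Assign an anatomical location label to a contact point.

    A contact inside the GPi and at least ``delta`` mm from its boundary
    is labelled ``"GPi"``; a contact within ``delta`` of the GPi-GPe
    interface is ``"GPi/GPe"``; within ``delta`` of the GPi-IC interface,
    ``"IC/GPi"``; otherwise ``"outside"``.  The default ``delta`` of
    0.65 mm is about half the lead diameter, i.e. a contact whose surface
    touches the interface.  Labels involving a structure whose mask was
    not supplied are unreachable; the result records which labels were
    decidable.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    point = np.asarray(contact, dtype=float)
    inside = bool(gpi.contains(point))
    d_gpi = 0.0 if inside else _distance_to_mask(gpi, point)
    depth = _depth_inside(gpi, point) if inside else 0.0
    d_gpe = _distance_to_mask(gpe, point)
    d_ic = _distance_to_mask(ic, point)

    reachable = ["GPi", "outside"]
    if gpe is not None:
        reachable.insert(1, "GPi/GPe")
    if ic is not None:
        reachable.insert(-1, "IC/GPi")

    near_gpi = inside or d_gpi <= delta
    if inside and depth >= delta:
        label = "GPi"
    elif near_gpi and d_gpe is not None and d_gpe <= delta:
        label = "GPi/GPe"
    elif near_gpi and d_ic is not None and d_ic <= delta:
        label = "IC/GPi"
    else:
        label = "outside"
    return ContactLocation(
        label=label,
        distance_to_gpi=float(d_gpi),
        distance_to_gpi_boundary=float(depth),
        distance_to_gpe=d_gpe,
        distance_to_ic=d_ic,
        reachable_labels=tuple(reachable),
    )
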