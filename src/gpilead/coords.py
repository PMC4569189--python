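"""AC-PC based stereotactic coordinate frames.

Functional stereotaxy references every target to the anterior commissure
(AC), posterior commissure (PC) and their midpoint, the midcommissural
point (MCP).  This module builds an orthonormal Cartesian frame with the
MCP as origin from the two commissural landmarks plus a midsagittal
normal, and converts points between scanner (world, mm) coordinates and
stereotactic (LAT, AP, VERT) coordinates.

Conventions
-----------
* The anterior axis points from PC toward AC.
* The lateral axis is the component of the midsagittal normal orthogonal
  to the anterior axis; internally the signed lateral component is
  positive toward the right hemisphere.
* The vertical axis is lateral x anterior, oriented superior.
* Reported LAT values are unsigned magnitudes with the hemisphere carried
  as a separate label, matching how bilateral lead cohorts pool left and
  right leads into a single LAT column.
* VERT is negative inferior to the AC-PC plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "InvalidLandmarksError",
    "StereotacticFrame",
    "StereoCoordinates",
    "build_frame",
    "world_to_stereo",
    "stereo_to_world",
    "read_landmarks",
]

Hemisphere = Literal["left", "right"]

_ORTHO_TOL = 1e-9


class InvalidLandmarksError(ValueError):
    """Raised when AC/PC/midsagittal landmarks cannot define a frame."""


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise InvalidLandmarksError(f"expected a 3D point, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise InvalidLandmarksError("non-finite landmark coordinates")
    return a


@dataclass(frozen=True)
class StereotacticFrame:
    """Orthonormal AC-PC frame with MCP origin.

    Attributes
    ----------
    ac, pc : (3,) float arrays, world mm.
    midsagittal_normal : unit vector defining the left-right direction.
    mcp : (ac + pc) / 2, the frame origin.
    axes : (3, 3) array whose rows are the lateral, anterior and vertical
        unit vectors (in that order).
    """

    ac: np.ndarray
    pc: np.ndarray
    midsagittal_normal: np.ndarray
    mcp: np.ndarray = field(init=False)
    axes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        ac = _as_point(self.ac)
        pc = _as_point(self.pc)
        msn = _as_point(self.midsagittal_normal)
        object.__setattr__(self, "ac", ac)
        object.__setattr__(self, "pc", pc)

        d = ac - pc
        norm_d = float(np.linalg.norm(d))
        if norm_d == 0.0:
            raise InvalidLandmarksError("AC and PC coincide")
        anterior = d / norm_d

        lateral = msn - np.dot(msn, anterior) * anterior
        norm_l = float(np.linalg.norm(lateral))
        if norm_l < 1e-12 * max(1.0, float(np.linalg.norm(msn))):
            raise InvalidLandmarksError(
                "midsagittal normal is parallel to the AC-PC line"
            )
        lateral = lateral / norm_l
        vertical = np.cross(lateral, anterior)
        vertical = vertical / float(np.linalg.norm(vertical))

        object.__setattr__(self, "midsagittal_normal", msn)
        object.__setattr__(self, "mcp", (ac + pc) / 2.0)
        object.__setattr__(self, "axes", np.vstack([lateral, anterior, vertical]))

    @property
    def lateral_axis(self) -> np.ndarray:
        return self.axes[0]

    @property
    def anterior_axis(self) -> np.ndarray:
        return self.axes[1]

    @property
    def vertical_axis(self) -> np.ndarray:
        return self.axes[2]

    @property
    def acpc_length(self) -> float:
        """|AC - PC| in mm; enters the atlas AP rule."""
        return float(np.linalg.norm(self.ac - self.pc))


@dataclass(frozen=True)
class StereoCoordinates:
    """Stereotactic coordinates relative to the MCP.

    ``lat`` is an unsigned lateral magnitude (mm); the side is carried in
    ``hemisphere``.  ``ap`` is positive anterior of the MCP and ``vert``
    negative inferior to the AC-PC plane.
    """

    lat: float
    ap: float
    vert: float
    hemisphere: Hemisphere

    def __post_init__(self) -> None:
        if self.lat < 0:
            raise ValueError("lat must be an unsigned magnitude (>= 0)")
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")

    @property
    def signed_lat(self) -> float:
        """Signed lateral component, positive right."""
        return self.lat if self.hemisphere == "right" else -self.lat

    def as_array(self) -> np.ndarray:
        """(signed_lat, ap, vert) as a vector in frame axes."""
        return np.array([self.signed_lat, self.ap, self.vert], dtype=float)


def build_frame(ac, pc, midsagittal_normal) -> StereotacticFrame:
    """Build the MCP-origin stereotactic frame from landmarks.

    Raises
    ------
    InvalidLandmarksError
        If AC and PC coincide or the midsagittal normal is parallel to
        the AC-PC line.
    """
    return StereotacticFrame(ac=ac, pc=pc, midsagittal_normal=midsagittal_normal)


def world_to_stereo(frame: StereotacticFrame, p) -> StereoCoordinates:
    """Express a world-mm point in (LAT, AP, VERT) relative to the MCP."""
    v = _as_point(p) - frame.mcp
    signed = frame.axes @ v
    hemisphere: Hemisphere = "right" if signed[0] >= 0 else "left"
    return StereoCoordinates(
        lat=abs(float(signed[0])),
        ap=float(signed[1]),
        vert=float(signed[2]),
        hemisphere=hemisphere,
    )


def stereo_to_world(frame: StereotacticFrame, c: StereoCoordinates) -> np.ndarray:
    """Exact inverse of :func:`world_to_stereo`."""
    return frame.mcp + frame.axes.T @ c.as_array()


def read_landmarks(path) -> dict[str, StereotacticFrame]:
    """Read a landmark CSV into per-patient frames.

    Expected columns: patient_id, ac_x, ac_y, ac_z, pc_x, pc_y, pc_z,
    msn_x, msn_y, msn_z (all mm, world).
    """
    df = pd.read_csv(path)
    frames: dict[str, StereotacticFrame] = {}
    for _, row in df.iterrows():
        frames[str(row["patient_id"])] = build_frame(
            [row["ac_x"], row["ac_y"], row["ac_z"]],
            [row["pc_x"], row["pc_y"], row["pc_z"]],
            [row["msn_x"], row["msn_y"], row["msn_z"]],
        )
    return frames
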