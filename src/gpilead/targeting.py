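"""Target planning rules and targeting-error geometry.

Two planning routes are compared for each pallidal lead:

* **indirect (atlas) targeting** — standard coordinates relative to the
  MCP, adapted to the patient's third-ventricle width and AC-PC length:
  LAT 20-22 mm, AP 2-3 mm (2 mm when the AC-PC distance is under 25 mm),
  VERT 1-2 mm below the AC-PC plane;
* **direct targeting** — the target chosen by visualizing the GPi on the
  patient's own MRI.

The targeting error of an implanted lead is evaluated *at the level of
the intended target*: the lead line is intersected with the axial plane
at the target's VERT value and the in-plane error is

    d = sqrt((AP_i - AP_t)^2 + (LAT_i - LAT_t)^2)

with i the intended target and t the lead at that level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coords import StereoCoordinates, StereotacticFrame, stereo_to_world
from .lead import LeadGeometry, LeadObservation, MODEL_3389, lead_direction

__all__ = [
    "InvalidMeasurementsError",
    "NoIntersectionError",
    "AtlasRule",
    "TargetPair",
    "TargetingError",
    "AxisDistances",
    "atlas_target",
    "delta_targets",
    "targeting_error",
    "closest_lead_distance",
]


class InvalidMeasurementsError(ValueError):
    """Ventricle width or AC-PC length is not a positive measurement."""


class NoIntersectionError(ValueError):
    """The lead line does not cross the axial plane of the target."""


@dataclass(frozen=True)
class AtlasRule:
    """Configurable atlas coordinate rules.

    ``lat_*``: LAT is interpolated linearly from ``lat_min`` at
    third-ventricle width <= ``ventricle_floor`` mm to ``lat_max`` at
    >= ``ventricle_ceiling`` mm, clamped outside.  ``ap_short``/``ap_long``
    apply below/at-or-above the ``acpc_threshold``; ``vert`` is the fixed
    vertical coordinate (negative inferior).
    """

    lat_min: float = 20.0
    lat_max: float = 22.0
    ventricle_floor: float = 2.0
    ventricle_ceiling: float = 10.0
    ap_short: float = 2.0
    ap_long: float = 3.0
    acpc_threshold: float = 25.0
    vert: float = -1.5


DEFAULT_ATLAS_RULE = AtlasRule()


@dataclass(frozen=True)
class TargetPair:
    """Atlas and direct targets for one lead."""

    atlas: StereoCoordinates
    direct: StereoCoordinates
    patient_id: str = ""
    hemisphere: str = "right"
    third_ventricle_width: float = float("nan")
    acpc_length: float = float("nan")

    def __post_init__(self) -> None:
        if self.atlas.hemisphere != self.direct.hemisphere:
            raise ValueError("atlas and direct targets must share a hemisphere")


@dataclass(frozen=True)
class TargetingError:
    """In-plane lead placement error at the intended target's level."""

    d_ap: float
    d_lat: float
    d_euclid: float
    evaluated_at_vert: float


@dataclass(frozen=True)
class AxisDistances:
    """Per-axis absolute distances plus the Euclidean distance."""

    d_lat: float
    d_ap: float
    d_vert: float
    d_euclid: float


def atlas_target(
    third_ventricle_width: float,
    acpc_length: float,
    hemisphere: str = "right",
    rule: AtlasRule = DEFAULT_ATLAS_RULE,
) -> StereoCoordinates:
    """Standard atlas coordinates adapted to the patient's measurements.

    Raises :class:`InvalidMeasurementsError` for non-positive inputs.
    """
    if third_ventricle_width <= 0 or acpc_length <= 0:
        raise InvalidMeasurementsError(
            "ventricle width and AC-PC length must be positive"
        )
    frac = (third_ventricle_width - rule.ventricle_floor) / (
        rule.ventricle_ceiling - rule.ventricle_floor
    )
    frac = min(max(frac, 0.0), 1.0)
    lat = rule.lat_min + frac * (rule.lat_max - rule.lat_min)
    ap = rule.ap_short if acpc_length < rule.acpc_threshold else rule.ap_long
    return StereoCoordinates(lat=lat, ap=ap, vert=rule.vert, hemisphere=hemisphere)


def delta_targets(pair: TargetPair) -> AxisDistances:
    """Per-axis absolute differences between atlas and direct targets.

    LAT is compared as an unsigned magnitude (both targets lie in the
    same hemisphere).
    """
    d_lat = abs(pair.atlas.lat - pair.direct.lat)
    d_ap = abs(pair.atlas.ap - pair.direct.ap)
    d_vert = abs(pair.atlas.vert - pair.direct.vert)
    return AxisDistances(
        d_lat=d_lat, d_ap=d_ap, d_vert=d_vert,
        d_euclid=float(np.sqrt(d_lat**2 + d_ap**2 + d_vert**2)),
    )


def _lead_frame_coords(lead: LeadObservation, frame: StereotacticFrame):
    """Tip and direction of the lead in frame axes (signed lateral)."""
    tip = frame.axes @ (lead.tip - frame.mcp)
    u = frame.axes @ lead_direction(lead)
    return tip, u


def targeting_error(
    intended: StereoCoordinates, lead: LeadObservation, frame: StereotacticFrame
) -> TargetingError:
    """Distance between the intended target and the lead at the same VERT.

    The lead line is intersected with the axial plane at the target's
    VERT; the AP and LAT differences there give the in-plane error
    ``d = sqrt(dAP^2 + dLAT^2)``.  Raises :class:`NoIntersectionError`
    when the lead runs parallel to the axial plane.
    """
    tip, u = _lead_frame_coords(lead, frame)
    if abs(u[2]) < 1e-12:
        raise NoIntersectionError("lead is parallel to the axial plane")
    k = (intended.vert - tip[2]) / u[2]
    at_level = tip + k * u
    d_lat = abs(at_level[0] - intended.signed_lat)
    d_ap = abs(at_level[1] - intended.ap)
    return TargetingError(
        d_ap=float(d_ap),
        d_lat=float(d_lat),
        d_euclid=float(np.hypot(d_ap, d_lat)),
        evaluated_at_vert=float(intended.vert),
    )


def closest_lead_distance(
    target: StereoCoordinates,
    lead: LeadObservation,
    frame: StereotacticFrame,
    geom: LeadGeometry = MODEL_3389,
) -> AxisDistances:
    """Per-axis distances from a target to the closest point of the
    contact-bearing segment of the lead.

    The closest point minimizes the Euclidean distance over the segment
    spanning all four contacts (not just the contact centers); the
    per-axis values are the absolute frame-axis differences at that
    point.
    """
    tip, u = _lead_frame_coords(lead, frame)
    tgt = np.array([target.signed_lat, target.ap, target.vert])
    k_lo, k_hi = geom.span
    k = float(np.clip((tgt - tip) @ u, k_lo, k_hi))
    closest = tip + k * u
    diff = np.abs(closest - tgt)
    return AxisDistances(
        d_lat=float(diff[0]),
        d_ap=float(diff[1]),
        d_vert=float(diff[2]),
        d_euclid=float(np.linalg.norm(closest - tgt)),
    )
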