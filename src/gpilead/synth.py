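"""Synthetic GPi-DBS cohorts with known ground truth.

No per-lead coordinates are published for the cohort the analyses were
designed around, so every pipeline stage is exercised on simulated data
whose *distribution* matches the printed cohort summaries:

* direct (MRI-visualized) targets are drawn per disease group from the
  reported means/SDs (dystonia LAT 19.33 +/- 0.90, AP 2.48 +/- 0.81,
  VERT -2.32 +/- 1.36; PD LAT 20.67 +/- 1.69, AP 2.46 +/- 0.64,
  VERT -2.89 +/- 1.18);
* atlas targets follow the standard-coordinate rules applied to sampled
  third-ventricle widths (wider in PD) and AC-PC lengths;
* leads are implanted along oblique trajectories through the direct
  target, displaced in the axial plane by isotropic Gaussian noise of
  scale ``implant_sigma`` — so the in-plane targeting error is Rayleigh
  with mean ``sigma * sqrt(pi/2)`` and sigma = 0 reproduces the plan
  exactly;
* each pallidum is an ellipsoid with an anterior-lateral yaw, posed so
  that typical direct targets fall in its posteroventral portion,
  voxelized at 1 mm isotropic resolution together with an abutting GPe
  shell and a medial internal-capsule slab.

The analytic ellipsoid parameters travel with every mask, giving a
closed-form oracle for boundary points and indices.  The generator is a
model of the *geometry and bookkeeping* of such a cohort, not of
pallidal morphology or image contrast.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .coords import StereotacticFrame, StereoCoordinates, build_frame, world_to_stereo
from .gpi import GpiBoundaryFix, IndexTriple, SegmentationMask, boundary_points, indices
from .lead import LeadGeometry, LeadObservation, MODEL_3389, contact_centers
from .targeting import atlas_target

__all__ = [
    "SimulationConfig",
    "EllipsoidShape",
    "StructureMasks",
    "LeadTruth",
    "CohortTables",
    "gen_gpi_mask",
    "gen_structure_masks",
    "gen_cohort",
    "analytic_boundary_points",
    "analytic_indices",
    "write_cohort",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Moments are (mean, SD) pairs; coordinates are stereotactic
    (LAT, AP, VERT) mm relative to the MCP with LAT unsigned.
    """

    n_patients: int = 13
    n_pd: int = 6  # remainder are dystonia patients
    seed: int = 0

    # direct-target moments per disease group: ((lat, ap, vert), (sd...))
    direct_moments: dict = field(
        default_factory=lambda: {
            "dystonia": ((19.33, 2.48, -2.32), (0.90, 0.81, 1.36)),
            "PD": ((20.67, 2.46, -2.89), (1.69, 0.64, 1.18)),
        }
    )
    ventricle_width_moments: dict = field(
        default_factory=lambda: {"dystonia": (4.0, 1.0), "PD": (7.0, 1.0)}
    )
    acpc_length_moments: tuple = (25.0, 1.5)
    age_moments: dict = field(
        default_factory=lambda: {"dystonia": (47.0, 22.0), "PD": (70.0, 4.0)}
    )

    #: per-axis SD (mm) of the in-plane lead displacement at the target
    #: level; 0.85 mm gives a mean in-plane error of ~1.07 mm.
    implant_sigma: float = 0.85
    #: SD (mm) of the insertion-depth jitter along the lead axis.
    depth_sigma: float = 0.5
    #: mean/SD (deg) of the lateral and anterior trajectory tilts.
    lateral_tilt: tuple = (10.0, 3.0)
    anterior_tilt: tuple = (25.0, 5.0)

    # GPi shape: semi-axes along (LAT, AP, VERT), pose relative to MCP.
    gpi_semi_axes: tuple = (6.0, 10.0, 5.0)
    gpi_center: tuple = (17.5, 4.2, -1.4)  # (LAT, AP, VERT), LAT mirrored left
    gpi_yaw_deg: float = 20.0  # anterior-lateral tilt about the vertical axis
    shape_jitter: float = 0.4  # SD (mm) of per-patient center/semi-axis jitter
    voxel_size: float = 1.0

    geometry: LeadGeometry = MODEL_3389

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "geometry" in raw:
            raw["geometry"] = LeadGeometry(**raw["geometry"])
        for key in ("acpc_length_moments", "lateral_tilt", "anterior_tilt",
                    "gpi_semi_axes", "gpi_center"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "direct_moments" in raw:
            raw["direct_moments"] = {
                k: (tuple(v[0]), tuple(v[1])) for k, v in raw["direct_moments"].items()
            }
        for key in ("ventricle_width_moments", "age_moments"):
            if key in raw:
                raw[key] = {k: tuple(v) for k, v in raw[key].items()}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# analytic shapes


@dataclass(frozen=True)
class EllipsoidShape:
    """Ellipsoid with semi-axes along frame (LAT, AP, VERT) directions
    after a yaw rotation about the vertical axis.

    ``center`` is in world mm; ``frame`` carries the axes the pose is
    expressed in.  A point x is inside iff |diag(1/a) R^T F (x - c)| <= 1
    where F maps world offsets to frame components.
    """

    center: np.ndarray
    semi_axes: np.ndarray  # (a_lat, a_ap, a_vert)
    yaw_deg: float
    frame: StereotacticFrame

    def _rot2(self) -> np.ndarray:
        th = np.deg2rad(self.yaw_deg)
        return np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])

    def _to_frame(self, pts: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(pts) - self.center) @ self.frame.axes.T

    def quadratic(self, pts) -> np.ndarray:
        """Ellipsoid quadratic form; <= 1 inside, 1 on the surface."""
        rel = self._to_frame(np.asarray(pts, dtype=float))
        R2 = self._rot2()
        xy = rel[:, :2] @ R2  # = R2^T applied to row vectors
        a = self.semi_axes
        return (xy[:, 0] / a[0]) ** 2 + (xy[:, 1] / a[1]) ** 2 + (rel[:, 2] / a[2]) ** 2

    def contains(self, pts) -> np.ndarray:
        return self.quadratic(pts) <= 1.0

    def line_intersections(self, origin, direction) -> tuple[np.ndarray, np.ndarray]:
        """Entry and exit points of a world line with the ellipsoid."""
        origin = np.asarray(origin, dtype=float)
        direction = np.asarray(direction, dtype=float)
        R2 = self._rot2()
        a = self.semi_axes

        def to_unit_sphere(v_frame):
            xy = v_frame[:2] @ R2
            return np.array([xy[0] / a[0], xy[1] / a[1], v_frame[2] / a[2]])

        o = to_unit_sphere(self._to_frame(origin)[0])
        d = to_unit_sphere(direction @ self.frame.axes.T)
        A = d @ d
        B = 2 * o @ d
        C = o @ o - 1.0
        disc = B * B - 4 * A * C
        if disc <= 0:
            raise ValueError("line does not cross the ellipsoid")
        t1 = (-B - np.sqrt(disc)) / (2 * A)
        t2 = (-B + np.sqrt(disc)) / (2 * A)
        return origin + t1 * direction, origin + t2 * direction

    def axial_support(self, vert_level: float, sign: float) -> np.ndarray:
        """Extreme point along +/- the anterior axis of the elliptical
        cross-section at frame height ``vert_level`` (frame coords)."""
        dz = vert_level - ((self.center - self.frame.mcp) @ self.frame.axes.T)[2]
        a = self.semi_axes
        k2 = 1.0 - (dz / a[2]) ** 2
        if k2 <= 0:
            raise ValueError("plane does not cross the ellipsoid")
        R2 = self._rot2()
        Q = R2 @ np.diag([a[0] ** 2, a[1] ** 2]) @ R2.T * k2
        e = np.array([0.0, sign])  # anterior direction in (lat, ap) components
        y = Q @ e / np.sqrt(e @ Q @ e)
        center_frame = (self.center - self.frame.mcp) @ self.frame.axes.T
        p_frame = np.array([center_frame[0] + y[0], center_frame[1] + y[1], vert_level])
        return self.frame.mcp + p_frame @ self.frame.axes


def analytic_boundary_points(
    shape: EllipsoidShape, frame: StereotacticFrame, contact
) -> GpiBoundaryFix:
    """Closed-form A/P/M/L/V/D for an ellipsoidal structure.

    Independent oracle for the mask-based boundary extraction: A and P
    are support points of the axial cross-section, M/L and V/D come from
    exact line-ellipsoid intersections.
    """
    contact = np.asarray(contact, dtype=float)
    rel = (contact - frame.mcp) @ frame.axes.T
    lat_ax, ant_ax, vert_ax = frame.axes
    A = shape.axial_support(rel[2], +1.0)
    P = shape.axial_support(rel[2], -1.0)
    e1, e2 = shape.line_intersections(contact, lat_ax)
    if abs((e1 - frame.mcp) @ lat_ax) <= abs((e2 - frame.mcp) @ lat_ax):
        M, L = e1, e2
    else:
        M, L = e2, e1
    V, D = shape.line_intersections(contact, vert_ax)
    if (V - frame.mcp) @ vert_ax > (D - frame.mcp) @ vert_ax:
        V, D = D, V
    return GpiBoundaryFix(A=A, P=P, M=M, L=L, V=V, D=D, contact=contact)


def analytic_indices(
    shape: EllipsoidShape, frame: StereotacticFrame, contact
) -> IndexTriple:
    fix = indices(analytic_boundary_points(shape, frame, contact))
    return IndexTriple(fix.ap_index, fix.ml_index, fix.vd_index)


# ---------------------------------------------------------------------------
# mask generation


@dataclass(frozen=True)
class StructureMasks:
    gpi: SegmentationMask
    gpe: SegmentationMask
    ic: SegmentationMask
    shape: EllipsoidShape


def _sample_shape(
    config: SimulationConfig, frame: StereotacticFrame, hemisphere: str,
    rng: np.random.Generator,
) -> EllipsoidShape:
    side = 1.0 if hemisphere == "right" else -1.0
    center_stereo = np.array(config.gpi_center, dtype=float)
    center_stereo[0] *= side
    center_stereo += rng.normal(0.0, config.shape_jitter, size=3)
    semi = np.asarray(config.gpi_semi_axes, dtype=float) * np.exp(
        rng.normal(0.0, config.shape_jitter / 10.0, size=3)
    )
    if np.any(semi <= 0):
        raise ValueError("degenerate ellipsoid semi-axes")
    yaw = side * rng.normal(config.gpi_yaw_deg, 3.0)
    center_world = frame.mcp + center_stereo @ frame.axes
    return EllipsoidShape(
        center=center_world, semi_axes=semi, yaw_deg=float(yaw), frame=frame
    )


def gen_structure_masks(
    config: SimulationConfig, shape: EllipsoidShape, hemisphere: str
) -> StructureMasks:
    """Voxelize the GPi ellipsoid plus an abutting GPe shell and a
    medial internal-capsule slab at ``config.voxel_size`` resolution."""
    frame = shape.frame
    vs = float(config.voxel_size)
    if np.any(np.asarray(shape.semi_axes) <= 0):
        raise ValueError("degenerate ellipsoid semi-axes")

    margin = 7.0
    half = np.max(shape.semi_axes) + margin
    lo = shape.center - half
    n = int(np.ceil(2 * half / vs))
    affine = np.eye(4)
    affine[:3, :3] *= vs
    affine[:3, 3] = lo
    ii = np.arange(n)
    grid = np.stack(np.meshgrid(ii, ii, ii, indexing="ij"), axis=-1).reshape(-1, 3)
    centers = grid * vs + lo[None, :]

    inside_gpi = shape.contains(centers)

    # GPe: larger co-posed ellipsoid displaced laterally/dorsally, minus GPi.
    side = 1.0 if hemisphere == "right" else -1.0
    gpe_center = shape.center + (np.array([side * 2.5, 0.0, 1.0]) @ frame.axes)
    gpe_shape = EllipsoidShape(
        center=gpe_center,
        semi_axes=np.asarray(shape.semi_axes) * 1.45,
        yaw_deg=shape.yaw_deg,
        frame=frame,
    )
    inside_gpe = gpe_shape.contains(centers) & ~inside_gpi

    # IC: slab abutting the GPi's medial extent.
    rel = (centers - frame.mcp) @ frame.axes.T
    lat = rel[:, 0] * side  # positive toward the implanted side
    gpi_rel = (shape.center - frame.mcp) @ frame.axes.T
    medial_edge = gpi_rel[0] * side - float(np.max(shape.semi_axes[:2]))
    inside_ic = (lat < medial_edge) & (lat >= medial_edge - 3.0) & ~inside_gpi & ~inside_gpe

    shp = (n, n, n)
    return StructureMasks(
        gpi=SegmentationMask(inside_gpi.reshape(shp), affine, label="GPi"),
        gpe=SegmentationMask(inside_gpe.reshape(shp), affine, label="GPe"),
        ic=SegmentationMask(inside_ic.reshape(shp), affine, label="IC"),
        shape=shape,
    )


def gen_gpi_mask(
    config: SimulationConfig, patient: int, hemisphere: str
) -> tuple[SegmentationMask, EllipsoidShape]:
    """GPi mask plus its analytic shape record for one patient side.

    Reproducible in isolation: the same deterministic per-patient
    substream of the cohort seed is replayed, so the mask matches the
    one a full :func:`gen_cohort` run assigns to this patient.
    """
    pat = _gen_patient(config, patient)
    shape = pat["shapes"][hemisphere]
    masks = gen_structure_masks(config, shape, hemisphere)
    return masks.gpi, shape


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class LeadTruth:
    """Ground truth for one synthetic lead."""

    patient_id: str
    hemisphere: str
    contact_centers: np.ndarray  # (4, 3) world mm
    active_index: int
    active_point: np.ndarray
    offset_lat: float  # implantation displacement at the target level
    offset_ap: float
    shape: EllipsoidShape
    analytic: IndexTriple
    mask_based: IndexTriple | None = None


@dataclass
class CohortTables:
    """Synthetic cohort: per-lead table, landmarks, truth and masks."""

    leads: pd.DataFrame
    landmarks: pd.DataFrame
    truth: list[LeadTruth]
    masks: dict[tuple[str, str], StructureMasks]
    config: SimulationConfig


def _patient_rng(seed: int, patient: int, hemisphere: str = "") -> np.random.Generator:
    key = [seed, patient] + ([0] if hemisphere in ("", "left") else [1])
    return np.random.default_rng(key)


#: acceptance bound on the ellipsoid quadratic at the active contact;
#: leads whose contact would fall beyond it pull the anatomy with them.
_Q_MAX = 0.8
_Q_TARGET = 0.6


def _gen_patient(config: SimulationConfig, p: int) -> dict:
    """All deterministic draws for one patient (both hemispheres).

    The anatomy is coupled to the plan: when a sampled active contact
    would fall too close to (or beyond) the sampled ellipsoid surface,
    the ellipsoid is translated along the contact-center axis until the
    contact sits at a fixed interior depth.  This mirrors the clinical
    situation — direct targets are chosen inside the visualized
    structure — and leaves the configured target moments untouched.
    """
    pid = f"S{p + 1:03d}"
    prng = _patient_rng(config.seed, p)
    group = "PD" if p < config.n_pd else "dystonia"
    age_mu, age_sd = config.age_moments[group]
    age = float(np.clip(prng.normal(age_mu, age_sd), 5, 90))
    sex = "m" if prng.random() < 0.5 else "f"
    acpc = float(np.clip(prng.normal(*config.acpc_length_moments), 20.0, 30.0))
    vw_mu, vw_sd = config.ventricle_width_moments[group]
    ventricle = float(np.clip(prng.normal(vw_mu, vw_sd), 1.0, 12.0))
    frame = build_frame([0, acpc / 2, 0], [0, -acpc / 2, 0], [1, 0, 0])

    geom = config.geometry
    landmark_row = dict(
        patient_id=pid,
        ac_x=0.0, ac_y=acpc / 2, ac_z=0.0,
        pc_x=0.0, pc_y=-acpc / 2, pc_z=0.0,
        msn_x=1.0, msn_y=0.0, msn_z=0.0,
    )
    shapes: dict[str, EllipsoidShape] = {}
    lead_rows = []
    truths = []

    for hemisphere in ("left", "right"):
        rng = _patient_rng(config.seed, p, hemisphere)
        shape = _sample_shape(config, frame, hemisphere, rng.spawn(1)[0])
        side = 1.0 if hemisphere == "right" else -1.0
        mu, sd = config.direct_moments[group]
        direct = StereoCoordinates(
            lat=float(np.clip(rng.normal(mu[0], sd[0]), 12.0, 28.0)),
            ap=float(rng.normal(mu[1], sd[1])),
            vert=float(rng.normal(mu[2], sd[2])),
            hemisphere=hemisphere,
        )
        atlas = atlas_target(ventricle, acpc, hemisphere=hemisphere)
        target_world = frame.mcp + direct.as_array() @ frame.axes

        alpha = np.deg2rad(rng.normal(*config.lateral_tilt))
        beta = np.deg2rad(rng.normal(*config.anterior_tilt))
        u_frame = np.array([side * np.tan(alpha), np.tan(beta), 1.0])
        u_frame /= np.linalg.norm(u_frame)
        u = u_frame @ frame.axes  # world, pointing dorsally

        eps_lat = float(rng.normal(0.0, config.implant_sigma))
        eps_ap = float(rng.normal(0.0, config.implant_sigma))
        depth = float(rng.normal(0.0, config.depth_sigma))
        shift = (np.array([side * eps_lat, eps_ap, 0.0])) @ frame.axes
        # tip placed so contact 1 sits at the target level, then
        # displaced in-plane by the implantation error and jittered
        # in depth along the lead axis.
        tip = target_world + shift - geom.contact_center_offset(1) * u + depth * u
        shaft = tip + 25.0 * u

        obs = LeadObservation(
            tip=tip, shaft=shaft, hemisphere=hemisphere, patient_id=pid
        )
        cset = contact_centers(obs, geom)
        d2 = np.linalg.norm(cset.centers - target_world[None, :], axis=1)
        active_index = int(np.argmin(d2))
        active_point = cset.centers[active_index]
        block = 0 if hemisphere == "left" else 8
        active_config = f"c+ {block + active_index}-"

        q = float(shape.quadratic(active_point)[0])
        if q > _Q_MAX:
            # translate the anatomy so the contact sits at depth _Q_TARGET
            v = active_point - shape.center
            shape = dataclasses.replace(
                shape, center=shape.center + v * (1.0 - np.sqrt(_Q_TARGET / q))
            )
        shapes[hemisphere] = shape

        truths.append(
            LeadTruth(
                patient_id=pid,
                hemisphere=hemisphere,
                contact_centers=cset.centers,
                active_index=active_index,
                active_point=active_point,
                offset_lat=eps_lat,
                offset_ap=eps_ap,
                shape=shape,
                analytic=analytic_indices(shape, frame, active_point),
                mask_based=None,
            )
        )
        active_stereo = world_to_stereo(frame, active_point)
        tip_stereo = world_to_stereo(frame, tip)
        lead_rows.append(
            dict(
                patient_id=pid,
                hemisphere=hemisphere,
                age=age,
                sex=sex,
                disease_group=group,
                acpc_length=acpc,
                third_ventricle_width=ventricle,
                atlas_lat=atlas.lat, atlas_ap=atlas.ap, atlas_vert=atlas.vert,
                direct_lat=direct.lat, direct_ap=direct.ap, direct_vert=direct.vert,
                tip_x=tip[0], tip_y=tip[1], tip_z=tip[2],
                shaft_x=shaft[0], shaft_y=shaft[1], shaft_z=shaft[2],
                active_config=active_config,
                tip_lat=tip_stereo.lat, tip_ap=tip_stereo.ap, tip_vert=tip_stereo.vert,
                active_lat=active_stereo.lat,
                active_ap=active_stereo.ap,
                active_vert=active_stereo.vert,
            )
        )

    return dict(
        pid=pid,
        frame=frame,
        landmark_row=landmark_row,
        lead_rows=lead_rows,
        truths=truths,
        shapes=shapes,
    )


def gen_cohort(config: SimulationConfig, with_masks: bool = False) -> CohortTables:
    """Simulate a full bilateral cohort.

    With ``with_masks=True`` each patient side also gets voxelized
    GPi/GPe/IC masks and the mask-based ground-truth indices of the true
    active contact (what a perfect lead localization should recover).
    """
    lead_rows = []
    lm_rows = []
    truths: list[LeadTruth] = []
    masks: dict[tuple[str, str], StructureMasks] = {}

    for p in range(config.n_patients):
        pat = _gen_patient(config, p)
        lm_rows.append(pat["landmark_row"])
        lead_rows.extend(pat["lead_rows"])
        for truth in pat["truths"]:
            if with_masks:
                hemisphere = truth.hemisphere
                mset = gen_structure_masks(config, truth.shape, hemisphere)
                masks[(pat["pid"], hemisphere)] = mset
                fix = indices(
                    boundary_points(mset.gpi, pat["frame"], truth.active_point)
                )
                truth = dataclasses.replace(
                    truth,
                    mask_based=IndexTriple(fix.ap_index, fix.ml_index, fix.vd_index),
                )
            truths.append(truth)

    return CohortTables(
        leads=pd.DataFrame(lead_rows),
        landmarks=pd.DataFrame(lm_rows),
        truth=truths,
        masks=masks,
        config=config,
    )


def write_cohort(tables: CohortTables, outdir) -> None:
    """Write cohort CSVs, NIfTI masks and a ground-truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tables.leads.to_csv(out / "leads.csv", index=False)
    tables.landmarks.to_csv(out / "landmarks.csv", index=False)
    for (pid, hemi), mset in tables.masks.items():
        for label, mask in (("gpi", mset.gpi), ("gpe", mset.gpe), ("ic", mset.ic)):
            mask.to_nifti(out / f"{pid}_{hemi}_{label}.nii.gz")
    truth = [
        dict(
            patient_id=t.patient_id,
            hemisphere=t.hemisphere,
            contact_centers=t.contact_centers.tolist(),
            active_index=t.active_index,
            active_point=t.active_point.tolist(),
            offset_lat=t.offset_lat,
            offset_ap=t.offset_ap,
            semi_axes=np.asarray(t.shape.semi_axes).tolist(),
            center=np.asarray(t.shape.center).tolist(),
            yaw_deg=t.shape.yaw_deg,
            analytic_indices=list(t.analytic),
            mask_indices=list(t.mask_based) if t.mask_based else None,
        )
        for t in tables.truth
    ]
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
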