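"""End-to-end cohort pipeline: localize -> index -> target-compare -> summarize.

Thin orchestration over the library modules.  A run takes either a
synthetic-cohort configuration or on-disk inputs (landmark CSV, lead
CSV, NIfTI masks), executes the four analysis stages, and writes CSV/
JSON outputs plus a run manifest (config snapshot, input hashes, seed,
version, per-stage timings) so identical manifests imply identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coords import StereoCoordinates, build_frame, read_landmarks, world_to_stereo
from .gpi import SegmentationMask, classify_contact, indices, boundary_points
from .lead import LeadObservation, MODEL_3389, active_contact_point, contact_centers
from .stats import compare_groups, describe, location_label_summary
from .synth import SimulationConfig, gen_cohort, write_cohort
from .targeting import TargetPair, closest_lead_distance, delta_targets, targeting_error

__all__ = ["PipelineError", "PipelineConfig", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending record."""

    def __init__(self, stage: str, record: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on record {record!r}: {cause}")
        self.stage = stage
        self.record = record
        self.cause = cause


@dataclass
class PipelineConfig:
    """Inputs for one pipeline run.

    Set ``simulate`` to generate a synthetic cohort; otherwise
    ``landmarks_csv``/``leads_csv`` (and optionally ``masks_dir`` with
    ``<patient>_<hemisphere>_<structure>.nii.gz`` files) are read.
    """

    output_dir: str | Path = "pipeline_out"
    simulate: SimulationConfig | None = None
    landmarks_csv: str | Path | None = None
    leads_csv: str | Path | None = None
    masks_dir: str | Path | None = None
    delta: float = 0.65  # mm, interface proximity for contact labels


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _load_masks(masks_dir: Path, pid: str, hemi: str) -> dict[str, SegmentationMask]:
    out = {}
    for structure in ("gpi", "gpe", "ic"):
        for suffix in (".nii.gz", ".nii"):
            p = masks_dir / f"{pid}_{hemi}_{structure}{suffix}"
            if p.exists():
                out[structure] = SegmentationMask.from_nifti(p, label=structure.upper())
                break
    return out


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages and return the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    input_hashes: dict[str, str] = {}

    # -- stage: simulate / load ------------------------------------------
    t0 = time.perf_counter()
    stage = "load"
    masks: dict[tuple[str, str], dict[str, SegmentationMask]] = {}
    if config.simulate is not None:
        stage = "simulate"
        cohort = gen_cohort(config.simulate, with_masks=True)
        write_cohort(
            dataclasses.replace(cohort, masks={}), out / "inputs"
        )  # CSVs only; masks stay in memory
        frames = {
            str(r["patient_id"]): build_frame(
                [r["ac_x"], r["ac_y"], r["ac_z"]],
                [r["pc_x"], r["pc_y"], r["pc_z"]],
                [r["msn_x"], r["msn_y"], r["msn_z"]],
            )
            for _, r in cohort.landmarks.iterrows()
        }
        lead_rows = cohort.leads
        for (pid, hemi), mset in cohort.masks.items():
            masks[(pid, hemi)] = {"gpi": mset.gpi, "gpe": mset.gpe, "ic": mset.ic}
    else:
        if config.landmarks_csv is None or config.leads_csv is None:
            raise ValueError("need landmarks_csv and leads_csv when not simulating")
        frames = read_landmarks(config.landmarks_csv)
        lead_rows = pd.read_csv(config.leads_csv)
        input_hashes["landmarks_csv"] = _hash_file(Path(config.landmarks_csv))
        input_hashes["leads_csv"] = _hash_file(Path(config.leads_csv))
        if config.masks_dir is not None:
            mdir = Path(config.masks_dir)
            for _, r in lead_rows.iterrows():
                key = (str(r["patient_id"]), str(r["hemisphere"]))
                if key not in masks:
                    found = _load_masks(mdir, *key)
                    if found:
                        masks[key] = found
    timings[stage] = time.perf_counter() - t0

    # -- stage: localize --------------------------------------------------
    t0 = time.perf_counter()
    localized = []
    for _, r in lead_rows.iterrows():
        rid = f"{r['patient_id']}/{r['hemisphere']}"
        try:
            frame = frames[str(r["patient_id"])]
            obs = LeadObservation(
                tip=[r["tip_x"], r["tip_y"], r["tip_z"]],
                shaft=[r["shaft_x"], r["shaft_y"], r["shaft_z"]],
                hemisphere=r["hemisphere"],
                patient_id=str(r["patient_id"]),
            )
            cset = active_contact_point(
                contact_centers(obs, MODEL_3389), str(r["active_config"])
            )
            stereo = world_to_stereo(frame, cset.active_point)
            tip_stereo = world_to_stereo(frame, obs.tip)
            localized.append(
                dict(
                    patient_id=r["patient_id"],
                    hemisphere=r["hemisphere"],
                    active_lat=stereo.lat, active_ap=stereo.ap, active_vert=stereo.vert,
                    tip_lat=tip_stereo.lat, tip_ap=tip_stereo.ap, tip_vert=tip_stereo.vert,
                    _obs=obs, _cset=cset, _frame=frame,
                )
            )
        except Exception as e:  # noqa: BLE001 - reported with stage context
            raise PipelineError("localize", rid, e) from e
    timings["localize"] = time.perf_counter() - t0

    # -- stage: index -----------------------------------------------------
    t0 = time.perf_counter()
    index_rows = []
    for row in localized:
        key = (str(row["patient_id"]), str(row["hemisphere"]))
        if key not in masks or "gpi" not in masks[key]:
            continue
        rid = "/".join(key)
        try:
            mset = masks[key]
            fix = indices(
                boundary_points(mset["gpi"], row["_frame"], row["_cset"].active_point)
            )
            loc = classify_contact(
                row["_cset"].active_point, mset["gpi"],
                gpe=mset.get("gpe"), ic=mset.get("ic"), delta=config.delta,
            )
            rec = dict(
                patient_id=key[0], hemisphere=key[1],
                ap_index=fix.ap_index, ml_index=fix.ml_index, vd_index=fix.vd_index,
                location_label=loc.label,
            )
            for name in "APMLVD":
                pt = getattr(fix, name)
                rec.update({f"{name}_x": pt[0], f"{name}_y": pt[1], f"{name}_z": pt[2]})
            index_rows.append(rec)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("index", rid, e) from e
    timings["index"] = time.perf_counter() - t0

    # -- stage: target-compare -------------------------------------------
    t0 = time.perf_counter()
    target_rows = []
    has_targets = {"atlas_lat", "direct_lat"} <= set(lead_rows.columns)
    if has_targets:
        for row, (_, r) in zip(localized, lead_rows.iterrows()):
            rid = f"{r['patient_id']}/{r['hemisphere']}"
            try:
                hemi = str(r["hemisphere"])
                atlas = StereoCoordinates(
                    r["atlas_lat"], r["atlas_ap"], r["atlas_vert"], hemisphere=hemi
                )
                direct = StereoCoordinates(
                    r["direct_lat"], r["direct_ap"], r["direct_vert"], hemisphere=hemi
                )
                pair = TargetPair(atlas=atlas, direct=direct, hemisphere=hemi)
                dt = delta_targets(pair)
                err = targeting_error(direct, row["_obs"], row["_frame"])
                close_d = closest_lead_distance(direct, row["_obs"], row["_frame"])
                close_a = closest_lead_distance(atlas, row["_obs"], row["_frame"])
                target_rows.append(
                    dict(
                        patient_id=r["patient_id"], hemisphere=hemi,
                        delta_lat=dt.d_lat, delta_ap=dt.d_ap,
                        delta_vert=dt.d_vert, delta_euclid=dt.d_euclid,
                        error_lat=err.d_lat, error_ap=err.d_ap, error_d=err.d_euclid,
                        closest_direct_lat=close_d.d_lat,
                        closest_direct_ap=close_d.d_ap,
                        closest_direct_vert=close_d.d_vert,
                        closest_direct_euclid=close_d.d_euclid,
                        closest_atlas_lat=close_a.d_lat,
                        closest_atlas_ap=close_a.d_ap,
                        closest_atlas_vert=close_a.d_vert,
                        closest_atlas_euclid=close_a.d_euclid,
                    )
                )
            except Exception as e:  # noqa: BLE001
                raise PipelineError("target-compare", rid, e) from e
    timings["target-compare"] = time.perf_counter() - t0

    # -- stage: summarize -------------------------------------------------
    t0 = time.perf_counter()
    loc_df = pd.DataFrame([{k: v for k, v in d.items() if not k.startswith("_")} for d in localized])
    loc_df.to_csv(out / "leads_localized.csv", index=False)
    summary: dict = {"n_leads": len(loc_df)}
    if index_rows:
        idx_df = pd.DataFrame(index_rows)
        idx_df.to_csv(out / "contact_indices.csv", index=False)
        summary["mean_indices"] = {
            k: float(idx_df[k].mean()) for k in ("ap_index", "ml_index", "vd_index")
        }
        summary["location_labels"] = location_label_summary(
            idx_df, "location_label"
        ).to_dict("records")
    if target_rows:
        tgt_df = pd.DataFrame(target_rows)
        tgt_df.to_csv(out / "target_comparison.csv", index=False)
        summary["mean_targeting_error"] = float(tgt_df["error_d"].mean())
        summary["mean_delta_euclid"] = float(tgt_df["delta_euclid"].mean())
    if has_targets and "disease_group" in lead_rows.columns:
        merged = lead_rows
        summary["direct_target_by_group"] = describe(
            merged, "direct_lat", group_by="disease_group"
        ).to_dict("records")
        cmp = compare_groups(merged, "direct_lat", "disease_group")
        summary["direct_lat_group_test"] = {
            "groups": cmp.groups, "p_value": cmp.p_value, "test": cmp.test,
        }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    timings["summarize"] = time.perf_counter() - t0

    manifest = {
        "tool": "gpilead",
        "version": __version__,
        "seed": config.simulate.seed if config.simulate is not None else None,
        "config": {
            "delta": config.delta,
            "simulate": dataclasses.asdict(config.simulate)
            if config.simulate is not None
            else None,
        },
        "input_hashes": input_hashes,
        "stage_seconds": {k: round(v, 4) for k, v in timings.items()},
        "record_counts": {
            "leads": len(loc_df),
            "indexed": len(index_rows),
            "target_compared": len(target_rows),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out
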