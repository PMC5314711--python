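"""End-to-end feature-tracking pipeline for one or more cine slices.

Stages: register every consecutive frame pair, compose the cumulative
ED->t transforms, propagate the ED endo/epi contours, derive the
midwall, compute the strain components for the slice's view, detect
end-systole, and write every artifact (fields, contours, strain and
strain-rate CSVs, summary JSON, MANIFEST with per-stage timings).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as csio
from .core import CineSequence, ValidationError
from .registration import (
    RegistrationParams,
    compose_to_reference,
    register_sequence,
)
from .strain import (
    build_segment_model,
    circumferential_strain,
    detect_end_systole,
    longitudinal_strain,
    radial_strain,
    strain_rate,
    summarize,
)
from .tracking import (
    Contour,
    midwall_contour,
    pair_endo_epi,
    propagate_with_transforms,
)

logger = logging.getLogger(__name__)


@dataclass
class SliceInput:
    cine: str  # NIfTI path
    endo: str  # contour JSON path
    epi: str
    level: str = "mid"  # basal|mid|apical (SAX); ignored for LAX
    septal_axis_angle: float = 0.0
    wall_labels: tuple = ("septal", "lateral")  # LAX only


@dataclass
class PipelineConfig:
    slices: list = field(default_factory=list)  # list[SliceInput]
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    wall_layer: str = "mid"  # endo|mid|epi feeds Ecc/Ell
    n_spokes: int = 72
    sax_points: int = 200
    lax_points: int = 150
    es_override: int | None = None
    out_dir: str = "cinestrain_out"
    seed: int = 0
    save_fields: bool = False

    def __post_init__(self) -> None:
        if self.wall_layer not in ("endo", "mid", "epi"):
            raise ValidationError("wall_layer must be endo|mid|epi")


@dataclass
class SliceResult:
    seq: CineSequence
    level: str | None
    transforms: list
    contours: dict  # role -> list[Contour] per frame
    curves: list  # StrainCurves


def _layer_contours(cfg: PipelineConfig, endo, epi):
    if cfg.wall_layer == "endo":
        return endo
    if cfg.wall_layer == "epi":
        return epi
    return [midwall_contour(a, b) for a, b in zip(endo, epi)]


def track_slice(
    seq: CineSequence,
    ed_endo: Contour,
    ed_epi: Contour,
    cfg: PipelineConfig,
    level: str = "mid",
    septal_axis_angle: float = 0.0,
    wall_labels: tuple = ("septal", "lateral"),
    transforms: list | None = None,
) -> SliceResult:
    """Register (unless transforms are supplied), propagate and compute strain.

    Passing stored ``transforms`` re-propagates an edited ED contour
    without re-running the registration.
    """
    if transforms is None:
        results = register_sequence(seq, cfg.registration)
        transforms = [r.grid for r in results]
    n_pts = cfg.sax_points if seq.view == "SAX" else cfg.lax_points
    endo0, epi0 = pair_endo_epi(ed_endo, ed_epi, n_pts)
    endo = [propagate_with_transforms(endo0, transforms, t) for t in range(seq.n_frames)]
    epi = [propagate_with_transforms(epi0, transforms, t) for t in range(seq.n_frames)]
    curves = []
    if seq.view == "SAX":
        model = build_segment_model(level, septal_axis_angle)
        layer = _layer_contours(cfg, endo, epi)
        curves.append(circumferential_strain(layer, model, seq.frame_times))
        curves.append(
            radial_strain(endo, epi, model, seq.frame_times, n_spokes=cfg.n_spokes)
        )
    else:
        layer = _layer_contours(cfg, endo, epi)
        curves.append(longitudinal_strain(layer, wall_labels, seq.frame_times))
    for c in curves:
        c.slice_id = seq.slice_id
    return SliceResult(seq, level if seq.view == "SAX" else None, transforms,
                       {"endo": endo, "epi": epi}, curves)


def run_pipeline(cfg: PipelineConfig) -> int:
    """Run the full pipeline; returns 0 on success, 1 on stage failure.

    Partial outputs are kept; the MANIFEST records per-stage status and
    timings, so a failed run is diagnosable from disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "config": _cfg_dict(cfg)}
    status = 0
    slice_results: list[SliceResult] = []
    try:
        for k, sl in enumerate(cfg.slices):
            t0 = time.perf_counter()
            sl = sl if isinstance(sl, SliceInput) else SliceInput(**sl)
            seq = csio.read_cine(sl.cine)
            endo = csio.read_contour(sl.endo)
            epi = csio.read_contour(sl.epi)
            res = track_slice(
                seq, endo, epi, cfg,
                level=sl.level,
                septal_axis_angle=sl.septal_axis_angle,
                wall_labels=tuple(sl.wall_labels),
            )
            slice_results.append(res)
            cdir = out / f"slice_{seq.slice_id}"
            cdir.mkdir(exist_ok=True)
            for role in ("endo", "epi"):
                for c in res.contours[role]:
                    csio.write_contour(c, cdir / f"contour_{role}_f{c.frame:03d}.json")
            if cfg.save_fields:
                for t in range(seq.n_frames):
                    fld = compose_to_reference(
                        res.transforms, t, seq.shape, seq.pixel_spacing
                    )
                    csio.write_field(fld, cdir / f"field_ed_to_f{t:03d}.nii.gz")
            manifest["stages"][f"track_slice_{k}"] = {
                "status": "ok", "seconds": round(time.perf_counter() - t0, 3),
            }
    except Exception as exc:  # stage failure: keep partials, flag in MANIFEST
        logger.exception("tracking stage failed")
        manifest["stages"]["tracking"] = {"status": "failed", "error": str(exc)}
        status = 1

    if slice_results and status == 0:
        try:
            t0 = time.perf_counter()
            all_curves = [c for r in slice_results for c in r.curves]
            ecc = [c for c in all_curves if c.component == "Ecc_SAX"]
            es = detect_end_systole(ecc, cfg.es_override) if ecc else (
                cfg.es_override if cfg.es_override is not None
                else int(np.argmin(all_curves[0].global_curve().to_numpy()))
            )
            csio.write_strain_csv(all_curves, out / "strain.csv")
            rate_rows = []
            for c in all_curves:
                r = strain_rate(c)
                tidy = r.reset_index(names="frame").melt(
                    id_vars="frame", var_name="segment", value_name="rate_pct_per_s"
                )
                tidy["component"] = c.component
                tidy["slice_id"] = c.slice_id
                rate_rows.append(tidy)
            pd.concat(rate_rows, ignore_index=True).to_csv(
                out / "strain_rate.csv", index=False
            )
            summary = {"es_frame": int(es), "slices": []}
            for r in slice_results:
                entry = {"slice_id": r.seq.slice_id, "view": r.seq.view,
                         "level": r.level, "components": {}}
                for c in r.curves:
                    s = summarize(c, es)
                    entry["components"][c.component] = {
                        "es_global": s.es_global,
                        "es_segmental": {
                            k: (None if pd.isna(v) else float(v))
                            for k, v in s.es_segmental.items()
                        },
                    }
                summary["slices"].append(entry)
            (out / "summary.json").write_text(json.dumps(summary, indent=1))
            manifest["stages"]["strain"] = {
                "status": "ok", "seconds": round(time.perf_counter() - t0, 3),
            }
        except Exception as exc:
            logger.exception("strain stage failed")
            manifest["stages"]["strain"] = {"status": "failed", "error": str(exc)}
            status = 1

    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=1))
    return status


def _cfg_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["slices"] = [
        dataclasses.asdict(s) if dataclasses.is_dataclass(s) else dict(s)
        for s in cfg.slices
    ]
    return d
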