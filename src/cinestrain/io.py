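"""Readers and writers for the pipeline's file formats.

Cine sequences and deformation fields travel as NIfTI, contours and
ground truth as JSON point lists (mm), strain as tidy CSV, and
configuration as YAML.  Every writer/reader pair is lossless on valid
data.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import CineSequence, DeformationField, ValidationError
from .phantom import PhantomGroundTruth
from .strain import StrainCurves
from .tracking import Contour

# ---------------------------------------------------------------- cine NIfTI


def write_cine(seq: CineSequence, path) -> None:
    """Write a cine slice as a 2D+t NIfTI (pixel spacing in the header)."""
    sy, sx = seq.pixel_spacing
    # NIfTI data axes (i, j, k, t) with i = image column, j = image row
    data = np.transpose(seq.frames, (2, 1, 0))[:, :, None, :]
    affine = np.diag([sx, sy, 1.0, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    dt = float(np.median(np.diff(seq.frame_times)))
    img.header["pixdim"][4] = dt
    img.header.set_xyzt_units(xyz="mm", t="sec")
    img.header["descrip"] = f"view={seq.view};slice={seq.slice_id}".encode()[:79]
    nib.save(img, str(path))


def read_cine(path, frame_times=None, view: str | None = None) -> CineSequence:
    """Load a single-slice 2D+t NIfTI cine.

    Frame times come from the header time step (``pixdim[4]``) unless
    overridden.  A volume with more than one slice in k is rejected
    with advice to split it per slice.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[:, :, :, None] if data.shape[2] > 1 else data[:, :, None, :]
    if data.ndim != 4:
        raise ValidationError(f"expected a 2D+t NIfTI, got shape {data.shape}")
    if data.shape[2] != 1:
        raise ValidationError(
            "3D spatial volume: split the acquisition into per-slice 2D+t files"
        )
    if data.shape[3] < 2:
        raise ValidationError("cine input needs at least 2 time frames")
    zooms = img.header.get_zooms()
    sx, sy = float(zooms[0]), float(zooms[1])
    if sx <= 0 or sy <= 0:
        raise ValidationError("missing or non-positive pixel spacing in header pixdim[1:3]")
    frames = np.transpose(data[:, :, 0, :], (2, 1, 0))
    if frame_times is None:
        dt = float(zooms[3]) if len(zooms) > 3 else 0.0
        if dt <= 0:
            raise ValidationError(
                "no frame timing in header pixdim[4]; pass frame_times explicitly"
            )
        frame_times = np.arange(frames.shape[0]) * dt
    desc = img.header["descrip"].tobytes().decode(errors="ignore")
    meta = dict(kv.split("=", 1) for kv in desc.strip("\x00").split(";") if "=" in kv)
    return CineSequence(
        frames,
        (sy, sx),
        np.asarray(frame_times, dtype=float),
        view=view or meta.get("view", "SAX"),
        slice_id=meta.get("slice", "slice0"),
    )


# ------------------------------------------------------------ vector fields


def write_field(fld: DeformationField, path) -> None:
    """Write a deformation field as a 2-component NIfTI vector image."""
    sy, sx = fld.pixel_spacing
    data = np.transpose(fld.disp, (2, 1, 0))[:, :, None, None, :]  # (i, j, 1, 1, 2)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.diag([sx, sy, 1.0, 1.0]))
    img.header.set_intent("vector")
    nib.save(img, str(path))


def read_field(path) -> DeformationField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 5 or data.shape[4] != 2:
        raise ValidationError(f"expected a 2-component vector NIfTI, got {data.shape}")
    zooms = img.header.get_zooms()
    disp = np.transpose(data[:, :, 0, 0, :], (2, 1, 0))
    return DeformationField(disp, (float(zooms[1]), float(zooms[0])))


# ---------------------------------------------------------------- contours


def write_contour(c: Contour, path) -> None:
    payload = {
        "slice_id": c.slice_id,
        "view": c.view,
        "frame": int(c.frame),
        "role": c.role,
        "closed": bool(c.closed),
        "clamped": bool(c.clamped),
        "points": np.asarray(c.points, dtype=float).tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_contour(path) -> Contour:
    """Read a contour JSON; invariant violations name the failing rule."""
    payload = json.loads(Path(path).read_text())
    try:
        return Contour(
            points=np.asarray(payload["points"], dtype=float),
            closed=bool(payload["closed"]),
            role=payload["role"],
            slice_id=payload.get("slice_id", "slice0"),
            view=payload.get("view", "SAX"),
            frame=int(payload.get("frame", 0)),
            clamped=bool(payload.get("clamped", False)),
        )
    except KeyError as exc:
        raise ValidationError(f"contour JSON missing required field {exc}") from exc


# ------------------------------------------------------------- ground truth


def write_ground_truth(gt: PhantomGroundTruth, path) -> None:
    """Serialise phantom ground truth (the closed-form maps go as params)."""
    payload = {
        "es_frame": int(gt.es_frame),
        "params": gt.params,
        "true_ecc": gt.true_ecc.tolist(),
        "true_err": gt.true_err.tolist(),
        "true_ell": gt.true_ell.tolist(),
        "ecc_by_layer": {k: np.asarray(v).tolist() for k, v in gt.ecc_by_layer.items()},
        "ed_endo": np.asarray(gt.ed_endo.points).tolist(),
        "ed_epi": np.asarray(gt.ed_epi.points).tolist(),
    }
    Path(path).write_text(json.dumps(payload))


# -------------------------------------------------------------- strain CSV


def write_strain_csv(curves_list: list[StrainCurves], path) -> None:
    tidy = pd.concat([c.to_tidy() for c in curves_list], ignore_index=True)
    tidy.to_csv(path, index=False)


def read_strain_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"view", "slice_id", "level", "segment", "frame", "time_s", "component", "value_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"strain CSV missing columns {sorted(missing)}")
    return df


# -------------------------------------------------------------------- YAML


def write_config(obj, path) -> None:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_config(path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValidationError("config YAML must hold a mapping")
    return data
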