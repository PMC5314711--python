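"""Lagrangian myocardial strain over the AHA 16-segment model.

Strain is referenced to end-diastole (frame 0): segment membership of
material points (contour edges, radial spokes) is fixed at ED, and
per-segment strain is the relative change of the corresponding
material arc length (Ecc, Ell) or spoke wall thickness (Err), in %.
Global strain at a level is the unweighted mean of its segments'
values.  Basal and mid short-axis levels use 6 sectors of 60 degrees,
the apical level 4 sectors of 90 degrees, anchored at a manually
placed mid-septal reference axis; long-axis walls split into
basal/mid/apical thirds per side plus the apex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ValidationError
from .tracking import Contour

LEVELS = ("basal", "mid", "apical")
SAX_LABELS_6 = (
    "anterior",
    "anteroseptal",
    "inferoseptal",
    "inferior",
    "inferolateral",
    "anterolateral",
)
SAX_LABELS_4 = ("anterior", "septal", "inferior", "lateral")
COMPONENTS = ("Err_SAX", "Ecc_SAX", "Ell_LAX")


@dataclass
class SegmentModel:
    """Angular sectors of one short-axis level, anchored mid-septally."""

    level: str
    septal_axis_angle: float  # radians from the image x-axis, CCW
    sector_bounds: list = field(default_factory=list)  # (start, end, label)

    @property
    def labels(self) -> list:
        return [b[2] for b in self.sector_bounds]

    def assign(self, angles: np.ndarray) -> np.ndarray:
        """Sector index for each angle (radians)."""
        n = len(self.sector_bounds)
        width = 2 * np.pi / n
        rel = np.mod(np.asarray(angles, dtype=float) - self.septal_axis_angle, 2 * np.pi)
        return np.minimum((rel / width).astype(int), n - 1)


def build_segment_model(level: str, septal_axis_angle: float = 0.0) -> SegmentModel:
    """6 equal 60-degree sectors (basal/mid) or 4 equal 90-degree (apical)."""
    if level not in LEVELS:
        raise ValidationError(f"level must be one of {LEVELS}")
    labels = SAX_LABELS_4 if level == "apical" else SAX_LABELS_6
    n = len(labels)
    width = 2 * np.pi / n
    bounds = [
        (septal_axis_angle + k * width, septal_axis_angle + (k + 1) * width, labels[k])
        for k in range(n)
    ]
    return SegmentModel(level, septal_axis_angle, bounds)


# ----------------------------------------------------------------------


@dataclass
class StrainCurves:
    """Per-segment, per-frame Lagrangian strain (%) for one component."""

    component: str
    values: pd.DataFrame  # index: frame, columns: segment labels
    frame_times: np.ndarray
    level: str | None = None
    slice_id: str = "slice0"
    view: str = "SAX"

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise ValidationError(f"component must be one of {COMPONENTS}")
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if len(self.frame_times) != len(self.values):
            raise ValidationError("frame_times length must match the number of frames")
        first = self.values.iloc[0].dropna()
        if len(first) and np.max(np.abs(first.to_numpy())) > 1e-9:
            raise ValidationError("strain must be 0 at frame 0 for every segment")

    @property
    def missing_segments(self) -> list:
        return [c for c in self.values.columns if self.values[c].isna().all()]

    def global_curve(self) -> pd.Series:
        """Unweighted mean over non-missing segments at each frame."""
        return self.values.mean(axis=1, skipna=True)

    def to_tidy(self) -> pd.DataFrame:
        rows = self.values.reset_index(names="frame").melt(
            id_vars="frame", var_name="segment", value_name="value_pct"
        )
        rows["time_s"] = self.frame_times[rows["frame"].to_numpy()]
        rows["component"] = self.component
        rows["view"] = self.view
        rows["slice_id"] = self.slice_id
        rows["level"] = self.level if self.level is not None else self.view
        return rows[
            ["view", "slice_id", "level", "segment", "frame", "time_s", "component", "value_pct"]
        ]


@dataclass
class StrainSummary:
    """End-systolic segmental strain and its per-level global mean."""

    component: str
    es_frame: int
    es_segmental: pd.Series
    es_global: float

    def __post_init__(self) -> None:
        seg = self.es_segmental.dropna()
        if len(seg) and not np.isclose(self.es_global, seg.mean(), atol=1e-9):
            raise ValidationError("es_global must equal the mean of its segments")


# ----------------------------------------------------------------------
# helpers


def _check_contour_stack(contours: list[Contour]) -> None:
    if len(contours) < 1:
        raise ValidationError("need at least one frame of contours")
    n = contours[0].n_points
    for c in contours:
        if c.n_points != n:
            raise ValidationError("contours must be consistently resampled across frames")


def _edge_lengths(points: np.ndarray, closed: bool) -> np.ndarray:
    pts = np.vstack([points, points[:1]]) if closed else points
    return np.linalg.norm(np.diff(pts, axis=0), axis=1)


def _segment_arc_strain(
    contours: list[Contour],
    edge_segment: np.ndarray,
    labels: list,
    component: str,
    frame_times: np.ndarray,
    level: str | None,
    view: str,
) -> StrainCurves:
    """Relative arc-length change of ED-assigned edge groups, in %."""
    n_frames = len(contours)
    closed = contours[0].closed
    out = np.full((n_frames, len(labels)), np.nan)
    l0 = np.zeros(len(labels))
    for s in range(len(labels)):
        member = edge_segment == s
        if not member.any():
            continue
        for t in range(n_frames):
            lt = _edge_lengths(contours[t].points, closed)[member].sum()
            if t == 0:
                l0[s] = lt
            out[t, s] = (lt - l0[s]) / l0[s] * 100.0
    df = pd.DataFrame(out, columns=list(labels))
    df.index.name = "frame"
    return StrainCurves(
        component, df, frame_times, level=level, slice_id=contours[0].slice_id, view=view
    )


# ----------------------------------------------------------------------
# circumferential


def circumferential_strain(
    midwall: list[Contour],
    model: SegmentModel,
    frame_times: np.ndarray | None = None,
) -> StrainCurves:
    """Ecc per AHA sector from the midwall arc length.

    Edges of the ED midwall polygon are assigned to sectors by the
    angle of their midpoint around the ED centroid; each sector's
    strain is the relative change of the summed length of those same
    (material) edges at every frame.
    """
    _check_contour_stack(midwall)
    if not midwall[0].closed:
        raise ValidationError("circumferential strain requires closed SAX contours")
    if frame_times is None:
        frame_times = np.arange(len(midwall), dtype=float)
    centre = midwall[0].centroid()
    pts = midwall[0].points
    nxt = np.roll(pts, -1, axis=0)
    mid = 0.5 * (pts + nxt) - centre
    ang = np.arctan2(mid[:, 1], mid[:, 0])
    edge_segment = model.assign(ang)
    return _segment_arc_strain(
        midwall, edge_segment, list(model.labels), "Ecc_SAX", frame_times, model.level, "SAX"
    )


# ----------------------------------------------------------------------
# radial


def _ray_polygon_crossing(points: np.ndarray, centre: np.ndarray, theta: float):
    """First crossing of the ray from centre at angle theta with a closed polygon.

    Returns ``(edge_index, fraction)`` or None if the ray misses.
    """
    d = np.array([np.cos(theta), np.sin(theta)])
    A = points
    B = np.roll(points, -1, axis=0)
    E = B - A
    AC = A - centre
    denom = d[0] * E[:, 1] - d[1] * E[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (AC[:, 0] * E[:, 1] - AC[:, 1] * E[:, 0]) / denom
        s = (AC[:, 0] * d[1] - AC[:, 1] * d[0]) / -denom
    ok = np.isfinite(r) & np.isfinite(s) & (r > 1e-12) & (s >= 0.0) & (s < 1.0)
    if not ok.any():
        return None
    idx = np.where(ok)[0]
    best = idx[np.argmin(r[idx])]
    return int(best), float(s[best])


def radial_strain(
    endo: list[Contour],
    epi: list[Contour],
    model: SegmentModel,
    frame_times: np.ndarray | None = None,
    n_spokes: int = 72,
) -> StrainCurves:
    """Err per AHA sector from spoke wall-thickness change.

    ``n_spokes`` radial spokes are cast from the ED endocardial
    centroid; where each spoke crosses the ED endo and epi contours
    defines a material point pair whose distance is the local wall
    thickness, tracked by linear interpolation along the propagated
    contours.  Positive for thickening.
    """
    _check_contour_stack(endo)
    _check_contour_stack(epi)
    if len(endo) != len(epi):
        raise ValidationError("endo and epi stacks must have the same frame count")
    if frame_times is None:
        frame_times = np.arange(len(endo), dtype=float)
    centre = endo[0].centroid()
    thetas = (np.arange(n_spokes) + 0.5) / n_spokes * 2 * np.pi
    crossings = []
    for theta in thetas:
        ce = _ray_polygon_crossing(endo[0].points, centre, theta)
        cp = _ray_polygon_crossing(epi[0].points, centre, theta)
        crossings.append((theta, ce, cp))
    spoke_segment = model.assign(thetas)
    labels = list(model.labels)
    n_frames = len(endo)
    out = np.full((n_frames, len(labels)), np.nan)
    th = np.full((n_frames, n_spokes), np.nan)
    for k, (theta, ce, cp) in enumerate(crossings):
        if ce is None or cp is None:
            continue
        for t in range(n_frames):
            pe = _interp_on_contour(endo[t].points, ce)
            pp = _interp_on_contour(epi[t].points, cp)
            th[t, k] = np.linalg.norm(pp - pe)
    for s in range(len(labels)):
        member = spoke_segment == s
        valid = member & np.isfinite(th[0])
        if valid.sum() == 0 or valid.sum() < 0.5 * member.sum():
            continue  # > 50% of spokes dropped: segment flagged missing
        rel = (th[:, valid] - th[0, valid]) / th[0, valid] * 100.0
        out[:, s] = rel.mean(axis=1)
    df = pd.DataFrame(out, columns=labels)
    df.index.name = "frame"
    return StrainCurves(
        "Err_SAX", df, frame_times, level=model.level, slice_id=endo[0].slice_id, view="SAX"
    )


def _interp_on_contour(points: np.ndarray, crossing: tuple) -> np.ndarray:
    i, s = crossing
    j = (i + 1) % len(points)
    return (1.0 - s) * points[i] + s * points[j]


# ----------------------------------------------------------------------
# longitudinal


def lax_segment_labels(wall_labels: tuple[str, str] = ("septal", "lateral")) -> list:
    w1, w2 = wall_labels
    return [
        f"basal_{w1}", f"mid_{w1}", f"apical_{w1}",
        "apex",
        f"apical_{w2}", f"mid_{w2}", f"basal_{w2}",
    ]


def longitudinal_strain(
    midwall: list[Contour],
    wall_labels: tuple[str, str] = ("septal", "lateral"),
    frame_times: np.ndarray | None = None,
) -> StrainCurves:
    """Ell per wall segment from midline arc-length change.

    The open ED midline (base -> apex -> base) is split into 7 equal
    arc-length segments: basal/mid/apical thirds of the first wall, the
    apex, then the second wall mirrored.  Negative for shortening.
    """
    _check_contour_stack(midwall)
    if midwall[0].closed:
        raise ValidationError("longitudinal strain requires open LAX contours")
    if midwall[0].n_points < 21:
        raise ValidationError("LAX contour too short to split into wall segments")
    if frame_times is None:
        frame_times = np.arange(len(midwall), dtype=float)
    labels = lax_segment_labels(wall_labels)
    seg_len = _edge_lengths(midwall[0].points, closed=False)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    mid_arc = 0.5 * (cum[:-1] + cum[1:]) / cum[-1]
    edge_segment = np.minimum((mid_arc * len(labels)).astype(int), len(labels) - 1)
    return _segment_arc_strain(
        midwall, edge_segment, labels, "Ell_LAX", frame_times,
        level=None, view="LAX",
    )


# ----------------------------------------------------------------------
# rates, end-systole, summaries


def strain_rate(curves: StrainCurves) -> pd.DataFrame:
    """Per-frame strain rate (%/s): central differences in the interior,
    one-sided at the ends."""
    t = curves.frame_times
    if len(t) < 3:
        raise ValidationError("strain rate needs at least 3 frames")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("frame_times must be strictly increasing")
    rate = np.gradient(curves.values.to_numpy(), t, axis=0)
    return pd.DataFrame(rate, columns=curves.values.columns, index=curves.values.index)


def detect_end_systole(
    ecc_curves: list[StrainCurves], es_override: int | None = None
) -> int:
    """Frame minimising the mean global Ecc across SAX slices.

    Ties break to the earliest frame; an explicit ``es_override`` wins.
    """
    if es_override is not None:
        return int(es_override)
    if not ecc_curves:
        raise ValidationError("need at least one Ecc curve")
    globals_ = []
    for c in ecc_curves:
        g = c.global_curve()
        if g.isna().all():
            continue
        globals_.append(g.to_numpy())
    if not globals_:
        raise ValidationError("all Ecc curves are missing")
    mean_curve = np.nanmean(np.column_stack(globals_), axis=1)
    return int(np.argmin(mean_curve))


def summarize(curves: StrainCurves, es_frame: int) -> StrainSummary:
    """End-systolic segmental values and their unweighted global mean."""
    if not 0 <= es_frame < len(curves.values):
        raise ValidationError("es_frame out of range")
    seg = curves.values.iloc[es_frame]
    nonmissing = seg.dropna()
    if len(nonmissing) == 0:
        raise ValidationError("no non-missing segments at the requested level")
    return StrainSummary(
        component=curves.component,
        es_frame=es_frame,
        es_segmental=seg,
        es_global=float(nonmissing.mean()),
    )
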