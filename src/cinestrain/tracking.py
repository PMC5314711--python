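"""Contours and their propagation through the cardiac cycle.

End-diastolic endo- and epicardial contours are drawn (or generated)
once and then carried through every frame by sampling the cumulative
ED->t deformation field at the contour points.  Because the fields are
stored, an edited ED contour can be re-propagated without re-running
the registration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import DeformationField, ValidationError

ROLES = ("endo", "epi", "midwall")


@dataclass
class Contour:
    """Ordered point list in physical mm, tied to a slice and frame."""

    points: np.ndarray  # (N, 2) as (x, y) mm
    closed: bool
    role: str
    slice_id: str = "slice0"
    view: str = "SAX"
    frame: int = 0
    clamped: bool = False  # set when propagation had to clamp points

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError("points must have shape (N, 2)")
        if len(self.points) < 16:
            raise ValidationError("a contour needs at least 16 points")
        if self.role not in ROLES:
            raise ValidationError(f"role must be one of {ROLES}")
        if self.view not in ("SAX", "LAX"):
            raise ValidationError("view must be 'SAX' or 'LAX'")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValidationError("consecutive duplicate points are not allowed")
        if self.view == "SAX" and not self.closed:
            raise ValidationError("SAX contours must be closed")
        if self.view == "LAX" and self.closed:
            raise ValidationError("LAX contours must be open")
        if self.closed and self.signed_area() < 0:
            raise ValidationError("closed contours must be oriented counter-clockwise")

    # ------------------------------------------------------------------
    @property
    def n_points(self) -> int:
        return len(self.points)

    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def segment_lengths(self) -> np.ndarray:
        """Edge lengths; includes the closing edge for closed contours."""
        pts = self.points
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        return np.linalg.norm(np.diff(pts, axis=0), axis=1)

    def arc_length(self) -> float:
        return float(self.segment_lengths().sum())


# ----------------------------------------------------------------------


def resample_contour(c: Contour, n: int) -> Contour:
    """Resample to ``n`` points at equal arc-length spacing.

    Keeps the first point (and total arc length to well below 0.1%).
    """
    if n < 16:
        raise ValidationError("resampling requires n >= 16")
    seg = c.segment_lengths()
    total = float(seg.sum())
    if total <= 0:
        raise ValidationError("degenerate zero-length contour")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    pts = c.points
    if c.closed:
        pts = np.vstack([pts, pts[:1]])
        targets = np.linspace(0.0, total, n, endpoint=False)
    else:
        targets = np.linspace(0.0, total, n)
    new_x = np.interp(targets, s, pts[:, 0])
    new_y = np.interp(targets, s, pts[:, 1])
    return replace(c, points=np.column_stack([new_x, new_y]))


def propagate_contour(c: Contour, fld: DeformationField, frame: int | None = None) -> Contour:
    """Displace each contour point by the field value at its position.

    The dense field is interpolated with cubic splines.  Points falling
    outside the field domain are clamped to the border and the returned
    contour carries ``clamped=True``.
    """
    ny, nx = fld.shape
    sy, sx = fld.pixel_spacing
    rows = c.points[:, 1] / sy + (ny - 1) / 2.0
    cols = c.points[:, 0] / sx + (nx - 1) / 2.0
    outside = (rows < 0) | (rows > ny - 1) | (cols < 0) | (cols > nx - 1)
    clamped = bool(np.any(outside))
    if clamped:
        warnings.warn("contour point(s) outside the field domain were clamped")
        rows = np.clip(rows, 0, ny - 1)
        cols = np.clip(cols, 0, nx - 1)
    dx = ndimage.map_coordinates(fld.disp[0], [rows, cols], order=3, mode="nearest")
    dy = ndimage.map_coordinates(fld.disp[1], [rows, cols], order=3, mode="nearest")
    new_pts = c.points + np.column_stack([dx, dy])
    return replace(
        c,
        points=new_pts,
        frame=c.frame if frame is None else frame,
        clamped=c.clamped or clamped,
    )


def propagate_with_transforms(c: Contour, transforms, t: int) -> Contour:
    """Propagate frame-0 contour points by composing pairwise transforms.

    Evaluates each B-spline transform exactly at the tracked point
    positions (no dense-field resampling error); used by the pipeline.
    """
    from .registration import _clamp_to_grid

    if not 0 <= t <= len(transforms):
        raise ValidationError(f"frame index {t} out of range")
    pts = c.points.copy()
    for s in range(t):
        g = transforms[s]
        pts = pts + g.evaluate(_clamp_to_grid(pts, g))
    return replace(c, points=pts, frame=t)


def midwall_contour(endo: Contour, epi: Contour) -> Contour:
    """Pointwise midpoint of paired endo/epi contours.

    SAX pairs by common angular coordinate around the endo centroid,
    LAX by normalised arc length; callers are expected to have
    resampled both contours to a matched parameterisation with equal
    point counts (as :func:`pair_endo_epi` does).
    """
    if endo.frame != epi.frame or endo.slice_id != epi.slice_id or endo.view != epi.view:
        raise ValidationError("endo and epi contours must match in frame/slice/view")
    if endo.n_points != epi.n_points:
        raise ValidationError("endo and epi must be resampled to equal point counts")
    if endo.view == "SAX":
        centre = endo.centroid()
        r_endo = np.linalg.norm(endo.points - centre, axis=1)
        r_epi = np.linalg.norm(epi.points - centre, axis=1)
        if np.any(r_epi < r_endo - 1e-9) and not np.allclose(endo.points, epi.points):
            raise ValidationError("epicardial contour crosses inside the endocardial one")
    mid = 0.5 * (endo.points + epi.points)
    return replace(endo, points=mid, role="midwall")


def pair_endo_epi(endo: Contour, epi: Contour, n: int | None = None) -> tuple[Contour, Contour]:
    """Resample endo/epi to a matched parameterisation of ``n`` points.

    SAX: both contours are re-parameterised by the polar angle around
    the ED endo centroid (requires star-shaped contours, true for LV
    sections).  LAX: both are resampled by normalised arc length.
    """
    if n is None:
        n = 200 if endo.view == "SAX" else 150
    if endo.view == "SAX":
        centre = endo.centroid()
        out = []
        for c in (endo, epi):
            out.append(_resample_by_angle(c, centre, n))
        return out[0], out[1]
    return resample_contour(endo, n), resample_contour(epi, n)


def _resample_by_angle(c: Contour, centre: np.ndarray, n: int) -> Contour:
    rel = c.points - centre
    ang = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
    if ang[-1] < ang[0]:  # enforce increasing angle
        rel = rel[::-1]
        ang = ang[::-1]
    rad = np.linalg.norm(rel, axis=1)
    # close the loop in angle
    ang_c = np.concatenate([ang, [ang[0] + 2 * np.pi]])
    rad_c = np.concatenate([rad, [rad[0]]])
    targets = ang_c[0] + np.arange(n) / n * 2 * np.pi
    r_new = np.interp(targets, ang_c, rad_c)
    pts = centre + np.column_stack([r_new * np.cos(targets), r_new * np.sin(targets)])
    return replace(c, points=pts)
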