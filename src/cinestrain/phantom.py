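"""Synthetic cine phantoms with analytically known deformation.

Short-axis (SAX) phantoms are contracting annuli: a material point at
end-diastolic radius R moves to

    r(R, t) = r_endo(t) + (R - R_endo_ed) * (r_epi(t) - r_endo(t))
                                          / (R_epi_ed - R_endo_ed)

inside the wall, with linear blood-pool scaling inside the endocardium
and a linear taper back to the identity outside the epicardium, so the
whole-image map is piecewise linear in radius, monotone and exactly
invertible.  The endo/epi radii follow a half-sine activation that
peaks at the end-systolic frame and relaxes back to the end-diastolic
geometry at the last frame (cyclic).  Long-axis (LAX) phantoms are
truncated-ellipse shells deforming by a uniform isotropic scaling about
the image centre, so the midline arc length changes by exactly the
prescribed long-axis shortening fraction (linear-in-arc-length
material mapping).

Image intensity is a band-limited seeded random texture riding on
SSFP-like class means (bright blood pool, mid-grey myocardium, dark
background), advected exactly with the material map; seeded Gaussian
noise is added per frame.  Ground-truth strain follows in closed form:

    Ecc(R, t) = (r(R, t) / R - 1) * 100
    Err(t)    = ((r_epi - r_endo) - (R_epi_ed - R_endo_ed))
                                  / (R_epi_ed - R_endo_ed) * 100
    Ell(t)    = (s(t) - 1) * 100          (LAX uniform scaling s)

identical across segments by construction, and exactly 0 at frame 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage

from .core import CineSequence, ValidationError
from .tracking import Contour

# LAX shell geometry (mm): midline semi-axes and wall thickness.
_LAX_SEMI_LONG = 40.0
_LAX_SEMI_SHORT = 22.0
_LAX_WALL = 8.0
_LAX_BASE_FRAC = -0.5  # base plane at y = frac * semi_long (apex at +y)


@dataclass
class PhantomSpec:
    """Geometry, motion and texture of a synthetic cine slice."""

    view: str = "SAX"
    grid_size: int = 160
    pixel_spacing: float = 1.6  # mm, isotropic
    n_frames: int = 30
    es_frame: int = 10
    endo_radius_ed: float = 25.0  # mm (SAX)
    epi_radius_ed: float = 35.0
    endo_radius_es: float = 20.0
    epi_radius_es: float = 33.0
    long_axis_shortening: float = 0.15  # fraction (LAX)
    rotation_deg: float = 0.0
    texture_scale: float = 6.0  # mm correlation length
    noise_sd: float = 0.02  # intensity units ([0, 1] range images)
    rr_interval_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.view not in ("SAX", "LAX"):
            raise ValidationError("view must be 'SAX' or 'LAX'")
        if self.n_frames < 2:
            raise ValidationError("n_frames must be >= 2")
        if not 0 <= self.es_frame < self.n_frames:
            raise ValidationError("es_frame must satisfy 0 <= es_frame < n_frames")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.texture_scale <= 0:
            raise ValidationError("texture_scale must be positive")
        if self.view == "SAX":
            if not (self.epi_radius_ed > self.endo_radius_ed > 0):
                raise ValidationError("need epi_radius_ed > endo_radius_ed > 0")
            if not (self.epi_radius_es > self.endo_radius_es > 0):
                raise ValidationError("need epi_radius_es > endo_radius_es > 0")
        else:
            if not 0 <= self.long_axis_shortening < 0.5:
                raise ValidationError("long_axis_shortening must be in [0, 0.5)")

    def activation(self) -> np.ndarray:
        """Half-sine contraction to es_frame, mirrored relaxation after."""
        t = np.arange(self.n_frames, dtype=float)
        a = np.zeros(self.n_frames)
        es, last = self.es_frame, self.n_frames - 1
        if es > 0:
            up = t <= es
            a[up] = np.sin(0.5 * np.pi * t[up] / es)
        if last > es:
            down = t > es
            a[down] = np.sin(0.5 * np.pi * (last - t[down]) / (last - es))
        return a

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.rr_interval_s / self.n_frames


@dataclass
class PhantomGroundTruth:
    """Closed-form motion and strain truth attached to a phantom."""

    es_frame: int
    material_map: Callable[[np.ndarray, int], np.ndarray]
    inverse_map: Callable[[np.ndarray, int], np.ndarray]
    ed_endo: Contour
    ed_epi: Contour
    true_ecc: np.ndarray  # (n_frames, n_segments), midwall layer (SAX)
    true_err: np.ndarray  # (n_frames, n_segments) wall-thickness strain (SAX)
    true_ell: np.ndarray  # (n_frames, n_segments) (LAX)
    ecc_by_layer: dict = field(default_factory=dict)  # endo/mid/epi curves
    params: dict = field(default_factory=dict)

    def es_global(self, component: str) -> float:
        arr = {"Ecc": self.true_ecc, "Err": self.true_err, "Ell": self.true_ell}[component]
        return float(np.nanmean(arr[self.es_frame]))


# ----------------------------------------------------------------------


def _texture_image(
    spec: PhantomSpec, class_map: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Band-limited seeded texture over SSFP-like class means."""
    sigma_px = spec.texture_scale / spec.pixel_spacing
    noise = rng.standard_normal(class_map.shape)
    tex = ndimage.gaussian_filter(noise, sigma=sigma_px)
    sd = tex.std()
    if sd > 0:
        tex /= sd
    base = ndimage.gaussian_filter(class_map, sigma=1.0)
    return base + 0.15 * tex


def _render_frames(
    spec: PhantomSpec,
    img_ed: np.ndarray,
    inverse_map: Callable[[np.ndarray, int], np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """Advect the ED image with the exact material map, then add noise."""
    n = spec.grid_size
    s = spec.pixel_spacing
    coords = (np.arange(n) - (n - 1) / 2.0) * s
    X, Y = np.meshgrid(coords, coords)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    pref = ndimage.spline_filter(img_ed, order=3, mode="nearest")
    frames = np.empty((spec.n_frames, n, n))
    for t in range(spec.n_frames):
        src = inverse_map(pts, t)
        rows = src[:, 1] / s + (n - 1) / 2.0
        cols = src[:, 0] / s + (n - 1) / 2.0
        frames[t] = ndimage.map_coordinates(
            pref, [rows, cols], order=3, prefilter=False, mode="nearest"
        ).reshape(n, n)
    if spec.noise_sd > 0:
        frames += spec.noise_sd * rng.standard_normal(frames.shape)
    return frames


def _circle_contour(radius: float, n: int, role: str, view: str = "SAX") -> Contour:
    ang = np.arange(n) / n * 2 * np.pi
    pts = radius * np.column_stack([np.cos(ang), np.sin(ang)])
    return Contour(pts, closed=True, role=role, view=view, frame=0)


def generate_sax_phantom(spec: PhantomSpec) -> tuple[CineSequence, PhantomGroundTruth]:
    """Contracting-annulus short-axis phantom with exact ground truth."""
    if spec.view != "SAX":
        raise ValidationError("generate_sax_phantom requires view='SAX'")
    n = spec.grid_size
    s = spec.pixel_spacing
    act = spec.activation()
    Rn, Rp = spec.endo_radius_ed, spec.epi_radius_ed
    r_endo = Rn + act * (spec.endo_radius_es - Rn)
    r_epi = Rp + act * (spec.epi_radius_es - Rp)
    r_out = Rp + 25.0  # background relaxes back to identity by this ED radius
    beta = np.deg2rad(spec.rotation_deg) * act

    # Radial material map r(R, t): linear inside the wall (the prescribed
    # strain), continued C^1 into blood pool and background with
    # slope-matched quadratics so the whole-image displacement has no
    # derivative kink at the contours (physiologically the blood and the
    # near-field tissue follow the wall motion smoothly).
    def _radial_coeffs(t: int):
        sw = (r_epi[t] - r_endo[t]) / (Rp - Rn)  # wall slope
        # blood: r = c R + d R^2 with r(Rn) = r_endo, r'(Rn) = sw
        c_bl = 2.0 * r_endo[t] / Rn - sw
        d_bl = (sw - r_endo[t] / Rn) / Rn
        if c_bl <= 0:  # extreme geometry: fall back to linear blood scaling
            c_bl, d_bl = r_endo[t] / Rn, 0.0
        # background: r = r_epi + sw (R-Rp) + e (R-Rp)^2 with r(r_out) = r_out
        span = r_out - Rp
        e_bg = (r_out - r_epi[t] - sw * span) / span**2
        if sw + 2.0 * e_bg * span <= 0:  # keep monotone; fall back to linear
            e_bg = 0.0
        return sw, c_bl, d_bl, e_bg

    def _radial(R: np.ndarray, t: int, forward: bool) -> np.ndarray:
        sw, c_bl, d_bl, e_bg = _radial_coeffs(t)
        R = np.asarray(R, dtype=float)
        out = np.empty_like(R)
        if forward:
            m = R <= Rn
            out[m] = c_bl * R[m] + d_bl * R[m] ** 2
            m = (R > Rn) & (R <= Rp)
            out[m] = r_endo[t] + sw * (R[m] - Rn)
            m = (R > Rp) & (R <= r_out)
            out[m] = r_epi[t] + sw * (R[m] - Rp) + e_bg * (R[m] - Rp) ** 2
            m = R > r_out
            out[m] = R[m]
            # background quadratic may not land exactly on identity slope at
            # r_out when e_bg fell back; clamp monotonicity is preserved
            return out
        # inverse: piecewise closed-form (quadratics invert analytically)
        rho = R
        m = rho <= r_endo[t]
        if d_bl == 0.0:
            out[m] = rho[m] / c_bl
        else:
            out[m] = (np.sqrt(c_bl**2 + 4.0 * d_bl * rho[m]) - c_bl) / (2.0 * d_bl)
        m = (rho > r_endo[t]) & (rho <= r_epi[t])
        out[m] = Rn + (rho[m] - r_endo[t]) / sw
        r_at_out = r_epi[t] + sw * (r_out - Rp) + e_bg * (r_out - Rp) ** 2
        m = (rho > r_epi[t]) & (rho <= r_at_out)
        if e_bg == 0.0:
            out[m] = Rp + (rho[m] - r_epi[t]) / sw
        else:
            out[m] = Rp + (
                np.sqrt(sw**2 + 4.0 * e_bg * (rho[m] - r_epi[t])) - sw
            ) / (2.0 * e_bg)
        m = rho > r_at_out
        out[m] = rho[m]
        return out

    def material_map(pts: np.ndarray, t: int) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        R = np.linalg.norm(pts, axis=1)
        r = _radial(R, t, forward=True)
        scale = np.divide(r, R, out=np.ones_like(R), where=R > 0)
        moved = pts * scale[:, None]
        c, sn = np.cos(beta[t]), np.sin(beta[t])
        rot = np.array([[c, -sn], [sn, c]])
        return moved @ rot.T

    def inverse_map(pts: np.ndarray, t: int) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        c, sn = np.cos(-beta[t]), np.sin(-beta[t])
        rot = np.array([[c, -sn], [sn, c]])
        unrot = pts @ rot.T
        rho = np.linalg.norm(unrot, axis=1)
        R = _radial(rho, t, forward=False)
        scale = np.divide(R, rho, out=np.ones_like(rho), where=rho > 0)
        return unrot * scale[:, None]

    # intensity: texture advected with the map
    coords = (np.arange(n) - (n - 1) / 2.0) * s
    X, Y = np.meshgrid(coords, coords)
    Rmap = np.hypot(X, Y)
    class_map = np.full((n, n), 0.2)
    class_map[Rmap < Rn] = 0.95  # blood pool
    class_map[(Rmap >= Rn) & (Rmap <= Rp)] = 0.6  # myocardium
    rng = np.random.default_rng(spec.seed)
    img_ed = _texture_image(spec, class_map, rng)
    frames = _render_frames(spec, img_ed, inverse_map, rng)
    seq = CineSequence(frames, (s, s), spec.frame_times(), view="SAX")

    # closed-form truth (identical across the 6 mid-level segments)
    n_seg = 6
    err = ((r_epi - r_endo) - (Rp - Rn)) / (Rp - Rn) * 100.0
    layers = {"endo": Rn, "mid": 0.5 * (Rn + Rp), "epi": Rp}
    ecc_by_layer = {}
    for name, R0 in layers.items():
        rt = r_endo + (R0 - Rn) * (r_epi - r_endo) / (Rp - Rn)
        ecc_by_layer[name] = (rt / R0 - 1.0) * 100.0
    gt = PhantomGroundTruth(
        es_frame=spec.es_frame,
        material_map=material_map,
        inverse_map=inverse_map,
        ed_endo=_circle_contour(Rn, 200, "endo"),
        ed_epi=_circle_contour(Rp, 200, "epi"),
        true_ecc=np.tile(ecc_by_layer["mid"][:, None], (1, n_seg)),
        true_err=np.tile(err[:, None], (1, n_seg)),
        true_ell=np.zeros((spec.n_frames, 0)),
        ecc_by_layer=ecc_by_layer,
        params={
            "view": "SAX",
            "r_endo": r_endo.tolist(),
            "r_epi": r_epi.tolist(),
            "rotation_rad": beta.tolist(),
            "r_out": r_out,
            "endo_radius_ed": Rn,
            "epi_radius_ed": Rp,
        },
    )
    return seq, gt


# ----------------------------------------------------------------------


def _lax_shell_contour(offset: float, n: int, role: str) -> Contour:
    """Open contour of the shell at midline offset ``offset`` mm."""
    a = _LAX_SEMI_LONG + offset
    b = _LAX_SEMI_SHORT + offset
    y_base = _LAX_BASE_FRAC * _LAX_SEMI_LONG
    phi_max = np.arccos(np.clip(y_base / a, -1.0, 1.0))
    phi = np.linspace(-phi_max, phi_max, n)
    pts = np.column_stack([b * np.sin(phi), a * np.cos(phi)])
    return Contour(pts, closed=False, role=role, view="LAX", frame=0)


def generate_lax_phantom(spec: PhantomSpec) -> tuple[CineSequence, PhantomGroundTruth]:
    """Truncated-ellipse long-axis phantom with uniform-shortening truth."""
    if spec.view != "LAX":
        raise ValidationError("generate_lax_phantom requires view='LAX'")
    n = spec.grid_size
    s = spec.pixel_spacing
    act = spec.activation()
    scale_t = 1.0 - spec.long_axis_shortening * act

    def material_map(pts: np.ndarray, t: int) -> np.ndarray:
        return np.atleast_2d(np.asarray(pts, dtype=float)) * scale_t[t]

    def inverse_map(pts: np.ndarray, t: int) -> np.ndarray:
        return np.atleast_2d(np.asarray(pts, dtype=float)) / scale_t[t]

    coords = (np.arange(n) - (n - 1) / 2.0) * s
    X, Y = np.meshgrid(coords, coords)
    a_en = _LAX_SEMI_LONG - _LAX_WALL / 2.0
    b_en = _LAX_SEMI_SHORT - _LAX_WALL / 2.0
    a_ep = _LAX_SEMI_LONG + _LAX_WALL / 2.0
    b_ep = _LAX_SEMI_SHORT + _LAX_WALL / 2.0
    y_base = _LAX_BASE_FRAC * _LAX_SEMI_LONG
    in_endo = (X / b_en) ** 2 + (Y / a_en) ** 2 < 1.0
    in_epi = (X / b_ep) ** 2 + (Y / a_ep) ** 2 < 1.0
    below_base = Y > y_base
    class_map = np.full((n, n), 0.2)
    class_map[in_epi & ~in_endo & below_base] = 0.6
    class_map[in_endo & below_base] = 0.95
    rng = np.random.default_rng(spec.seed)
    img_ed = _texture_image(spec, class_map, rng)
    frames = _render_frames(spec, img_ed, inverse_map, rng)
    seq = CineSequence(frames, (s, s), spec.frame_times(), view="LAX")

    n_seg = 7  # basal/mid/apical per side + apex
    ell = (scale_t - 1.0) * 100.0
    gt = PhantomGroundTruth(
        es_frame=spec.es_frame,
        material_map=material_map,
        inverse_map=inverse_map,
        ed_endo=_lax_shell_contour(-_LAX_WALL / 2.0, 150, "endo"),
        ed_epi=_lax_shell_contour(+_LAX_WALL / 2.0, 150, "epi"),
        true_ecc=np.zeros((spec.n_frames, 0)),
        true_err=np.zeros((spec.n_frames, 0)),
        true_ell=np.tile(ell[:, None], (1, n_seg)),
        params={
            "view": "LAX",
            "scale": scale_t.tolist(),
            "semi_long": _LAX_SEMI_LONG,
            "semi_short": _LAX_SEMI_SHORT,
            "wall": _LAX_WALL,
        },
    )
    return seq, gt


def generate_phantom(spec: PhantomSpec) -> tuple[CineSequence, PhantomGroundTruth]:
    if spec.view == "SAX":
        return generate_sax_phantom(spec)
    return generate_lax_phantom(spec)
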