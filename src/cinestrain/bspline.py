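"""Cubic tensor-product B-spline deformation model.

The displacement at a physical point p is

    u(p) = sum_ij  beta3((px - ox)/hx - i) * beta3((py - oy)/hy - j) * c_ij

with c_ij the 2-vector control-point displacements (mm) on a regular
grid of spacing (hy, hx) mm.  The cubic basis has support 4, so each
point is influenced by its surrounding 4x4 control points; grids built
with :meth:`BSplineGrid.for_domain` carry the extra border control
points required for every point of the image domain to be spanned.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import DomainError, ValidationError


def bspline3(t: np.ndarray) -> np.ndarray:
    """Cubic B-spline basis function, support ``|t| < 2``."""
    t = np.abs(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    m1 = t <= 1.0
    out[m1] = 2.0 / 3.0 - t[m1] ** 2 + 0.5 * t[m1] ** 3
    m2 = (t > 1.0) & (t < 2.0)
    out[m2] = (2.0 - t[m2]) ** 3 / 6.0
    return out


@dataclass
class BSplineGrid:
    """Regular grid of control-point displacements (mm).

    ``coeffs`` has shape ``(2, ncy, ncx)``: component 0 is the
    x-displacement, component 1 the y-displacement.
    """

    coeffs: np.ndarray
    spacing: tuple[float, float]  # (hy, hx) mm
    origin: tuple[float, float]  # (oy, ox) mm, position of control point (0, 0)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 3 or self.coeffs.shape[0] != 2:
            raise ValidationError(
                f"coeffs must have shape (2, ncy, ncx); got {self.coeffs.shape}"
            )
        hy, hx = self.spacing
        if hy <= 0 or hx <= 0:
            raise ValidationError("grid spacing must be positive")

    # ------------------------------------------------------------------
    @classmethod
    def for_domain(
        cls,
        x_range: tuple[float, float],
        y_range: tuple[float, float],
        spacing: tuple[float, float],
    ) -> "BSplineGrid":
        """Zero grid spanning ``[x_min, x_max] x [y_min, y_max]`` (mm).

        Control points extend one cell beyond each edge so the cubic
        support of every domain point is fully populated.
        """
        hy, hx = spacing
        x0, x1 = x_range
        y0, y1 = y_range
        if x1 <= x0 or y1 <= y0:
            raise ValidationError("domain extents must be positive")
        ox = x0 - hx
        oy = y0 - hy
        ncx = int(np.ceil((x1 - x0) / hx)) + 4
        ncy = int(np.ceil((y1 - y0) / hy)) + 4
        return cls(np.zeros((2, ncy, ncx)), (hy, hx), (oy, ox))

    @property
    def n_control(self) -> tuple[int, int]:
        return self.coeffs.shape[1], self.coeffs.shape[2]

    def copy(self) -> "BSplineGrid":
        return replace(self, coeffs=self.coeffs.copy())

    # ------------------------------------------------------------------
    def _local(self, coords: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
        """Base control index and 4 basis weights along one axis.

        ``axis`` 0 = x (columns of coeffs), 1 = y (rows).
        """
        h = self.spacing[1 - axis]
        o = self.origin[1 - axis]
        nc = self.coeffs.shape[2 - axis]
        u = (np.asarray(coords, dtype=float) - o) / h
        i0 = np.floor(u).astype(int) - 1
        if np.any(i0 < 0) or np.any(i0 + 3 > nc - 1):
            raise DomainError("point outside the domain spanned by the control grid")
        offs = np.arange(4)
        w = bspline3(u[:, None] - (i0[:, None] + offs[None, :]))
        return i0, w

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Displacements (mm) at ``(N, 2)`` (x, y) mm points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        i0, wx = self._local(pts[:, 0], axis=0)
        j0, wy = self._local(pts[:, 1], axis=1)
        offs = np.arange(4)
        jj = j0[:, None, None] + offs[None, :, None]  # (N, 4, 1)
        ii = i0[:, None, None] + offs[None, None, :]  # (N, 1, 4)
        out = np.empty((pts.shape[0], 2))
        for c in range(2):
            patch = self.coeffs[c][jj, ii]  # (N, 4, 4)
            out[:, c] = np.einsum("nl,nk,nlk->n", wy, wx, patch)
        return out

    def basis_matrix(self, coords: np.ndarray, axis: int) -> np.ndarray:
        """Dense basis matrix ``B`` with ``B[p, i] = beta3(u_p - i)``.

        Row p corresponds to the p-th coordinate; columns run over all
        control points along the axis.  ``field = By @ C @ Bx.T``.
        """
        nc = self.coeffs.shape[2 - axis]
        i0, w = self._local(np.asarray(coords, dtype=float), axis)
        B = np.zeros((len(i0), nc))
        rows = np.arange(len(i0))[:, None]
        B[rows, i0[:, None] + np.arange(4)[None, :]] = w
        return B

    def dense_field(self, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
        """Displacement field ``(2, len(ys), len(xs))`` on a pixel grid."""
        Bx = self.basis_matrix(xs, axis=0)
        By = self.basis_matrix(ys, axis=1)
        return np.stack([By @ self.coeffs[c] @ Bx.T for c in range(2)])


# ----------------------------------------------------------------------
# Bending energy: integral of the squared second spatial derivatives of
# the displacement field, approximated by a knot-point Riemann sum.  At
# a knot, the spline's derivatives are exact 3x3 stencils of the control
# displacements: second difference [1, -2, 1]/h^2 along the derivative
# axis, B-spline smoothing [1/6, 4/6, 1/6] across it, and central
# differences [-1/2, 0, 1/2]/h for the mixed term.

_S2 = np.array([1.0, -2.0, 1.0])  # second difference
_S0 = np.array([1.0, 4.0, 1.0]) / 6.0  # cubic B-spline knot weights
_S1 = np.array([-0.5, 0.0, 0.5])  # central first difference


def _stencil_valid(C: np.ndarray, K: np.ndarray) -> np.ndarray:
    """3x3 correlation over interior knots (no padding)."""
    out = np.zeros((C.shape[0] - 2, C.shape[1] - 2))
    for a in range(3):
        for b in range(3):
            if K[a, b] != 0.0:
                out += K[a, b] * C[a : a + out.shape[0], b : b + out.shape[1]]
    return out


def _stencil_adjoint(D: np.ndarray, K: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape)
    for a in range(3):
        for b in range(3):
            if K[a, b] != 0.0:
                out[a : a + D.shape[0], b : b + D.shape[1]] += K[a, b] * D
    return out


def bending_energy(grid: BSplineGrid, gradient: bool = False):
    """Bending energy of the spline displacement field (and gradient).

    Zero for any affine displacement field, strictly positive otherwise;
    agrees with a dense finite-difference evaluation of the field's
    second derivatives sampled at the knots.
    """
    hy, hx = grid.spacing
    area = hx * hy
    Kxx = np.outer(_S0, _S2) / hx**2
    Kyy = np.outer(_S2, _S0) / hy**2
    Kxy = np.outer(_S1, _S1) / (hx * hy)
    energy = 0.0
    grad = np.zeros_like(grid.coeffs) if gradient else None
    for c in range(2):
        C = grid.coeffs[c]
        dxx = _stencil_valid(C, Kxx)
        dyy = _stencil_valid(C, Kyy)
        dxy = _stencil_valid(C, Kxy)
        energy += area * (np.sum(dxx**2) + np.sum(dyy**2) + 2.0 * np.sum(dxy**2))
        if gradient:
            g = _stencil_adjoint(2.0 * area * dxx, Kxx, C.shape)
            g += _stencil_adjoint(2.0 * area * dyy, Kyy, C.shape)
            g += _stencil_adjoint(4.0 * area * dxy, Kxy, C.shape)
            grad[c] = g
    if gradient:
        return energy, grad
    return energy
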