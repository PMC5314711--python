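"""Core containers shared across the feature-tracking pipeline.

Coordinate convention (used package-wide): positions are physical
millimetres with the origin at the image centre, x to the right along
image columns and y downward along image rows.  Pixel ``(row, col)``
therefore sits at ``x = (col - (nx-1)/2) * sx`` and
``y = (row - (ny-1)/2) * sy``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class DomainError(ValueError):
    """Raised when a query point falls outside a spanned domain."""


@dataclass
class CineSequence:
    """One slice's 2D+t cine frames with acquisition geometry.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, ny, nx)``, arbitrary intensity units.
    pixel_spacing
        ``(sy, sx)`` in mm.
    frame_times
        Acquisition time of each frame in seconds, strictly increasing.
    view
        ``"SAX"`` or ``"LAX"``.
    slice_id
        Free-form slice identifier.
    """

    frames: np.ndarray
    pixel_spacing: tuple[float, float]
    frame_times: np.ndarray
    view: str = "SAX"
    slice_id: str = "slice0"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3:
            raise ValidationError(
                f"frames must be (n_frames, ny, nx); got shape {self.frames.shape}"
            )
        if self.n_frames < 2:
            raise ValidationError("a cine sequence needs at least 2 frames")
        if len(self.frame_times) != self.n_frames:
            raise ValidationError("frame_times length must match n_frames")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValidationError("frame_times must be strictly increasing")
        sy, sx = self.pixel_spacing
        if sy <= 0 or sx <= 0:
            raise ValidationError("pixel spacing must be positive")
        if self.view not in ("SAX", "LAX"):
            raise ValidationError(f"view must be 'SAX' or 'LAX', got {self.view!r}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def pixel_coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(ys, xs)`` coordinate vectors of pixel centres in mm."""
        ny, nx = self.shape
        sy, sx = self.pixel_spacing
        ys = (np.arange(ny) - (ny - 1) / 2.0) * sy
        xs = (np.arange(nx) - (nx - 1) / 2.0) * sx
        return ys, xs

    def mm_to_index(self, points: np.ndarray) -> np.ndarray:
        """Convert ``(N, 2)`` (x, y) mm points to fractional (row, col)."""
        ny, nx = self.shape
        sy, sx = self.pixel_spacing
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rows = pts[:, 1] / sy + (ny - 1) / 2.0
        cols = pts[:, 0] / sx + (nx - 1) / 2.0
        return np.column_stack([rows, cols])


@dataclass
class DeformationField:
    """Dense displacement field on a pixel grid, in mm.

    ``disp[0]`` is the x-displacement and ``disp[1]`` the y-displacement,
    each of shape ``(ny, nx)``.  A zero field is the identity transform.
    """

    disp: np.ndarray
    pixel_spacing: tuple[float, float]

    def __post_init__(self) -> None:
        self.disp = np.asarray(self.disp, dtype=float)
        if self.disp.ndim != 3 or self.disp.shape[0] != 2:
            raise ValidationError(
                f"disp must have shape (2, ny, nx); got {self.disp.shape}"
            )
        if not np.all(np.isfinite(self.disp)):
            raise ValidationError("deformation field must be finite everywhere")

    @property
    def shape(self) -> tuple[int, int]:
        return self.disp.shape[1], self.disp.shape[2]

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.disp[0], self.disp[1])
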