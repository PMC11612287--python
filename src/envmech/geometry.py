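"""Spherocylindrical (capsule) cell geometry in the image plane.

All lengths are in nanometres. The cell is a rod of total pole-to-pole
length ``length`` with hemispherical caps of radius ``radius``, lying in the
image plane with its long axis at ``orientation`` radians from the x axis.
The axial coordinate is the signed distance from the cell midpoint along the
axis, so the poles sit at +/- length/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CellGeometry", "make_geometry"]

NM_PER_UM = 1e3
NM2_PER_UM2 = 1e6


@dataclass(frozen=True)
class CellGeometry:
    """Spherocylinder lying in the image plane.

    Parameters
    ----------
    length : float
        Pole-to-pole length in nm. Must satisfy ``length >= 2 * radius``.
    radius : float
        Cap (and half-width) radius in nm.
    center : tuple of float
        Midpoint (x, y) in image-frame nm.
    orientation : float
        Axis angle in radians, normalized to [0, pi).
    """

    length: float
    radius: float
    center: tuple[float, float] = (0.0, 0.0)
    orientation: float = 0.0
    cap_model: str = field(default="hemispherical")

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        if self.length < 2 * self.radius:
            raise ValueError(
                f"length ({self.length}) must be >= 2*radius ({2 * self.radius})"
            )
        object.__setattr__(self, "orientation", float(self.orientation) % np.pi)

    # -- frames -------------------------------------------------------------

    @property
    def half_core(self) -> float:
        """Half-length of the cylindrical core (axial position of cap centers)."""
        return self.length / 2.0 - self.radius

    @property
    def axis_unit(self) -> np.ndarray:
        return np.array([np.cos(self.orientation), np.sin(self.orientation)])

    def to_cell_frame(self, points: np.ndarray) -> np.ndarray:
        """Map image-frame (x, y) nm points to (axial, transverse) nm.

        The axial coordinate is signed distance from the midpoint along the
        axis; poles are at +/- length/2.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(self.center)
        u = self.axis_unit
        n = np.array([-u[1], u[0]])
        return np.column_stack([pts @ u, pts @ n])

    def to_image_frame(self, cell_points: np.ndarray) -> np.ndarray:
        cp = np.atleast_2d(np.asarray(cell_points, dtype=float))
        u = self.axis_unit
        n = np.array([-u[1], u[0]])
        return cp[:, :1] * u + cp[:, 1:2] * n + np.asarray(self.center)

    # -- footprint ----------------------------------------------------------

    def distance_to_axis(self, points: np.ndarray) -> np.ndarray:
        """Distance from image-frame points to the core axis segment."""
        cf = self.to_cell_frame(points)
        s = np.clip(cf[:, 0], -self.half_core, self.half_core)
        return np.hypot(cf[:, 0] - s, cf[:, 1])

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: points inside the projected footprint."""
        return self.distance_to_axis(points) <= self.radius

    @property
    def footprint_area_nm2(self) -> float:
        """Projected 2D footprint area (rectangle plus two half-disks)."""
        return 2 * self.radius * (self.length - 2 * self.radius) + np.pi * self.radius**2

    @property
    def footprint_area_um2(self) -> float:
        return self.footprint_area_nm2 / NM2_PER_UM2

    def surface_height(self, points: np.ndarray) -> np.ndarray:
        """Topographic height of the cell surface above the substrate.

        For a capsule resting on the substrate the apex is at 2*radius:
        h = r + sqrt(r^2 - d^2) for axis distance d < r, 0 outside.
        """
        d = self.distance_to_axis(points)
        h = np.zeros_like(d)
        inside = d < self.radius
        h[inside] = self.radius + np.sqrt(self.radius**2 - d[inside] ** 2)
        return h

    # -- axial banding ------------------------------------------------------

    def axial_band_area_nm2(self, lo: float, hi: float) -> float:
        """Projected footprint area with |axial coordinate| in [lo, hi).

        Both cell halves contribute (the axial bin coordinate is the absolute
        distance from midpoint). Bands intersecting the caps pick up circular
        segment areas.
        """
        if not 0 <= lo < hi:
            raise ValueError("need 0 <= lo < hi")
        hi = min(hi, self.length / 2.0)
        if hi <= lo:
            return 0.0
        c, r = self.half_core, self.radius
        # cylindrical part: |s| in [lo, min(hi, c)), width 2r
        area = 0.0
        if lo < c:
            area += 2 * r * (min(hi, c) - lo)
        # cap part: |s| in [max(lo, c), hi), half-width sqrt(r^2 - (s-c)^2)
        a, b = max(lo, c) - c, hi - c
        if b > a >= 0:

            def antider(u: float) -> float:
                u = min(u, r)
                return u * np.sqrt(max(r**2 - u**2, 0.0)) + r**2 * np.arcsin(
                    min(u / r, 1.0)
                )

            area += antider(b) - antider(a)
        return 2.0 * area  # both halves

    # -- sampling -----------------------------------------------------------

    def sample_footprint(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n points uniformly over the projected footprint (image frame)."""
        if n == 0:
            return np.empty((0, 2))
        out = np.empty((0, 2))
        c, r = self.half_core, self.radius
        while len(out) < n:
            m = max(2 * (n - len(out)), 16)
            s = rng.uniform(-c - r, c + r, m)
            t = rng.uniform(-r, r, m)
            keep = np.hypot(np.clip(np.abs(s) - c, 0, None), t) <= r
            out = np.vstack([out, np.column_stack([s[keep], t[keep]])])
        return self.to_image_frame(out[:n])


def make_geometry(
    length: float,
    radius: float,
    orientation: float = 0.0,
    center: tuple[float, float] = (0.0, 0.0),
) -> CellGeometry:
    """Validate and build a :class:`CellGeometry` (lengths in nm)."""
    if length <= 0 or radius <= 0:
        raise ValueError("length and radius must be positive")
    return CellGeometry(
        length=float(length),
        radius=float(radius),
        center=tuple(center),
        orientation=float(orientation),
    )
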