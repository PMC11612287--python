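"""AFM height/phase image conditioning and roughness quantification.

Implements the conditioning chain used for AFM topography of bacterial
surfaces: masked plane levelling for large scans, per-row polynomial
alignment and light Gaussian smoothing for small scans, and an iterative
"flatten base" background fit that levels the substrate while preserving
protruding features (cells, pores). Roughness is reported as the RMS height
deviation of a (re-aligned) crop, and line profiles provide feature-height
readouts such as the ~3 nm protrusion of membrane attack complex rims.

Height values are in nm (phase images carry degrees through unchanged);
pixel size is in nm. Masks mark pixels *excluded* from fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "HeightMap",
    "Profile",
    "plane_level",
    "align_rows",
    "flatten_base",
    "smooth",
    "rms_roughness",
    "extract_profile",
    "feature_protrusion",
]


@dataclass
class HeightMap:
    """Calibrated 2D topography (nm) or phase (degrees) grid.

    ``mask`` marks pixels excluded from background fits (True = excluded).
    Image-frame coordinates are x = col * pixel_size, y = row * pixel_size,
    with values at pixel centers and the origin at pixel (0, 0).
    """

    values: np.ndarray
    pixel_size: float
    channel: str = "height"
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D grid")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must equal values shape")
        if not np.isfinite(self.values[self.included]).all():
            raise ValueError("non-finite values outside the mask")

    @property
    def included(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.values.shape, dtype=bool)
        return ~self.mask

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def crop(self, region: tuple[int, int, int, int]) -> "HeightMap":
        """Crop to (row0, row1, col0, col1), half-open in pixels."""
        r0, r1, c0, c1 = region
        nr, nc = self.values.shape
        if not (0 <= r0 < r1 <= nr and 0 <= c0 < c1 <= nc):
            raise ValueError(f"region {region} outside image of shape {self.shape}")
        m = None if self.mask is None else self.mask[r0:r1, c0:c1].copy()
        return replace(self, values=self.values[r0:r1, c0:c1].copy(), mask=m)


@dataclass
class Profile:
    """Height profile along a line: positions (nm, from the first endpoint)."""

    positions: np.ndarray
    heights: np.ndarray
    line: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.positions.shape != self.heights.shape:
            raise ValueError("positions and heights must have the same length")
        if len(self.positions) > 1 and not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")


# ---------------------------------------------------------------------------
# plane levelling


def _fit_plane(values: np.ndarray, include: np.ndarray) -> np.ndarray:
    """Least-squares plane a + b*x + c*y over included pixels, evaluated everywhere."""
    nr, nc = values.shape
    yy, xx = np.mgrid[0:nr, 0:nc]
    A = np.column_stack(
        [np.ones(include.sum()), xx[include], yy[include]]
    )
    coef, *_ = np.linalg.lstsq(A, values[include], rcond=None)
    return coef[0] + coef[1] * xx + coef[2] * yy


def high_pixel_mask(values: np.ndarray, k: float = 2.0) -> np.ndarray:
    """Pixels above median + k * robust SD (1.4826 * MAD), to exclude from fits."""
    med = np.median(values)
    sd = 1.4826 * np.median(np.abs(values - med))
    return values > med + k * sd


def plane_level(hmap: HeightMap, mask_high: bool = True, k_high: float = 2.0) -> HeightMap:
    """Subtract the least-squares plane fitted over background pixels.

    With ``mask_high`` (the treatment used for large scans where cells
    protrude far above the substrate), pixels above median + ``k_high``
    robust SDs are excluded from the fit; the plane is subtracted from all
    pixels.
    """
    include = hmap.included.copy()
    if mask_high:
        include &= ~high_pixel_mask(hmap.values, k_high)
        if include.sum() < 3:  # threshold degenerate; fall back to the full mask
            include = hmap.included.copy()
    if include.sum() < 3:
        raise ValueError("fewer than 3 unmasked pixels for the plane fit")
    plane = _fit_plane(hmap.values, include)
    return replace(hmap, values=hmap.values - plane)


def align_rows(hmap: HeightMap, order: int = 2) -> HeightMap:
    """Subtract a per-row polynomial (default 2nd order) fitted on unmasked pixels.

    Rows with fewer unmasked pixels than ``order + 1`` are left unchanged.
    """
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    out = hmap.values.copy()
    include = hmap.included
    nc = out.shape[1]
    x = np.linspace(-1.0, 1.0, nc) if nc > 1 else np.zeros(1)
    for i in range(out.shape[0]):
        sel = include[i]
        if sel.sum() < order + 1:
            logger.warning("align_rows: row %d has too few unmasked pixels; skipped", i)
            continue
        coef = np.polynomial.polynomial.polyfit(x[sel], out[i, sel], order)
        out[i] -= np.polynomial.polynomial.polyval(x, coef)
    return replace(hmap, values=out)


def flatten_base(
    hmap: HeightMap,
    k_sd: float = 1.0,
    max_iter: int = 10,
    tol: float = 0.01,
) -> HeightMap:
    """Iterative background flattening (plane + per-row offsets on substrate pixels).

    Starting from all unmasked pixels, a plane plus per-row constant offsets
    is fitted to the current background set; pixels within ``k_sd`` robust
    SDs (1.4826 * MAD of the residual over all unmasked pixels, so features
    cannot inflate the scale and noise cannot shrink it) are re-selected and
    the fit repeated until the background set stabilizes, its robust SD
    changes by less than ``tol`` (relative), or ``max_iter`` iterations.
    Protruding features (cells, pores) are excluded from the background
    within a couple of iterations and therefore preserved, in height above
    the levelled substrate.
    """
    if hmap.included.sum() < 3:
        raise ValueError("fewer than 3 unmasked pixels")
    bg = hmap.included.copy()
    prev_sd = None
    resid = hmap.values.copy()
    for it in range(max_iter):
        plane = _fit_plane(hmap.values, bg)
        r = hmap.values - plane
        offsets = np.zeros(r.shape[0])
        for i in range(r.shape[0]):
            if bg[i].any():
                offsets[i] = r[i, bg[i]].mean()
        resid = r - offsets[:, None]
        inc = resid[hmap.included]
        sd = 1.4826 * np.median(np.abs(inc - np.median(inc)))
        if sd == 0:
            break
        new_bg = hmap.included & (np.abs(resid) < k_sd * sd)
        if new_bg.sum() < 3:
            break
        converged = (new_bg == bg).all() or (
            prev_sd is not None and abs(sd - prev_sd) < tol * prev_sd
        )
        bg = new_bg
        if converged:
            break
        prev_sd = sd
    else:
        logger.warning("flatten_base: no convergence after %d iterations", max_iter)
    return replace(hmap, values=resid)


def smooth(hmap: HeightMap, sigma_px: float = 1.0) -> HeightMap:
    """Gaussian smoothing (sigma in pixels, reflective boundaries)."""
    if sigma_px < 0:
        raise ValueError("sigma_px must be non-negative")
    if sigma_px == 0:
        return replace(hmap, values=hmap.values.copy())
    return replace(
        hmap, values=ndimage.gaussian_filter(hmap.values, sigma_px, mode="reflect")
    )


# ---------------------------------------------------------------------------
# quantification


def rms_roughness(
    hmap: HeightMap,
    region: tuple[int, int, int, int] | None = None,
    realign: bool = True,
) -> float:
    """RMS height deviation of a crop, by default after 2nd-order row alignment.

    This is the roughness readout used to quantify surface disruption: crop
    to a well-imaged region, align rows with a 2nd-order polynomial, and take
    the root mean square deviation from the crop mean.
    """
    crop = hmap.crop(region) if region is not None else hmap
    if realign:
        crop = align_rows(crop, order=2)
    v = crop.values[crop.included]
    return float(np.sqrt(np.mean((v - v.mean()) ** 2)))


def extract_profile(
    hmap: HeightMap,
    line: tuple[tuple[float, float], tuple[float, float]],
    width_px: int = 1,
) -> Profile:
    """Bilinear line profile between two image-frame (x, y) nm endpoints.

    ``width_px > 1`` averages that many parallel lines offset perpendicular
    to the profile at 1-pixel spacing.
    """
    (x0, y0), (x1, y1) = line
    px = hmap.pixel_size
    nr, nc = hmap.shape
    for x, y in ((x0, y0), (x1, y1)):
        if not (0 <= x <= (nc - 1) * px and 0 <= y <= (nr - 1) * px):
            raise ValueError(f"endpoint ({x}, {y}) nm outside image")
    length = float(np.hypot(x1 - x0, y1 - y0))
    n = max(int(np.ceil(length / px)) + 1, 2)
    t = np.linspace(0.0, 1.0, n)
    xs = x0 + t * (x1 - x0)
    ys = y0 + t * (y1 - y0)
    if length > 0:
        perp = np.array([-(y1 - y0), x1 - x0]) / length
    else:
        perp = np.array([0.0, 0.0])
    offsets = (np.arange(width_px) - (width_px - 1) / 2.0) * px
    acc = np.zeros(n)
    for off in offsets:
        cx = (xs + off * perp[0]) / px
        cy = (ys + off * perp[1]) / px
        acc += ndimage.map_coordinates(
            hmap.values, np.vstack([cy, cx]), order=1, mode="nearest"
        )
    return Profile(positions=t * length, heights=acc / width_px, line=line)


def feature_protrusion(profile: Profile, peak_window: float) -> float:
    """Peak height above flanking background along a profile.

    The background is the median of the profile outside ``peak_window`` nm
    (total width) centred on the maximum; the return value is max minus
    background. Operationalizes the line-profile feature-height readout.
    """
    i_max = int(np.argmax(profile.heights))
    outside = np.abs(profile.positions - profile.positions[i_max]) > peak_window / 2.0
    if not outside.any():
        raise ValueError("peak window covers the whole profile")
    background = float(np.median(profile.heights[outside]))
    return float(profile.heights[i_max] - background)
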