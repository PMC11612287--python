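"""Spatial statistics of membrane attack complex (MAC) positions.

MAC pores picked on an imaged cell region are treated as a planar point
pattern. The module quantifies their axial distribution along the cell
(five equal-width bins from midpoint to pole, normalized to band footprint
area), nearest-neighbour distances, the pair distribution function g(r)
with per-point edge correction, and chain/cluster structure via
dilate-skeletonize-longest-branch. Observed patterns are compared against a
random-deposition (complete spatial randomness, CSR) null by drawing
replicate uniform patterns with the same point count over the same region
and placing each observed statistic within the null distribution.

Lengths in nm; areas exposed in um^2 at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from scipy.stats import chi2 as chi2_dist
from skimage.morphology import disk, skeletonize

from .geometry import NM2_PER_UM2, CellGeometry

__all__ = [
    "Region",
    "CapsuleRegion",
    "RectRegion",
    "PolygonRegion",
    "PointPattern",
    "PairDistribution",
    "SpatialSummary",
    "axial_density",
    "nn_distances",
    "pair_distribution",
    "csr_replicates",
    "chain_stats",
    "summarize_pattern",
    "csr_compare",
]


# ---------------------------------------------------------------------------
# regions


class Region:
    """Observation window for a point pattern (image-frame nm coordinates)."""

    @property
    def area_nm2(self) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def contains(self, points: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def bbox(self) -> tuple[float, float, float, float]:  # pragma: no cover
        """(xmin, xmax, ymin, ymax) in nm."""
        raise NotImplementedError

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n uniform points by rejection from the bounding box."""
        if self.area_nm2 <= 0:
            raise ValueError("cannot sample from a zero-area region")
        if n == 0:
            return np.empty((0, 2))
        xmin, xmax, ymin, ymax = self.bbox
        out = np.empty((0, 2))
        while len(out) < n:
            m = max(4 * (n - len(out)), 16)
            pts = np.column_stack(
                [rng.uniform(xmin, xmax, m), rng.uniform(ymin, ymax, m)]
            )
            out = np.vstack([out, pts[self.contains(pts)]])
        return out[:n]


class CapsuleRegion(Region):
    """Projected spherocylinder footprint of a cell."""

    def __init__(self, geometry: CellGeometry):
        self.geometry = geometry

    @property
    def area_nm2(self) -> float:
        return self.geometry.footprint_area_nm2

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.geometry.contains(points)

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        g = self.geometry
        pad = g.length / 2.0
        cx, cy = g.center
        return (cx - pad, cx + pad, cy - pad, cy + pad)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.geometry.sample_footprint(n, rng)


class RectRegion(Region):
    """Axis-aligned rectangle [x0, x1] x [y0, y1] nm."""

    def __init__(self, x0: float, x1: float, y0: float, y1: float):
        if x1 <= x0 or y1 <= y0:
            raise ValueError("degenerate rectangle")
        self.x0, self.x1, self.y0, self.y1 = x0, x1, y0, y1

    @property
    def area_nm2(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return (
            (p[:, 0] >= self.x0)
            & (p[:, 0] <= self.x1)
            & (p[:, 1] >= self.y0)
            & (p[:, 1] <= self.y1)
        )

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        return (self.x0, self.x1, self.y0, self.y1)


class PolygonRegion(Region):
    """Arbitrary polygon region (vertices in nm), backed by shapely."""

    def __init__(self, vertices: np.ndarray):
        import shapely

        self.vertices = np.asarray(vertices, dtype=float)
        self._poly = shapely.Polygon(self.vertices)
        if not self._poly.is_valid or self._poly.area <= 0:
            raise ValueError("invalid polygon")

    @property
    def area_nm2(self) -> float:
        return float(self._poly.area)

    def contains(self, points: np.ndarray) -> np.ndarray:
        import shapely

        p = np.atleast_2d(points)
        return shapely.contains_xy(self._poly.buffer(1e-9), p[:, 0], p[:, 1])

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        xmin, ymin, xmax, ymax = self._poly.bounds
        return (xmin, xmax, ymin, ymax)


# ---------------------------------------------------------------------------
# pattern containers


@dataclass
class PointPattern:
    """MAC coordinates on an imaged region with its area and cell frame."""

    points: np.ndarray
    region: Region
    geometry: CellGeometry | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(self.points) and not self.region.contains(self.points).all():
            raise ValueError("all points must lie inside the region")

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def area_um2(self) -> float:
        return self.region.area_nm2 / NM2_PER_UM2

    @property
    def intensity_per_um2(self) -> float:
        return self.n / self.area_um2


@dataclass
class PairDistribution:
    """Binned pair distribution function with its normalization bookkeeping."""

    r_centers: np.ndarray
    g: np.ndarray
    pair_counts: np.ndarray  # ordered pair counts per bin
    expected: np.ndarray  # CSR-expected ordered pair counts (edge corrected)


@dataclass
class SpatialSummary:
    """Per-pattern summaries feeding the CSR comparison."""

    n: int
    nn: np.ndarray | None = None
    g_r: PairDistribution | None = None
    axial_counts: np.ndarray | None = None
    axial_areas_um2: np.ndarray | None = None
    axial_densities: np.ndarray | None = None
    chain_lengths: np.ndarray | None = None
    stats: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# operations


def axial_density(
    pattern: PointPattern,
    geometry: CellGeometry | None = None,
    n_bins: int = 5,
) -> np.ndarray:
    """Point density (count/um^2) in equal axial bins from midpoint to pole.

    The axial coordinate of each point is the absolute signed distance from
    the cell midpoint along the axis; bins are half-open [lo, hi) on
    [0, length/2] (the last bin closes at the pole) and each count is
    normalized to the projected footprint area of its band.
    """
    geometry = geometry or pattern.geometry
    if geometry is None:
        raise ValueError("axial_density requires a cell geometry")
    edges = np.linspace(0.0, geometry.length / 2.0, n_bins + 1)
    if pattern.n:
        s = np.abs(geometry.to_cell_frame(pattern.points)[:, 0])
        counts, _ = np.histogram(s, bins=edges)
    else:
        counts = np.zeros(n_bins, dtype=int)
    areas = np.array(
        [geometry.axial_band_area_nm2(lo, hi) for lo, hi in zip(edges[:-1], edges[1:])]
    )
    return counts / (areas / NM2_PER_UM2)


def nn_distances(
    pattern: PointPattern, torus: tuple[float, float] | None = None
) -> np.ndarray:
    """Euclidean nearest-neighbour distance for every point (nm).

    ``torus=(Lx, Ly)`` wraps distances periodically, for comparisons against
    the unbounded-Poisson closed form mean 1/(2*sqrt(lambda)).
    """
    if pattern.n < 2:
        raise ValueError("nearest neighbours need at least 2 points")
    if torus is not None:
        pts = np.mod(pattern.points, torus)
        tree = cKDTree(pts, boxsize=torus)
    else:
        tree = cKDTree(pattern.points)
    d, _ = tree.query(tree.data, k=2)
    return d[:, 1]


def _annulus_region_areas(
    points: np.ndarray,
    region: Region,
    edges: np.ndarray,
    n_radial: int = 4,
    n_angular: int = 64,
) -> np.ndarray:
    """area(annulus(p, r_k, r_{k+1}) ∩ region) for all points and bins (nm^2).

    Quadrature: for sub-radii within each annulus, the fraction of a circle of
    that radius lying inside the region is estimated from n_angular points and
    integrated over 2*pi*rho d rho (midpoint rule).
    """
    n = len(points)
    nb = len(edges) - 1
    sub = (np.arange(n_radial) + 0.5) / n_radial
    radii = edges[:-1, None] + sub[None, :] * np.diff(edges)[:, None]  # (nb, nr)
    widths = (np.diff(edges) / n_radial)[:, None] * np.ones_like(radii)
    ang = 2 * np.pi * (np.arange(n_angular) + 0.5) / n_angular
    ring = np.column_stack([np.cos(ang), np.sin(ang)])  # (na, 2)
    flat_r = radii.ravel()  # (nb*nr,)
    # sample points: (n, nb*nr, na, 2)
    samples = (
        points[:, None, None, :]
        + flat_r[None, :, None, None] * ring[None, None, :, :]
    )
    inside = region.contains(samples.reshape(-1, 2)).reshape(n, len(flat_r), n_angular)
    frac = inside.mean(axis=2)  # (n, nb*nr)
    contrib = (2 * np.pi * flat_r * widths.ravel())[None, :] * frac
    return contrib.reshape(n, nb, n_radial).sum(axis=2)


def pair_distribution(
    pattern: PointPattern,
    r_max: float,
    dr: float,
    n_radial: int = 4,
    n_angular: int = 64,
) -> PairDistribution:
    """Pair distribution function g(r) with per-point edge correction.

    For each annulus [r_k, r_k + dr) the ordered pair count is divided by the
    CSR expectation lambda * sum_i area(annulus_i ∩ region), so that g -> 1
    at large r for random patterns and the total pair count is recovered from
    sum_k g_k * expected_k by construction.
    """
    if dr <= 0 or r_max <= dr:
        raise ValueError("need dr > 0 and r_max > dr")
    edges = np.arange(0.0, r_max + dr / 2, dr)
    centers = 0.5 * (edges[:-1] + edges[1:])
    nb = len(centers)
    if pattern.n < 2:
        zero = np.zeros(nb)
        return PairDistribution(centers, zero, zero.copy(), zero.copy())
    d = cdist(pattern.points, pattern.points)
    np.fill_diagonal(d, np.inf)
    counts, _ = np.histogram(d[np.isfinite(d)], bins=edges)
    lam = pattern.n / pattern.region.area_nm2  # points per nm^2
    areas = _annulus_region_areas(
        pattern.points, pattern.region, edges, n_radial, n_angular
    )
    expected = lam * areas.sum(axis=0)  # ordered pairs
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(expected > 0, counts / expected, 0.0)
    return PairDistribution(centers, g, counts.astype(float), expected)


def csr_replicates(
    pattern: PointPattern, n_reps: int = 5, seed: int | None = None
) -> list[PointPattern]:
    """Uniform random patterns with the observed point count over the same region.

    This is the random-deposition null: the same number of coordinates as
    observed MACs, drawn uniformly over the same area, ``n_reps`` times.
    """
    rng = np.random.default_rng(seed)
    return [
        PointPattern(
            points=pattern.region.sample(pattern.n, rng),
            region=pattern.region,
            geometry=pattern.geometry,
        )
        for _ in range(n_reps)
    ]


def chain_stats(
    pattern: PointPattern,
    dilation_radius: float = 25.0,
    pixel_size: float = 10.0,
) -> np.ndarray:
    """Longest skeleton branch length (nm) per chain of merged points.

    Points are rasterized, dilated by a disk of ``dilation_radius`` so close
    points merge into continuous shapes, and skeletonized; for each connected
    component the geodesic diameter of its skeleton (longest shortest path,
    8-connected with diagonal steps weighted sqrt(2)) is reported. Isolated
    points give lengths near zero.
    """
    if dilation_radius < pixel_size:
        raise ValueError("dilation_radius must be >= pixel_size")
    if pattern.n == 0:
        return np.array([])
    r_px = max(int(round(dilation_radius / pixel_size)), 1)
    pts = pattern.points
    mins = pts.min(axis=0) - 2 * dilation_radius
    ij = np.round((pts - mins) / pixel_size).astype(int)
    shape = ij.max(axis=0) + int(np.ceil(2 * dilation_radius / pixel_size)) + 2
    img = np.zeros((shape[1], shape[0]), dtype=bool)  # rows = y
    img[ij[:, 1], ij[:, 0]] = True
    from scipy.ndimage import binary_dilation

    img = binary_dilation(img, structure=disk(r_px))
    skel = skeletonize(img)
    rows, cols = np.nonzero(skel)
    if len(rows) == 0:
        return np.zeros(1)
    idx = {(r, c): i for i, (r, c) in enumerate(zip(rows, cols))}
    data, ii, jj = [], [], []
    for (r, c), i in idx.items():
        for drr, dcc in ((0, 1), (1, 0), (1, 1), (1, -1)):
            j = idx.get((r + drr, c + dcc))
            if j is not None:
                w = pixel_size * (np.sqrt(2.0) if drr and dcc else 1.0)
                data += [w, w]
                ii += [i, j]
                jj += [j, i]
    graph = sparse.csr_matrix(
        (data, (ii, jj)), shape=(len(rows), len(rows))
    )
    n_comp, labels = connected_components(graph, directed=False)
    # double-sweep geodesic diameter per component, two batched Dijkstra passes
    firsts = np.array(
        [np.nonzero(labels == c)[0][0] for c in range(n_comp)], dtype=int
    )
    d1 = dijkstra(graph, directed=False, indices=firsts)
    ends = np.empty(n_comp, dtype=int)
    for c in range(n_comp):
        in_c = labels == c
        row = np.where(in_c, d1[c], -np.inf)
        ends[c] = int(np.argmax(row))
    d2 = dijkstra(graph, directed=False, indices=ends)
    lengths = np.empty(n_comp)
    for c in range(n_comp):
        in_c = labels == c
        row = np.where(in_c, d2[c], -np.inf)
        lengths[c] = row.max()
    return lengths


# ---------------------------------------------------------------------------
# CSR comparison


def summarize_pattern(
    pattern: PointPattern,
    r_max: float = 100.0,
    dr: float = 25.0,
    g_small_r: float = 50.0,
    dilation_radius: float = 25.0,
    chain_pixel_size: float = 10.0,
    include: Sequence[str] = ("nn", "g", "chain", "axial"),
    n_axial_bins: int = 5,
) -> SpatialSummary:
    """Compute the per-pattern statistics used by :func:`csr_compare`.

    Scalar statistics derived: ``mean_nn`` (nm), ``g_small`` (mean g at
    r <= g_small_r), ``max_chain`` (nm).
    """
    s = SpatialSummary(n=pattern.n)
    if "nn" in include and pattern.n >= 2:
        s.nn = nn_distances(pattern)
        s.stats["mean_nn"] = float(s.nn.mean())
    if "g" in include and pattern.n >= 2:
        s.g_r = pair_distribution(pattern, r_max=r_max, dr=dr)
        small = s.g_r.r_centers <= g_small_r
        s.stats["g_small"] = float(s.g_r.g[small].mean()) if small.any() else np.nan
    if "chain" in include and pattern.n >= 1:
        s.chain_lengths = chain_stats(pattern, dilation_radius, chain_pixel_size)
        s.stats["max_chain"] = float(s.chain_lengths.max())
    if "axial" in include and (pattern.geometry is not None):
        geometry = pattern.geometry
        edges = np.linspace(0.0, geometry.length / 2.0, n_axial_bins + 1)
        if pattern.n:
            ax = np.abs(geometry.to_cell_frame(pattern.points)[:, 0])
            counts, _ = np.histogram(ax, bins=edges)
        else:
            counts = np.zeros(n_axial_bins, dtype=int)
        areas = np.array(
            [
                geometry.axial_band_area_nm2(lo, hi) / NM2_PER_UM2
                for lo, hi in zip(edges[:-1], edges[1:])
            ]
        )
        s.axial_counts = counts
        s.axial_areas_um2 = areas
        s.axial_densities = counts / areas
    return s


def _empirical_p(obs: float, null: np.ndarray) -> float:
    """Two-sided empirical p with the (r+1)/(m+1) correction."""
    m = len(null)
    p_low = (np.sum(null <= obs) + 1) / (m + 1)
    p_high = (np.sum(null >= obs) + 1) / (m + 1)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def csr_compare(
    observed: SpatialSummary, nulls: Sequence[SpatialSummary]
) -> dict:
    """Place observed statistics within the CSR null distribution.

    For each scalar statistic shared by the observed summary and the null
    replicates, the report carries the observed value, the null mean +/- SD,
    a z-score, and a two-sided empirical p-value with the (r+1)/(m+1)
    correction. Axial bin counts are additionally tested against the
    area-proportional expectation with a chi-squared test on n_bins - 1
    degrees of freedom.
    """
    if len(nulls) < 2:
        raise ValueError("need at least 2 null replicates")
    if any(nl.n != observed.n for nl in nulls):
        raise ValueError("null replicates must match the observed point count")
    report: dict = {"n_points": observed.n, "n_reps": len(nulls), "statistics": {}}
    for name, obs in observed.stats.items():
        null_vals = np.array([nl.stats[name] for nl in nulls if name in nl.stats])
        if len(null_vals) < 2 or not np.isfinite(obs):
            continue
        sd = float(null_vals.std(ddof=1))
        report["statistics"][name] = {
            "observed": float(obs),
            "null_mean": float(null_vals.mean()),
            "null_sd": sd,
            "z": float((obs - null_vals.mean()) / sd) if sd > 0 else np.nan,
            "p_empirical": _empirical_p(obs, null_vals),
        }
    if observed.axial_counts is not None:
        counts = observed.axial_counts
        areas = observed.axial_areas_um2
        total = counts.sum()
        if total > 0:
            expected = total * areas / areas.sum()
            stat = float(((counts - expected) ** 2 / expected).sum())
            df = len(counts) - 1
            report["axial_chi2"] = {
                "statistic": stat,
                "df": df,
                "p": float(chi2_dist.sf(stat, df)),
                "counts": counts.tolist(),
                "expected": expected.tolist(),
            }
    return report
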