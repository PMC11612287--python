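"""Force-curve processing and Hertzian surface mechanics.

Processes approach force curves and quantitative-imaging (QI) force maps:
constant baseline from the far-from-surface tail, contact-point detection as
the first sustained deviation from the zero-force line, conversion of piezo
position to indentation by correcting for cantilever bending, and a
least-squares fit of the Hertz sphere-on-half-space model

    F = (4/3) * E / (1 - nu^2) * sqrt(R_tip) * delta^(3/2)

yielding an effective Young's modulus E. Per-pixel processing of QI maps
gives un-indented height maps (contact point above a substrate reference)
and stiffness maps; time series of maps quantify swelling (relative height
change) and stiffening, including plateau detection after inner-membrane
permeation.

Units: force pN, stiffness kPa, lengths nm, spring constant N/m
(1 N/m = 1000 pN/nm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

__all__ = [
    "ForceCurve",
    "IndentationCurve",
    "MechModel",
    "QIMap",
    "MechSeries",
    "NoContactError",
    "hertz_force",
    "baseline_correct",
    "find_contact",
    "to_indentation",
    "fit_hertz",
    "process_qi_map",
    "height_from_profile",
    "analyze_timeseries",
    "relative_change",
    "plateau_detect",
]

PN_PER_NM_PER_N_PER_M = 1e-3  # deflection nm = force pN / k N/m * 1e-3


class NoContactError(RuntimeError):
    """Raised when no sustained deviation from the zero-force line is found."""


def hertz_force(
    delta_nm: np.ndarray | float, e_kpa: float, r_tip_nm: float, nu: float = 0.5
) -> np.ndarray | float:
    """Hertz sphere-indentation force (pN) at indentation delta (nm)."""
    delta = np.clip(delta_nm, 0.0, None)
    return (4.0 / 3.0) * (e_kpa / (1.0 - nu**2)) * np.sqrt(r_tip_nm) * delta**1.5 * 1e-3


# ---------------------------------------------------------------------------
# containers


@dataclass
class ForceCurve:
    """Approach force curve: piezo position z (nm, ordered far -> near) and force (pN)."""

    z: np.ndarray
    force: np.ndarray
    k: float  # cantilever spring constant, N/m
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.z.shape != self.force.shape or self.z.ndim != 1:
            raise ValueError("z and force must be 1D arrays of equal length")
        dz = np.diff(self.z)
        if not ((dz < 0).all() or (dz > 0).all()):
            raise ValueError("z must be strictly monotone")
        if not np.isfinite(self.force).all():
            raise ValueError("force must be finite")
        if self.k <= 0:
            raise ValueError("spring constant must be positive")

    @property
    def far_to_near(self) -> "ForceCurve":
        """The curve ordered far from surface (large z) first."""
        if self.z[0] >= self.z[-1]:
            return self
        return replace(self, z=self.z[::-1].copy(), force=self.force[::-1].copy())


@dataclass
class IndentationCurve:
    """Indentation delta (nm, >= 0 in contact) vs force (pN)."""

    delta: np.ndarray
    force: np.ndarray
    contact_z: float
    tip_position: np.ndarray

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.tip_position = np.asarray(self.tip_position, dtype=float)


@dataclass
class MechModel:
    """Fitted Hertz parameters."""

    E: float  # effective Young's modulus, kPa
    nu: float
    R_tip: float  # nm
    residual_rms: float  # pN
    contact_offset: float = 0.0  # refinement shift applied to contact_z, nm
    n_samples: int = 0


@dataclass
class QIMap:
    """Rectangular grid of force curves sharing cantilever calibration."""

    curves: list  # nested list [row][col] of ForceCurve
    pixel_size: float  # nm
    timestamp: float = 0.0  # min

    def __post_init__(self) -> None:
        ncols = {len(row) for row in self.curves}
        if len(ncols) != 1:
            raise ValueError("grid must be rectangular")
        ks = {c.k for row in self.curves for c in row}
        if len(ks) != 1:
            raise ValueError("all curves must share the spring constant")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.curves), len(self.curves[0]))

    @property
    def k(self) -> float:
        return self.curves[0][0].k


@dataclass
class MechSeries:
    """Cell height and stiffness trajectories with the death (SYTOX) flag."""

    times: np.ndarray  # min
    heights: np.ndarray  # nm
    E_values: np.ndarray  # kPa
    sytox_flags: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        self.E_values = np.asarray(self.E_values, dtype=float)
        self.sytox_flags = np.asarray(self.sytox_flags, dtype=bool)
        n = len(self.times)
        if not (len(self.heights) == len(self.E_values) == len(self.sytox_flags) == n):
            raise ValueError("series arrays must have equal length")
        if n > 1 and not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")


# ---------------------------------------------------------------------------
# single-curve chain


def _tail_slice(n: int, tail_fraction: float) -> slice:
    n_tail = int(round(tail_fraction * n))
    if n_tail < 2:
        raise ValueError("fewer than 2 samples in the baseline tail")
    return slice(0, n_tail)


def baseline_correct(curve: ForceCurve, tail_fraction: float = 0.1) -> ForceCurve:
    """Subtract the constant baseline averaged over the far-from-surface tail.

    The tail is the ``tail_fraction`` of samples farthest from the surface
    (largest z), where there is no tip-sample force.
    """
    if not 0 < tail_fraction < 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5)")
    c = curve.far_to_near
    tail = _tail_slice(len(c.z), tail_fraction)
    baseline = float(c.force[tail].mean())
    return replace(c, force=c.force - baseline)


def find_contact(
    curve: ForceCurve,
    noise_k: float = 3.0,
    run_length: int = 5,
    tail_fraction: float = 0.1,
) -> float:
    """Contact point: where the force first deviates from the zero-force line.

    A deviation is force above ``noise_k`` times the baseline-tail SD
    sustained for ``run_length`` consecutive samples; the contact z is then
    refined backwards to the last zero-crossing of the force before that run,
    which removes the threshold-induced late bias. Expects a
    baseline-corrected approach curve.
    """
    c = curve.far_to_near
    tail = _tail_slice(len(c.z), tail_fraction)
    sd = float(c.force[tail].std())
    threshold = noise_k * sd if sd > 0 else 0.0
    above = c.force > threshold
    # first index starting a run of run_length consecutive True; a deviation
    # sustained through the end of the curve (the ramp stops at the setpoint)
    # also qualifies even if fewer than run_length samples remain
    above_ext = np.concatenate([above, np.ones(run_length - 1, dtype=bool)])
    run = np.convolve(above_ext.astype(int), np.ones(run_length, dtype=int), "valid")
    starts = np.nonzero(run == run_length)[0]
    if len(starts) == 0:
        raise NoContactError("no sustained deviation from the zero-force line")
    i0 = int(starts[0])
    # walk back to the last non-positive force sample before the run
    j = i0
    while j > 0 and c.force[j - 1] > 0:
        j -= 1
    return float(c.z[j])


def to_indentation(curve: ForceCurve, contact_z: float) -> IndentationCurve:
    """Convert piezo position to indentation, correcting for cantilever bending.

    Deflection d = F/k lifts the tip away from the sample, so the tip
    vertical position is z + d and the indentation is
    delta = contact_z - (z + d), clipped at zero before contact. On a rigid
    surface (F = k * (contact_z - z)) this gives delta = 0 identically.
    """
    if curve.k <= 0:
        raise ValueError("spring constant required")
    c = curve.far_to_near
    deflection = c.force / curve.k * PN_PER_NM_PER_N_PER_M
    tip_position = c.z + deflection
    delta = np.clip(contact_z - tip_position, 0.0, None)
    return IndentationCurve(
        delta=delta, force=c.force, contact_z=contact_z, tip_position=tip_position
    )


def _ls_amplitude(delta: np.ndarray, force: np.ndarray) -> tuple[float, float]:
    """Least-squares amplitude A of F = A * delta^(3/2) and its residual SSE."""
    x = delta**1.5
    sxx = float(x @ x)
    if sxx == 0:
        return 0.0, float(force @ force)
    a = float(x @ force) / sxx
    r = force - a * x
    return a, float(r @ r)


def fit_hertz(
    ind: IndentationCurve,
    R_tip: float = 65.0,
    nu: float = 0.5,
    max_delta: float = 200.0,
    refine_contact: bool = True,
    refine_range: float = 20.0,
    min_samples: int = 10,
) -> MechModel:
    """Least-squares Hertz fit over indentations 0 < delta <= max_delta.

    The model is linear in the amplitude A = (4/3) E sqrt(R) / (1 - nu^2)
    after the delta^(3/2) transform, so the amplitude is solved in closed
    form; with ``refine_contact`` the contact offset is additionally refined
    within +/- ``refine_range`` nm by minimizing the residual.
    """

    # Piecewise model around the detected contact: zero force above, Hertz
    # below. The residual window extends refine_range above the detected
    # contact so near-contact samples constrain the offset; feasibility
    # still requires min_samples below the *detected* contact, so a rigid
    # rise of a couple of samples cannot be rescued by shifting the contact
    # into free air.
    delta_raw = ind.contact_z - ind.tip_position
    # feasibility allows a few nm of contact-detection jitter (recoverable by
    # the offset refinement) without letting a 2-3 sample rigid rise through
    feasible = (delta_raw > -5.0) & (delta_raw <= max_delta)
    if int(feasible.sum()) < min_samples:
        raise ValueError(f"fewer than {min_samples} in-range samples for the Hertz fit")
    window = delta_raw > -refine_range

    def fit_at(offset: float) -> tuple[float, float, int]:
        delta = delta_raw + offset
        pos = window & (delta > 0) & (delta <= max_delta)
        n = int(pos.sum())
        if n < min_samples:
            return np.nan, np.inf, n
        a, _ = _ls_amplitude(delta[pos], ind.force[pos])
        pred = np.zeros_like(ind.force)
        pred[pos] = a * delta[pos] ** 1.5
        in_window = window & (delta <= max_delta)
        r = ind.force[in_window] - pred[in_window]
        return a, float(r @ r), n

    offset = 0.0
    if refine_contact:
        with np.errstate(invalid="ignore"):  # inf objective outside feasibility
            res = minimize_scalar(
                lambda c: fit_at(c)[1],
                bounds=(-refine_range, refine_range),
                method="bounded",
                options={"xatol": 0.05},
            )
        offset = float(res.x)
    a, sse, n_used = fit_at(offset)
    if not np.isfinite(a) or n_used < min_samples:
        raise ValueError(
            f"fewer than {min_samples} in-range samples for the Hertz fit"
        )
    e_kpa = a * 1e3 * (1.0 - nu**2) * 0.75 / np.sqrt(R_tip)
    return MechModel(
        E=float(e_kpa),
        nu=nu,
        R_tip=R_tip,
        residual_rms=float(np.sqrt(sse / n_used)),
        contact_offset=offset,
        n_samples=n_used,
    )


# ---------------------------------------------------------------------------
# maps and series


def process_qi_map(
    qimap: QIMap,
    R_tip: float = 65.0,
    nu: float = 0.5,
    max_delta: float = 200.0,
    refine_contact: bool = True,
    substrate_quantile: float = 0.25,
    max_failed_fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel baseline -> contact -> indentation -> Hertz over a QI map.

    Returns ``(height0, E_map, failed)``: the un-indented height (contact
    point above the substrate reference, nm), the effective Young's modulus
    map (kPa), and a boolean mask of pixels whose chain failed (flagged, not
    interpolated). The substrate reference is a robust plane fitted through
    the lowest-``substrate_quantile`` contact points.
    """
    nr, nc = qimap.shape
    contact = np.full((nr, nc), np.nan)
    e_map = np.full((nr, nc), np.nan)
    failed = np.zeros((nr, nc), dtype=bool)
    for i in range(nr):
        for j in range(nc):
            try:
                c = baseline_correct(qimap.curves[i][j])
                cz = find_contact(c)
                ind = to_indentation(c, cz)
                contact[i, j] = cz
                n_tail = max(len(c.force) // 10, 2)
                noise_sd = float(c.force[:n_tail].std())
                try:
                    model = fit_hertz(
                        ind,
                        R_tip=R_tip,
                        nu=nu,
                        max_delta=max_delta,
                        refine_contact=refine_contact,
                    )
                    # quality gate: a Hertz curve cannot reproduce a rigid
                    # (cantilever-slope) rise, so a residual far above the
                    # noise floor marks a pixel without compliant contact
                    if model.residual_rms <= max(3.0 * noise_sd, 0.5):
                        e_map[i, j] = model.E
                        contact[i, j] = cz + model.contact_offset
                except ValueError:
                    # contact found but no usable indentation range (e.g. rigid)
                    pass
            except (NoContactError, ValueError):
                failed[i, j] = True
    if failed.mean() > max_failed_fraction:
        raise RuntimeError(
            f"{failed.mean():.0%} of pixels failed force-curve processing"
        )
    # substrate reference: robust plane over the lowest-quantile contact points
    valid = ~np.isnan(contact)
    vals = contact[valid]
    cutoff = np.quantile(vals, substrate_quantile)
    yy, xx = np.mgrid[0:nr, 0:nc]
    sel = valid & (contact <= cutoff)
    if sel.sum() >= 3:
        A = np.column_stack([np.ones(sel.sum()), xx[sel], yy[sel]])
        coef, *_ = np.linalg.lstsq(A, contact[sel], rcond=None)
        substrate = coef[0] + coef[1] * xx + coef[2] * yy
    else:
        substrate = np.full((nr, nc), float(np.median(vals)))
    height0 = contact - substrate
    return height0, e_map, failed


def height_from_profile(
    height0_map,
    line: tuple[tuple[float, float], tuple[float, float]] | None = None,
    tail_fraction: float = 0.1,
    min_height: float = 50.0,
) -> float:
    """Cell height from a profile across an un-indented height map (nm).

    ``height0_map`` is a :class:`~envmech.afm_image.HeightMap` whose values
    are un-indented heights. The default line runs horizontally through the
    row containing the map maximum. Cell height = profile maximum minus the
    substrate level (median of the profile tails); raises if the profile
    misses the cell (max - background < ``min_height``).
    """
    from .afm_image import extract_profile

    hm = height0_map

    def readout(prof) -> float:
        n_tail = max(int(round(tail_fraction * len(prof.heights))), 1)
        background = float(
            np.median(np.concatenate([prof.heights[:n_tail], prof.heights[-n_tail:]]))
        )
        return float(np.nanmax(prof.heights) - background)

    if line is None:
        # default: the row and column lines through the apex; a line running
        # along the cell axis has no substrate tails, so keep the one with
        # the larger height contrast (the one crossing the cell)
        finite = np.where(np.isfinite(hm.values), hm.values, -np.inf)
        i, j = np.unravel_index(np.argmax(finite), hm.values.shape)
        px = hm.pixel_size
        row_line = ((0.0, i * px), ((hm.shape[1] - 1) * px, i * px))
        col_line = ((j * px, 0.0), (j * px, (hm.shape[0] - 1) * px))
        height = max(
            readout(extract_profile(hm, row_line)),
            readout(extract_profile(hm, col_line)),
        )
    else:
        height = readout(extract_profile(hm, line))
    if height < min_height:
        raise ValueError(f"profile misses the cell (max - background = {height:.1f} nm)")
    return height


def analyze_timeseries(
    frames: list,
    R_tip: float = 65.0,
    nu: float = 0.5,
    max_delta: float = 200.0,
    refine_contact: bool = True,
    cell_height_fraction: float = 0.5,
) -> MechSeries:
    """Run the QI-map chain on a (QIMap, sytox_flag) time series.

    Per frame, processes the map, reads the cell height from a profile
    through the apex, and summarizes stiffness as the median fitted E over
    cell pixels (un-indented height above ``cell_height_fraction`` of the
    frame maximum).
    """
    from .afm_image import HeightMap

    times, heights, e_vals, flags = [], [], [], []
    for qimap, sytox in frames:
        height0, e_map, _ = process_qi_map(
            qimap,
            R_tip=R_tip,
            nu=nu,
            max_delta=max_delta,
            refine_contact=refine_contact,
        )
        hm = HeightMap(values=np.nan_to_num(height0, nan=0.0), pixel_size=qimap.pixel_size)
        heights.append(height_from_profile(hm))
        on_cell = height0 > cell_height_fraction * np.nanmax(height0)
        e_cell = e_map[on_cell & np.isfinite(e_map)]
        e_vals.append(float(np.median(e_cell)) if len(e_cell) else np.nan)
        times.append(qimap.timestamp)
        flags.append(bool(sytox))
    return MechSeries(
        times=np.array(times),
        heights=np.array(heights),
        E_values=np.array(e_vals),
        sytox_flags=np.array(flags),
    )


def relative_change(series: MechSeries, window: int = 1) -> tuple[float, float]:
    """Signed fractional change of height and stiffness, end vs start.

    ``window`` frames are averaged at each end; change = end/start - 1.
    """
    n = len(series.times)
    if n < 2:
        raise ValueError("series must have at least 2 frames")
    w = min(window, n // 2)
    h0, h1 = series.heights[:w].mean(), series.heights[-w:].mean()
    e0, e1 = np.nanmean(series.E_values[:w]), np.nanmean(series.E_values[-w:])
    return float(h1 / h0 - 1.0), float(e1 / e0 - 1.0)


def plateau_detect(
    series: MechSeries, slope_ratio: float = 0.1
) -> tuple[bool, int]:
    """Two-segment piecewise-linear fit of E vs time; detect a terminal plateau.

    The breakpoint is found by exhaustive search over frame indices
    (minimum total SSE of independent line fits to the two segments). A
    plateau is declared when the post-breakpoint slope is within
    ``slope_ratio`` of zero relative to the pre-breakpoint slope. A series
    that is flat throughout reports a plateau starting at index 0.
    """
    n = len(series.times)
    if n < 6:
        raise ValueError("plateau detection needs at least 6 frames")
    t, e = series.times, series.E_values
    scale = max(float(np.nanmax(e) - np.nanmin(e)), 0.0)
    if scale <= 1e-9 * max(abs(float(np.nanmean(e))), 1.0):
        return True, 0

    def linfit(tt: np.ndarray, ee: np.ndarray) -> tuple[float, float]:
        coef = np.polyfit(tt, ee, 1)
        r = ee - np.polyval(coef, tt)
        return float(coef[0]), float(r @ r)

    best = (np.inf, -1, 0.0, 0.0)
    for b in range(2, n - 1):
        s1, sse1 = linfit(t[: b + 1], e[: b + 1])
        s2, sse2 = linfit(t[b:], e[b:])
        if sse1 + sse2 < best[0]:
            best = (sse1 + sse2, b, s1, s2)
    _, b, s1, s2 = best
    is_plateau = abs(s2) <= slope_ratio * abs(s1)
    return bool(is_plateau), int(b)
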