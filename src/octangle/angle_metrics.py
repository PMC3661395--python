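"""Iridocorneal-angle metrics on extracted contours.

Six measures are computed from an :class:`~octangle.segmentation.AngleContours`
with physical calibration:

``AOD``
    distance from the cornea point at 500 (or 750) μm of arc from the
    scleral spur, along the perpendicular to the local cornea tangent, to
    the first crossing of the anterior iris surface (μm);
``TIA``
    the angle between least-squares lines fitted to the two contours near
    the recess (degrees);
``TISA``
    the area of the recess bounded by the cornea, the AOD segment, the iris
    and the perpendicular dropped from the spur onto the iris (mm²);
``AOS``
    the full sequence of iris–cornea distances ordered by arc length from
    the apex, with a four-symbol run-length alphabet (/ ^ v _) describing
    its shape;
``AOM`` / ``AOM2``
    the minimum Euclidean distance between the contours over the
    measurement window — searched from the cornea side against every iris
    point (AOM), or from the windowed iris span against every cornea point
    (AOM2).

The cornea measurement window extends from the spur toward the angle
recess; at 31.3 μm/pixel the 500 μm window covers 16 pixels of contour.
Minima are exact pairwise-distance minima with deterministic
(lexicographic) tie-breaking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import MetricError
from .io_calibration import px_to_um, um_to_px
from .segmentation import AngleContours

__all__ = [
    "AngleMeasurement",
    "AosToken",
    "AosEncoding",
    "window_cornea",
    "compute_aom",
    "compute_aom2",
    "compute_aod",
    "compute_tia",
    "compute_tisa",
    "compute_aos",
    "encode_aos",
]


@dataclass(frozen=True)
class AngleMeasurement:
    """One metric's result with method tag, range and units."""

    method: str  # AOD | TIA | TISA | AOS | AOM | AOM2
    range_um: int | None
    value: float
    units: str
    value_px: float | None = None
    argmin_pair: tuple[tuple[float, float], tuple[float, float]] | None = None
    sequence: list[float] | None = None
    notes: dict = field(default_factory=dict)


@dataclass(frozen=True)
class AosToken:
    symbol: str  # one of "/", "^", "v", "_"
    value: float
    start: int
    end: int


@dataclass(frozen=True)
class AosEncoding:
    tokens: tuple[AosToken, ...]

    @property
    def symbols(self) -> str:
        return "".join(t.symbol for t in self.tokens)


def _poly(contours, which) -> np.ndarray:
    p = np.asarray(getattr(contours, f"{which}_contour"), dtype=float)
    if p.size == 0:
        raise MetricError(f"empty {which} contour")
    return p


def _arcs_px(poly: np.ndarray) -> np.ndarray:
    seg = np.hypot(np.diff(poly[:, 0]), np.diff(poly[:, 1]))
    return np.concatenate([[0.0], np.cumsum(seg)])


def _spur_index(contours: AngleContours, cornea: np.ndarray) -> int:
    if contours.spur_rc is None:
        raise MetricError("contours carry no scleral spur")
    d = np.hypot(cornea[:, 0] - contours.spur_rc[0], cornea[:, 1] - contours.spur_rc[1])
    return int(np.argmin(d))


def _window_indices(contours: AngleContours, range_um: int) -> np.ndarray:
    """Cornea vertex indices strictly apexward of the spur within the window
    (arc distance from the spur toward the recess <= the pixel-count
    equivalent of range_um)."""
    cornea = _poly(contours, "cornea")
    arcs = _arcs_px(cornea)
    i_spur = _spur_index(contours, cornea)
    n_px = um_to_px(range_um, contours.scale_um_per_px, "nearest")
    lo = arcs[i_spur] - n_px - 1e-9
    idx = np.flatnonzero((arcs >= lo) & (np.arange(len(cornea)) < i_spur))
    if arcs[i_spur] < n_px:
        warnings.warn(
            f"spur only {arcs[i_spur]:.1f} px from the apex; {range_um} μm window "
            "truncated",
            stacklevel=3,
        )
    if idx.size == 0 and i_spur == 0:
        warnings.warn("spur at the contour end: empty measurement window", stacklevel=3)
    return idx


def window_cornea(contours: AngleContours, range_um: int) -> np.ndarray:
    """Cornea sub-polyline covered by the measurement window (vertices
    beyond the spur toward the recess, arc <= range_um)."""
    cornea = _poly(contours, "cornea")
    return cornea[_window_indices(contours, range_um)]


def _lexi_min_pair(a: np.ndarray, b: np.ndarray):
    """Exact pairwise minimum with lexicographic tie-breaking on (a, b)."""
    d2 = cdist(a, b, "sqeuclidean")
    m = d2.min()
    ii, jj = np.nonzero(d2 == m)
    keys = np.column_stack([a[ii], b[jj]])
    k = int(np.lexsort(keys.T[::-1])[0])
    pair = (tuple(map(float, a[ii[k]])), tuple(map(float, b[jj[k]])))
    return float(np.sqrt(m)), pair


def compute_aom(contours: AngleContours, range_um: int = 500) -> AngleMeasurement:
    """Angle Opening Minimum: the minimum distance between the windowed
    cornea vertices and *all* iris vertices (range restriction on the
    cornea side only)."""
    if contours.closed:
        return AngleMeasurement("AOM", range_um, 0.0, "um", value_px=0.0,
                                notes={"closed": True})
    win = window_cornea(contours, range_um)
    if win.size == 0:
        raise MetricError("empty cornea window: cannot compute AOM")
    iris = _poly(contours, "iris")
    d_px, pair = _lexi_min_pair(win, iris)
    return AngleMeasurement(
        "AOM", range_um, px_to_um(d_px, contours.scale_um_per_px), "um",
        value_px=d_px, argmin_pair=pair,
    )


def compute_aom2(contours: AngleContours, range_um: int = 500) -> AngleMeasurement:
    """AOM with the roles swapped: minimum over iris vertices whose arc from
    the apex matches the cornea window's span, against all cornea vertices."""
    if contours.closed:
        return AngleMeasurement("AOM2", range_um, 0.0, "um", value_px=0.0,
                                notes={"closed": True})
    cornea = _poly(contours, "cornea")
    iris = _poly(contours, "iris")
    arcs_c = _arcs_px(cornea)
    i_spur = _spur_index(contours, cornea)
    n_px = um_to_px(range_um, contours.scale_um_per_px, "nearest")
    hi = arcs_c[i_spur]
    lo = max(hi - n_px, 0.0)
    arcs_i = _arcs_px(iris)
    sel = np.flatnonzero((arcs_i > lo - 1e-9) & (arcs_i <= hi + 1e-9))
    if sel.size == 0:
        raise MetricError("empty iris window: cannot compute AOM2")
    d_px, (pi, pc) = _lexi_min_pair(iris[sel], cornea)
    return AngleMeasurement(
        "AOM2", range_um, px_to_um(d_px, contours.scale_um_per_px), "um",
        value_px=d_px, argmin_pair=(pc, pi),
    )


def _point_at_arc(poly: np.ndarray, arcs: np.ndarray, t: float) -> np.ndarray:
    t = float(np.clip(t, 0.0, arcs[-1]))
    j = int(np.searchsorted(arcs, t, side="right")) - 1
    j = min(j, len(poly) - 2) if len(poly) > 1 else 0
    seg = arcs[j + 1] - arcs[j] if len(poly) > 1 else 1.0
    w = 0.0 if seg == 0 else (t - arcs[j]) / seg
    return poly[j] * (1 - w) + poly[min(j + 1, len(poly) - 1)] * w


def _tangent_at_arc(poly: np.ndarray, arcs: np.ndarray, t: float) -> np.ndarray:
    p0 = _point_at_arc(poly, arcs, t - 2.0)
    p1 = _point_at_arc(poly, arcs, t + 2.0)
    d = p1 - p0
    n = np.linalg.norm(d)
    if n == 0:
        raise MetricError("degenerate cornea tangent")
    return d / n


def _ray_polyline_crossing(origin, direction, poly):
    """Smallest s >= 0 with origin + s·direction on a polyline segment."""
    best = None
    o, d = np.asarray(origin, float), np.asarray(direction, float)
    for p, q in zip(poly[:-1], poly[1:]):
        u = q - p
        det = u[0] * d[1] - d[0] * u[1]
        if abs(det) < 1e-12:
            continue
        b = p - o
        s = (u[0] * b[1] - b[0] * u[1]) / det
        w = (d[0] * b[1] - d[1] * b[0]) / det
        if s >= -1e-9 and -1e-9 <= w <= 1 + 1e-9:
            if best is None or s < best:
                best = max(s, 0.0)
    return best


def _point_to_polyline(pt, poly):
    """(distance, foot, arc position) of the nearest point on a polyline."""
    pt = np.asarray(pt, float)
    arcs = _arcs_px(poly)
    best = (np.inf, poly[0], 0.0)
    for j, (p, q) in enumerate(zip(poly[:-1], poly[1:])):
        u = q - p
        L2 = u @ u
        w = 0.0 if L2 == 0 else float(np.clip((pt - p) @ u / L2, 0.0, 1.0))
        foot = p + w * u
        dist = float(np.hypot(*(pt - foot)))
        if dist < best[0]:
            best = (dist, foot, float(arcs[j] + w * np.sqrt(L2)))
    if len(poly) == 1:
        best = (float(np.hypot(*(pt - poly[0]))), poly[0], 0.0)
    return best


def _aod_construction(contours: AngleContours, range_um: int, snap: bool = True):
    """Shared AOD geometry: the cornea point C at range_um of arc from the
    spur (toward the recess), the outward perpendicular, and the first iris
    crossing I (or nearest-vertex fallback).  With ``snap`` the point is
    moved to the nearest contour vertex inside the pixel-count window (AOD
    then shares its support with the AOM search set); without it the exact
    interpolated arc position is used (TISA's boundary segment)."""
    cornea = _poly(contours, "cornea")
    iris = _poly(contours, "iris")
    arcs = _arcs_px(cornea)
    i_spur = _spur_index(contours, cornea)
    t_px = float(range_um) / contours.scale_um_per_px
    t_C = arcs[i_spur] - t_px
    if t_C < 0:
        warnings.warn(
            f"spur arc shorter than {range_um} μm; AOD point clamped to the apex",
            stacklevel=3,
        )
        t_C = 0.0
    if snap:
        # nearest contour vertex inside the pixel-count window: the AOD
        # point then belongs to the AOM search window, preserving the
        # definitional AOM <= AOD ordering
        i_C = int(np.argmin(np.abs(arcs - t_C)))
        lo_w = arcs[i_spur] - um_to_px(range_um, contours.scale_um_per_px, "nearest")
        if arcs[i_C] < lo_w - 1e-9 and i_C + 1 < i_spur:
            i_C += 1
        t_C = float(arcs[i_C])
        C = cornea[i_C]
    else:
        C = _point_at_arc(cornea, arcs, t_C)
    tan = _tangent_at_arc(cornea, arcs, t_C)
    normal = np.array([tan[1], -tan[0]])
    if normal @ (iris.mean(axis=0) - C) < 0:
        normal = -normal
    s = _ray_polyline_crossing(C, normal, iris) if len(iris) > 1 else None
    fallback = s is None
    if fallback:
        d, foot, _ = _point_to_polyline(C, iris)
        s, I = d, foot
    else:
        I = C + s * normal
    return cornea, iris, arcs, i_spur, t_C, C, I, float(s), fallback


def compute_aod(contours: AngleContours, range_um: int = 500) -> AngleMeasurement:
    """Angle Opening Distance at 500/750 μm from the scleral spur."""
    if contours.closed:
        return AngleMeasurement("AOD", range_um, 0.0, "um", value_px=0.0,
                                notes={"closed": True})
    *_, C, I, s, fallback = _aod_construction(contours, range_um)
    notes = {"fallback_nearest": True} if fallback else {}
    return AngleMeasurement(
        "AOD", range_um, px_to_um(s, contours.scale_um_per_px), "um",
        value_px=s, argmin_pair=(tuple(map(float, C)), tuple(map(float, I))),
        notes=notes,
    )


def _pca_direction(pts: np.ndarray) -> np.ndarray:
    ctr = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(ctr, full_matrices=False)
    d = vt[0]
    span = pts[-1] - pts[0]
    if d @ span < 0:
        d = -d
    return d


def compute_tia(contours: AngleContours, range_um: int = 500) -> AngleMeasurement:
    """Trabecular-Iris Angle: angle between total-least-squares lines fitted
    to the cornea and iris sides of the recess, reported in degrees in
    [0, 180).

    Each side is a linear interpolation of its contour between the angle's
    two anchors: the fit covers the observed vertices from the end of any
    reconstructed apex bridge out to the spur's arc distance (or, without a
    spur, out to range_um from the apex).  Rasterization merges the wedge
    tip over several columns, so near-apex bridged vertices are
    interpolated rather than observed and are excluded from the fit.
    """
    if contours.closed:
        return AngleMeasurement("TIA", range_um, 0.0, "deg")
    cornea = _poly(contours, "cornea")
    iris = _poly(contours, "iris")
    t_px = float(range_um) / contours.scale_um_per_px
    lo = max(contours.bridge_px) if contours.bridge_px else 0.0
    if contours.spur_rc is not None:
        hi = float(_arcs_px(cornea)[_spur_index(contours, cornea)])
    else:
        hi = lo + t_px
    if hi <= lo:
        hi = lo + t_px
    sides = []
    for poly in (cornea, iris):
        arcs = _arcs_px(poly)
        pts = poly[(arcs >= lo - 1e-9) & (arcs <= hi + 1e-9)]
        if len(pts) < 2:
            raise MetricError("degenerate contour window: cannot fit a TIA side")
        sides.append(_pca_direction(pts))
    cosang = float(np.clip(sides[0] @ sides[1], -1.0, 1.0))
    ang = float(np.degrees(np.arccos(cosang)))
    if ang >= 180.0:
        ang = 0.0
    return AngleMeasurement("TIA", range_um, ang, "deg")


def compute_tisa(contours: AngleContours, range_um: int = 500) -> AngleMeasurement:
    """Trabecular-Iris Space Area: shoelace area of the recess polygon
    bounded by the cornea (spur → AOD point), the AOD segment, the iris and
    the perpendicular dropped from the spur onto the iris; reported in mm²."""
    if contours.closed:
        return AngleMeasurement("TISA", range_um, 0.0, "mm2")
    from shapely.geometry import Polygon

    cornea, iris, arcs, i_spur, t_C, C, I, s, fallback = _aod_construction(
        contours, range_um, snap=False
    )
    spur = cornea[i_spur]
    _, F, u_F = _point_to_polyline(spur, iris)
    arcs_i = _arcs_px(iris)
    _, _, u_I = _point_to_polyline(I, iris)

    mid = np.flatnonzero((arcs > t_C + 1e-9) & (np.arange(len(cornea)) < i_spur))
    cornea_leg = cornea[mid[::-1]]  # spur -> C direction
    lo_u, hi_u = sorted((u_I, u_F))
    isel = np.flatnonzero((arcs_i > lo_u + 1e-9) & (arcs_i < hi_u - 1e-9))
    iris_leg = iris[isel] if u_I <= u_F else iris[isel[::-1]]

    ring = np.vstack([[spur], cornea_leg, [C], [I], iris_leg, [F]])
    xy = [(p[1], p[0]) for p in ring]  # shapely wants (x, y) = (col, row)
    poly = Polygon(xy)
    if not poly.is_valid:
        if abs(poly.area) < 1e-6:
            area_px2 = 0.0
        elif u_I > u_F + 1e-9:
            # wide angles push the AOD foot beyond the spur perpendicular's
            # foot, so the boundary crosses itself by construction; the
            # signed shoelace subtracts the overshoot lobe, which is the
            # area the four boundary curves enclose
            x, y = ring[:, 1], ring[:, 0]
            area_px2 = 0.5 * abs(x @ np.roll(y, -1) - np.roll(x, -1) @ y)
        else:
            from shapely.validation import explain_validity

            raise MetricError(f"self-intersecting TISA polygon: {explain_validity(poly)}")
    else:
        area_px2 = poly.area
    scale = contours.scale_um_per_px
    area_mm2 = area_px2 * scale * scale / 1e6
    notes = {"fallback_nearest": True} if fallback else {}
    return AngleMeasurement("TISA", range_um, float(area_mm2), "mm2", notes=notes)


def _resample(poly: np.ndarray, n: int) -> np.ndarray:
    arcs = _arcs_px(poly)
    t = np.linspace(0.0, arcs[-1], n)
    return np.column_stack(
        [np.interp(t, arcs, poly[:, 0]), np.interp(t, arcs, poly[:, 1])]
    )


def compute_aos(contours: AngleContours) -> AngleMeasurement:
    """Angle Opening Sequence: iris–cornea distances at matched arc-length
    positions from the apex, in μm.  The scalar value carried is the
    sequence minimum; the full sequence rides along."""
    cornea = _poly(contours, "cornea")
    iris = _poly(contours, "iris")
    if contours.closed:
        n = len(cornea)
        return AngleMeasurement("AOS", None, 0.0, "um", sequence=[0.0] * n,
                                notes={"closed": True})
    n = min(len(cornea), len(iris))
    if n < 2:
        raise MetricError("contours too short for an AOS sequence")
    pc, pi = _resample(cornea, n), _resample(iris, n)
    seq = np.hypot(pc[:, 0] - pi[:, 0], pc[:, 1] - pi[:, 1]) * contours.scale_um_per_px
    return AngleMeasurement(
        "AOS", None, float(seq.min()), "um", sequence=[float(v) for v in seq]
    )


def encode_aos(
    sequence,
    flat_tol: float | None = None,
    scale_um_per_px: float | None = None,
    invert_extrema: bool = False,
) -> AosEncoding:
    """Run-length symbolic encoding of an AOS sequence.

    Alphabet (as printed in the source grading scheme): ``/`` increasing
    run, ``^`` interior local minimum, ``v`` interior local maximum, ``_``
    constant run (|Δ| <= flat_tol).  ``invert_extrema`` swaps ^ and v for
    readers who prefer the pictographic convention.  The default flat
    tolerance is half a pixel-equivalent when a scale is supplied.
    """
    seq = np.asarray(list(sequence), dtype=float)
    if seq.size < 2:
        raise MetricError("AOS sequence must have at least 2 samples")
    if flat_tol is None:
        flat_tol = 0.5 * scale_um_per_px if scale_um_per_px else 0.0
    sym_min, sym_max = ("v", "^") if invert_extrema else ("^", "v")

    diffs = np.diff(seq)
    cls = np.where(np.abs(diffs) <= flat_tol, 0, np.sign(diffs)).astype(int)

    tokens: list[tuple] = []  # (index, priority, AosToken)
    # maximal runs
    i = 0
    while i < len(cls):
        j = i
        while j + 1 < len(cls) and cls[j + 1] == cls[i]:
            j += 1
        if cls[i] == 1:
            tokens.append((i, 1, AosToken("/", float(seq[j + 1]), i, j + 1)))
        elif cls[i] == 0:
            tokens.append((i, 1, AosToken("_", float(seq[i]), i, j + 1)))
        # decreasing runs have no symbol in the alphabet; they are implied
        i = j + 1
    # interior extrema at sign changes of the non-flat slope
    nz = np.flatnonzero(cls != 0)
    for a, b in zip(nz[:-1], nz[1:]):
        if cls[a] == -1 and cls[b] == 1:
            k = a + 1
            tokens.append((k, 0, AosToken(sym_min, float(seq[k]), k, k)))
        elif cls[a] == 1 and cls[b] == -1:
            k = a + 1
            tokens.append((k, 0, AosToken(sym_max, float(seq[k]), k, k)))
    tokens.sort(key=lambda t: (t[0], t[1]))
    return AosEncoding(tuple(t[2] for t in tokens))
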