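"""Automatic extraction of the iridocorneal-angle contours from a B-scan.

The chain mirrors fully automatic anterior-segment analysis: median
pre-filtering, column-wise Otsu binarization, morphological hole filling,
scleral-boundary extraction with a degree-4 polynomial approximation, and
tracing of the dark anterior-chamber wedge between the corneo-scleral inner
edge and the anterior iris surface.  The wedge tip (apex, the point of
greatest boundary curvature) anchors the two contours; the scleral spur is
either supplied explicitly or located by a residual-from-polynomial
heuristic.

The whole chain is deterministic: identical input scans yield identical
contours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial
from scipy import ndimage as ndi
from skimage import measure
from skimage.draw import line as bresenham

from .errors import AnchoringError, SegmentationError
from .io_calibration import OctScan

__all__ = [
    "AngleContours",
    "preprocess",
    "binarize_per_column",
    "fill_holes",
    "extract_sclera_boundary",
    "extract_angle_contours",
    "locate_spur",
    "render_overlay",
]


@dataclass
class AngleContours:
    """Ordered iris and cornea boundary polylines with their anchors.

    Both contours are (N, 2) arrays of (row, col) vertices ordered from the
    apex outward, the apex being the first vertex of both.  ``closed`` marks
    scans whose chamber wedge has zero separation everywhere (contours
    touching over the whole field), in which case both contours coincide.
    """

    cornea_contour: np.ndarray
    iris_contour: np.ndarray
    apex_rc: tuple[int, int]
    spur_rc: tuple[int, int] | None
    sclera_poly_coeffs: np.ndarray | None
    sclera_polyline: np.ndarray | None
    scale_um_per_px: float
    closed: bool = False
    # arc length (px) of the reconstructed near-apex prefix of each contour
    # (vertices bridged from the refined apex to the first observed gap
    # column); zero for analytic contours
    bridge_px: tuple[float, float] = (0.0, 0.0)


def preprocess(scan: OctScan, mask_px: int = 3, normalize: bool = False) -> OctScan:
    """Median-filter (3×3 or 5×5, edge replication) and optionally min-max
    normalize a scan.  Returns a new scan; the input is untouched."""
    if mask_px not in (3, 5):
        raise ValueError(f"mask_px must be 3 or 5, got {mask_px}")
    if scan.height_px < mask_px or scan.width_px < mask_px:
        raise SegmentationError(
            f"image {scan.pixels.shape} smaller than the {mask_px}×{mask_px} mask"
        )
    px = ndi.median_filter(scan.pixels, size=mask_px, mode="nearest")
    if normalize:
        lo, hi = px.min(), px.max()
        px = (px - lo) / (hi - lo) if hi > lo else np.zeros_like(px)
    return OctScan(px, scan.scale_um_per_px, scan.source, scan.frame_id, dict(scan.meta))


def otsu_threshold_counts(counts: np.ndarray) -> int | None:
    """Otsu level for one 256-bin histogram.

    Returns the lowest T maximizing the between-class variance of the split
    {0..T−1} | {T..255}, or None for a zero-variance (single-level) column.
    Foreground is defined as level >= T.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(counts)[:-1]  # class {0..t}, t = 0..254
    s0 = np.cumsum(counts * levels)[:-1]
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        return None
    mu0 = np.where(valid, s0 / np.where(w0 > 0, w0, 1), 0.0)
    mu1 = np.where(valid, (counts @ levels - s0) / np.where(w1 > 0, w1, 1), 0.0)
    var = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    return int(np.argmax(var)) + 1  # argmax takes the first (lowest) maximizer


def binarize_per_column(scan: OctScan) -> np.ndarray:
    """Threshold every column independently at its own Otsu level.

    Intensities are quantized to 256 levels; a pixel is foreground when its
    level is >= the column threshold.  Constant columns binarize to
    background (air outside tissue must not create foreground).
    """
    q = np.clip(np.round(scan.pixels * 255.0), 0, 255).astype(np.int64)
    H, W = q.shape
    # one bincount for all per-column histograms
    flat = q.T.ravel() + 256 * np.repeat(np.arange(W), H)
    hist = np.bincount(flat, minlength=256 * W).reshape(W, 256).astype(float)

    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(hist, axis=1)[:, :-1]
    s0 = np.cumsum(hist * levels, axis=1)[:, :-1]
    total_s = hist @ levels
    w1 = H - w0
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.divide(s0, w0, out=np.zeros_like(s0), where=w0 > 0)
    mu1 = np.divide(total_s[:, None] - s0, w1, out=np.zeros_like(s0), where=w1 > 0)
    var = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    T = np.argmax(var, axis=1) + 1  # (W,) thresholds; lowest maximizer
    mask = q >= T[None, :]
    mask[:, ~valid.any(axis=1)] = False  # zero-variance columns -> background
    return mask


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background regions not connected (4-connectivity) to the border."""
    return ndi.binary_fill_holes(np.asarray(mask, dtype=bool))


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = measure.label(mask, connectivity=2, return_num=True)
    if n == 0:
        raise SegmentationError("empty mask: no foreground component")
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == int(np.argmax(sizes))


def fit_quartic(cols: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Degree-4 least-squares fit row = P(col), columns internally scaled to
    [-1, 1] for conditioning; coefficients returned in original coordinates,
    ascending order (c0..c4)."""
    p = Polynomial.fit(cols, rows, 4).convert()
    coef = np.zeros(5)
    coef[: len(p.coef)] = p.coef
    return coef


def extract_sclera_boundary(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Anterior boundary of the corneo-scleral shell plus its quartic fit.

    Per column, the first anterior→posterior transition of the largest
    foreground component gives the boundary row (small specular reflexes
    above the cornea, being separate components, are ignored).
    """
    comp = _largest_component(np.asarray(mask, dtype=bool))
    has = comp.any(axis=0)
    cols = np.flatnonzero(has)
    if cols.size < 5:
        raise SegmentationError("no corneo-scleral band found")
    rows = np.argmax(comp[:, cols], axis=0)
    poly = np.column_stack([rows, cols]).astype(int)
    coeffs = fit_quartic(cols.astype(float), rows.astype(float))
    return poly, coeffs


def _column_wedge(comp: np.ndarray, c: int):
    """(cornea_inner_row, iris_top_row, gap) flanking the widest dark gap of
    column c within the tissue component, or None if the column has no gap."""
    idx = np.flatnonzero(comp[:, c])
    if idx.size == 0:
        return None
    jumps = np.flatnonzero(np.diff(idx) > 1)
    if jumps.size == 0:
        return None
    gaps = idx[jumps + 1] - idx[jumps] - 1
    k = int(np.argmax(gaps))
    return int(idx[jumps[k]]), int(idx[jumps[k] + 1]), int(gaps[k])


def _k_cosine_apex(boundary: np.ndarray, k: int = 5, window=None) -> int:
    """Index of maximum discrete curvature (k-cosine, window k) on a
    polyline; ties broken by smallest column, then smallest row.

    ``window = (lo, hi)`` restricts the search to that index interval —
    used to keep the apex at the wedge's deepest point instead of any
    sharp focal feature elsewhere on the boundary.
    """
    n = len(boundary)
    if n < 2 * k + 1:
        return n // 2
    p = boundary.astype(float)
    a = p[: n - 2 * k] - p[k : n - k]
    b = p[2 * k :] - p[k : n - k]
    cosang = np.einsum("ij,ij->i", a, b) / (
        np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1) + 1e-12
    )
    if window is not None:
        lo = max(int(window[0]) - k, 0)
        hi = min(int(window[1]) - k, len(cosang))
        if lo >= hi:
            lo, hi = 0, len(cosang)
        masked = np.full_like(cosang, -np.inf)
        masked[lo:hi] = cosang[lo:hi]
        cosang = masked
    best = np.flatnonzero(cosang == cosang.max()) + k
    order = np.lexsort((boundary[best, 0], boundary[best, 1]))
    return int(best[order[0]])


def _fit_line(pts: np.ndarray):
    """OLS row = a + b·col over a few near-apex vertices."""
    c, r = pts[:, 1].astype(float), pts[:, 0].astype(float)
    b, a = np.polyfit(c, r, 1)
    return a, b


def _refine_apex(cornea_pts, iris_pts, coarse_rc, max_shift=15.0):
    """Sub-pixel apex from the intersection of line fits to the first
    vertices of each contour; falls back to the curvature apex when the fit
    is degenerate or the intersection wanders."""
    m = min(8, len(cornea_pts), len(iris_pts))
    if m < 3:
        return coarse_rc
    a1, b1 = _fit_line(np.asarray(cornea_pts[:m]))
    a2, b2 = _fit_line(np.asarray(iris_pts[:m]))
    if abs(b1 - b2) < 1e-6:
        return coarse_rc
    c = (a2 - a1) / (b1 - b2)
    r = a1 + b1 * c
    if math.hypot(r - coarse_rc[0], c - coarse_rc[1]) > max_shift:
        return coarse_rc
    return (int(round(r)), int(round(c)))


def _bridge(p0, p1):
    """8-connected pixel path from p0 to p1, excluding both endpoints."""
    rr, cc = bresenham(p0[0], p0[1], p1[0], p1[1])
    return np.column_stack([rr, cc])[1:-1]


def extract_angle_contours(
    mask: np.ndarray,
    scan: OctScan,
    spur_hint: tuple[int, int] | None = None,
    max_arc_px: float | None = None,
) -> AngleContours:
    """Trace the dark anterior-chamber wedge and split it at the apex.

    ``max_arc_px`` bounds the traced arc length of each contour from the
    apex (iris visibility beyond ~2.5 mm of the recess does not occur
    anatomically); None traces the whole visible wedge.

    Per column the widest dark gap inside the largest tissue component is
    taken as the chamber; its lower cornea edge and upper iris edge form the
    chamber boundary.  The apex is the boundary point of maximum k-cosine
    curvature (window 5), refined to the intersection of near-apex line fits
    (rasterization merges the wedge tip over several columns, which biases
    the raw curvature maximum outward for narrow angles).  When no gap
    exists anywhere the scan is flagged ``closed`` and both contours
    coincide with the tissue interface.
    """
    mask = np.asarray(mask, dtype=bool)
    comp = _largest_component(mask)
    H, W = comp.shape

    wedges = {c: w for c in range(W) if (w := _column_wedge(comp, c)) is not None}
    sclera_poly, sclera_coeffs = extract_sclera_boundary(mask)

    if not wedges:
        # fully closed angle: zero-length separation, contours coincide
        cols = np.flatnonzero(comp.any(axis=0))
        rows = np.array([np.flatnonzero(comp[:, c])[-1] for c in cols])
        contour = np.column_stack([rows, cols])
        contours = AngleContours(
            cornea_contour=contour,
            iris_contour=contour.copy(),
            apex_rc=(int(rows[0]), int(cols[0])),
            spur_rc=None,
            sclera_poly_coeffs=sclera_coeffs,
            sclera_polyline=sclera_poly,
            scale_um_per_px=scan.scale_um_per_px,
            closed=True,
        )
        contours.spur_rc = spur_hint if spur_hint is not None else None
        return contours

    # contiguous blocks of gap columns; a focal near-touch of the contours
    # (narrowed angle) closes the rasterized gap over a few columns and
    # splits the wedge, so blocks separated by short closed stretches are
    # merged before picking the largest
    cols = np.array(sorted(wedges))
    blocks = np.split(cols, np.flatnonzero(np.diff(cols) > 1) + 1)
    merged = [blocks[0]]
    for b in blocks[1:]:
        if b[0] - merged[-1][-1] <= 8:
            merged[-1] = np.concatenate([merged[-1], b])
        else:
            merged.append(b)
    block = max(merged, key=len)
    if len(block) < 3:
        raise SegmentationError("chamber wedge too short to trace")

    # orient so the apex (smaller gap) is on the left
    flipped = wedges[block[0]][2] > wedges[block[-1]][2]
    order = block[::-1] if flipped else block

    cornea_pts = np.array([(wedges[c][0], c) for c in order])
    iris_pts = np.array([(wedges[c][1], c) for c in order])

    boundary = np.vstack([cornea_pts[::-1], iris_pts])
    # the apex is the deepest point: search the curvature maximum around
    # the cornea->iris junction at the boundary's closed end
    n_c = len(cornea_pts)
    coarse = _k_cosine_apex(boundary, k=5, window=(n_c - 12, n_c + 12))
    apex = _refine_apex(cornea_pts, iris_pts, tuple(boundary[coarse]))
    apex = (int(np.clip(apex[0], 0, H - 1)), int(np.clip(apex[1], 0, W - 1)))

    def assemble(pts):
        first = tuple(pts[0])
        if first == apex:
            return pts, 0.0
        full = np.vstack([[apex], _bridge(apex, first), pts])
        k = len(full) - len(pts)  # number of reconstructed vertices
        seg = np.hypot(np.diff(full[: k + 1, 0]), np.diff(full[: k + 1, 1]))
        return full, float(seg.sum())

    cornea_full, bridge_c = assemble(cornea_pts)
    iris_full, bridge_i = assemble(iris_pts)
    if max_arc_px is not None:
        def truncate(poly):
            seg = np.hypot(*np.diff(np.asarray(poly, float), axis=0).T)
            arcs = np.concatenate([[0.0], np.cumsum(seg)])
            return poly[arcs <= max_arc_px + 1e-9]

        cornea_full = truncate(cornea_full)
        iris_full = truncate(iris_full)
    contours = AngleContours(
        cornea_contour=cornea_full,
        iris_contour=iris_full,
        apex_rc=apex,
        spur_rc=None,
        sclera_poly_coeffs=sclera_coeffs,
        sclera_polyline=sclera_poly,
        scale_um_per_px=scan.scale_um_per_px,
        bridge_px=(bridge_c, bridge_i),
    )
    if spur_hint is not None:
        contours.spur_rc = _snap_to_contour(contours.cornea_contour, spur_hint)
    else:
        contours.spur_rc = locate_spur(contours, scan)
    return contours


def _snap_to_contour(contour: np.ndarray, rc: tuple[int, int]) -> tuple[int, int]:
    """Return rc itself when it is a contour vertex, else the nearest one."""
    d = np.hypot(contour[:, 0] - rc[0], contour[:, 1] - rc[1])
    i = int(np.argmin(d))
    if d[i] == 0:
        return (int(rc[0]), int(rc[1]))
    return (int(contour[i, 0]), int(contour[i, 1]))


def locate_spur(contours: AngleContours, scan: OctScan) -> tuple[int, int]:
    """Default scleral-spur heuristic.

    The spur protrudes from the otherwise smooth scleral boundary, so it is
    taken as the cornea-contour point whose column maximizes the signed
    anterior deviation between the raw scleral boundary and a fresh
    degree-4 fit restricted to the cornea-contour span.  The search covers
    the half of the contour nearer the apex, where the spur bounds the
    measurement windows.  This is a stand-in heuristic (automatic spur
    detection has no agreed definition and the spur is invisible in ~20% of
    clinical scans); an explicit spur is always the first-class pathway.
    """
    cornea = np.asarray(contours.cornea_contour)
    if len(cornea) < 5:
        raise AnchoringError("cornea contour too short to anchor a spur")
    if contours.sclera_polyline is None:
        raise AnchoringError("no scleral boundary available for the spur heuristic")
    sb = np.asarray(contours.sclera_polyline)
    lo, hi = cornea[:, 1].min(), cornea[:, 1].max()
    sel = (sb[:, 1] >= lo) & (sb[:, 1] <= hi)
    if sel.sum() < 5:
        raise AnchoringError("scleral boundary does not cover the cornea contour")
    cols = sb[sel, 1].astype(float)
    rows = sb[sel, 0].astype(float)
    coef = fit_quartic(cols, rows)
    resid = np.polyval(coef[::-1], cols) - rows  # >0 = boundary anterior to fit

    # apex-side half of the contour span
    apex_col = contours.apex_rc[1]
    mid = (lo + hi) / 2.0
    half = (cols <= mid) if abs(apex_col - lo) <= abs(apex_col - hi) else (cols >= mid)
    if not half.any():
        raise AnchoringError("degenerate contour span")
    resid_half, cols_half = resid[half], cols[half]
    if resid_half.max() < 1.25:
        raise AnchoringError("no distinguished spur point (flat scleral boundary)")
    spur_col = cols_half[int(np.argmax(resid_half))]
    i = int(np.argmin(np.abs(cornea[:, 1] - spur_col)))
    return (int(round(cornea[i, 0])), int(round(cornea[i, 1])))


def render_overlay(scan: OctScan, contours: AngleContours) -> np.ndarray:
    """RGB uint8 visual QC image: cornea contour green, iris red, scleral
    boundary blue, spur marked with a yellow cross."""
    g = np.clip(np.round(scan.pixels * 255), 0, 255).astype(np.uint8)
    rgb = np.stack([g, g, g], axis=-1)
    H, W = g.shape

    def paint(pts, color):
        pts = np.round(np.asarray(pts)).astype(int)
        ok = (pts[:, 0] >= 0) & (pts[:, 0] < H) & (pts[:, 1] >= 0) & (pts[:, 1] < W)
        rgb[pts[ok, 0], pts[ok, 1]] = color

    if contours.sclera_polyline is not None:
        paint(contours.sclera_polyline, (60, 60, 255))
    paint(contours.cornea_contour, (0, 255, 0))
    paint(contours.iris_contour, (255, 0, 0))
    if contours.spur_rc is not None:
        r, c = contours.spur_rc
        for dr, dc in [(0, 0), (-1, 0), (1, 0), (0, -1), (0, 1), (-2, 0), (2, 0), (0, -2), (0, 2)]:
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W:
                rgb[rr, cc] = (255, 255, 0)
    return rgb
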