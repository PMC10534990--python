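"""Bead detection in fluorescence well images.

The detector follows the maximally-stable-extremal-region (MSER) idea:
bright beads are extremal regions of the intensity landscape that keep a
nearly constant pixel area while the binarisation threshold sweeps over
a wide range, whereas noise and artifacts appear and vanish quickly.
The image is normalised (so detection is invariant to positive intensity
rescaling), thresholded on a ladder of levels, and connected components
are chained across levels through each region's peak pixel; a region's
*variation* is the relative area change ``(area(level - delta) -
area(level + delta)) / area(level)`` along its chain, and the most
stable member of each chain below the variation cap is reported.

Each detected region gets a minimal enclosing circle (beads are imaged
as discs whose outer boundary the circle defines), and a representative
fluorescence intensity from the projected-sphere model: the amplitude A
of ``I(r) = A * sqrt(1 - (r/R)^2) + background`` least-squares fitted
over the interior pixels, with the local background taken from an
annulus at 1.1-1.5 R.  Validity filters then drop detections by size,
shape, image-edge proximity, and mutual overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label

__all__ = [
    "SegmentationParams",
    "BeadDetection",
    "detect_regions",
    "fit_circle",
    "representative_intensity",
    "apply_validity_filters",
    "detect_beads",
    "measure_channel",
    "count_beads",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Detector and validity-filter settings.

    Area bounds default to the circle areas at the radius bounds; the
    stability parameters (ladder resolution, delta, variation cap) are
    expressed on the normalised [0, 1] intensity scale.
    """

    min_radius_px: float = 3.0
    max_radius_px: float = 10.0
    mser_delta: float = 0.05
    n_levels: int = 40
    min_level: float = 0.02
    max_variation: float = 0.35
    min_prominence: float = 0.05  # chain peak height above its lowest stable level, normalised
    min_region_area: float | None = None  # default 4 px (admits artifacts; size filter rejects them)
    max_region_area: float | None = None  # default 1.2x circle area at max_radius
    min_shape_score: float = 0.5
    edge_margin_px: float = 1.0
    max_overlap: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.min_radius_px < self.max_radius_px:
            raise ValueError("require 0 < min_radius_px < max_radius_px")
        if self.n_levels < 3:
            raise ValueError("n_levels must be >= 3")
        if not 0 < self.mser_delta < 1:
            raise ValueError("mser_delta must be in (0, 1)")
        if not self.min_area < self.max_area:
            raise ValueError("require min_region_area < max_region_area")

    @property
    def min_area(self) -> float:
        return 4.0 if self.min_region_area is None else self.min_region_area

    @property
    def max_area(self) -> float:
        if self.max_region_area is None:
            return 1.2 * math.pi * self.max_radius_px**2
        return self.max_region_area


@dataclass
class BeadDetection:
    """One segmented bead candidate."""

    center: tuple[float, float]  # (x, y), 0-based pixel coordinates
    radius: float
    intensities: dict[str, float] = field(default_factory=dict)
    shape_score: float = math.nan
    region_area: int = 0
    valid: bool = True
    reason: str = ""  # primary invalidity reason
    degenerate_circle: bool = False
    background_fallback: bool = False


# ---------------------------------------------------------------------------
# MSER-style region detection
# ---------------------------------------------------------------------------

@dataclass
class Region:
    """A stable extremal region: pixel set and its threshold level."""

    pixels: np.ndarray  # (n, 2) array of (row, col)
    level: float  # absolute intensity of the binarisation threshold
    variation: float

    def __len__(self) -> int:
        return len(self.pixels)


def detect_regions(
    image: np.ndarray, params: SegmentationParams
) -> list[Region]:
    """Stable bright regions of a single-channel image.

    Returns one :class:`Region` per detection, holding the (row, col)
    pixel coordinates, the absolute intensity threshold at which the
    region was taken, and its area variation.  A constant or empty
    image yields no regions.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty single-channel image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image must contain finite values")
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return []
    # robust top anchor: rare hot pixels or bright artifacts must not
    # compress the bead contrast onto too few ladder levels
    hi_p = float(np.percentile(img, 99.9))
    if hi_p > lo:
        hi = hi_p
    norm = np.clip((img - lo) / (hi - lo), 0.0, 1.0)

    levels = np.linspace(params.min_level, 1.0, params.n_levels, endpoint=False)
    step = levels[1] - levels[0]
    dlev = max(1, int(round(params.mser_delta / step)))

    flat = norm.ravel()
    order_max = np.argsort(flat, kind="stable")  # ascending; last write wins = max

    labels: list[np.ndarray] = []
    areas: list[np.ndarray] = []
    reps: list[np.ndarray] = []  # peak (max-intensity) flat pixel per label
    for lv in levels:
        lbl = cc_label(norm >= lv, connectivity=2)
        lflat = lbl.ravel()
        nlab = lbl.max()
        area = np.bincount(lflat, minlength=nlab + 1)
        rep = np.zeros(nlab + 1, dtype=np.int64)
        sel = order_max[lflat[order_max] > 0]
        rep[lflat[sel]] = sel  # ascending scan: final write is the region max
        labels.append(lflat)
        areas.append(area)
        reps.append(rep)

    n_lv = len(levels)
    # all stable candidates per chain, keyed by peak pixel
    cands: dict[int, list[tuple[float, int, int]]] = {}  # rep -> [(variation, level, label)]
    for i in range(n_lv):
        nlab = len(areas[i]) - 1
        if nlab == 0:
            continue
        ids = np.arange(1, nlab + 1)
        a = areas[i][1:]
        in_bounds = (a >= params.min_area) & (a <= params.max_area)
        if not in_bounds.any():
            continue
        rep_px = reps[i][1:]
        j = max(i - dlev, 0)
        k = i + dlev
        a_down = areas[j][labels[j][rep_px]]
        if k < n_lv:
            lab_up = labels[k][rep_px]
            a_up = np.where(lab_up > 0, areas[k][lab_up], 0)
        else:
            a_up = np.zeros_like(a)
        var = (a_down - a_up) / a
        stable = in_bounds & (var <= params.max_variation)
        for lab_id, v, p in zip(ids[stable], var[stable], rep_px[stable]):
            cands.setdefault(int(p), []).append((float(v), i, int(lab_id)))

    # prune chains of insignificant prominence (noise spikes riding on a
    # bead surface form their own shallow chains)
    cands = {
        p: lst
        for p, lst in cands.items()
        if flat[p] - levels[min(c[1] for c in lst)] >= params.min_prominence
    }

    # most stable candidate per chain; a region that swallows another
    # chain's peak is a merger of adjacent beads, so fall back to the
    # best single-peak member of the chain when one exists
    all_reps = np.fromiter(cands.keys(), dtype=np.int64, count=len(cands))

    def _n_peaks(level: int, lab_id: int) -> int:
        return int(np.count_nonzero(labels[level][all_reps] == lab_id))

    best: dict[int, tuple[float, int, int]] = {}
    for p, lst in cands.items():
        # outer boundary: the largest (lowest-level) stable region that
        # still holds a single peak; merged multi-bead regions excluded
        lst.sort(key=lambda c: (-areas[c[1]][c[2]], c[0]))
        choice = None
        for cand in lst:
            if _n_peaks(cand[1], cand[2]) == 1:
                choice = cand
                break
        if choice is None:
            choice = min(lst)  # fully merged chain: most stable member
        best[p] = choice

    # extract pixel sets, batched per level
    by_level: dict[int, list[tuple[int, int]]] = {}
    for p, (v, i, lab_id) in best.items():
        by_level.setdefault(i, []).append((lab_id, p))
    h, w = norm.shape
    regions: list[tuple[int, Region]] = []
    for i, entries in by_level.items():
        entries.sort()  # searchsorted below needs ascending label ids
        lflat = labels[i]
        nlab = len(areas[i]) - 1
        keep = np.zeros(nlab + 1, dtype=bool)
        for lab_id, _ in entries:
            keep[lab_id] = True
        sel_px = np.nonzero(keep[lflat])[0]
        sel_lab = lflat[sel_px]
        order = np.argsort(sel_lab, kind="stable")
        sel_px, sel_lab = sel_px[order], sel_lab[order]
        ids = np.array([lab_id for lab_id, _ in entries])
        starts = np.searchsorted(sel_lab, ids)
        ends = np.searchsorted(sel_lab, ids, side="right")
        level_abs = lo + levels[i] * (hi - lo)
        for (lab_id, p), b, e in zip(entries, starts, ends):
            px = sel_px[b:e]
            regions.append(
                (p, Region(np.c_[px // w, px % w], level_abs, best[p][0]))
            )
    # deterministic output order: by peak pixel index
    regions.sort(key=lambda t: t[0])
    return [r for _, r in regions]


# ---------------------------------------------------------------------------
# circle fitting (minimal enclosing circle)
# ---------------------------------------------------------------------------

def _circle_two(p, q):
    c = (p + q) / 2.0
    return c, float(np.hypot(*(p - c)))


def _circumcircle(a, b, c):
    d = 2.0 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
    if abs(d) < 1e-12:
        return None
    ux = ((a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1]) + (c @ c) * (a[1] - b[1])) / d
    uy = ((a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0]) + (c @ c) * (b[0] - a[0])) / d
    ctr = np.array([ux, uy])
    return ctr, float(np.hypot(*(a - ctr)))


def _welzl(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Smallest enclosing circle, incremental (Welzl-style), deterministic."""
    pts = points[np.lexsort((points[:, 1], points[:, 0]))]
    c, r = pts[0], 0.0
    eps = 1e-9
    for i in range(1, len(pts)):
        if np.hypot(*(pts[i] - c)) <= r + eps:
            continue
        c, r = pts[i], 0.0
        for j in range(i):
            if np.hypot(*(pts[j] - c)) <= r + eps:
                continue
            c, r = _circle_two(pts[i], pts[j])
            for k in range(j):
                if np.hypot(*(pts[k] - c)) <= r + eps:
                    continue
                cc = _circumcircle(pts[i], pts[j], pts[k])
                if cc is not None:
                    c, r = cc
    return c, r


def fit_circle(region: np.ndarray) -> tuple[tuple[float, float], float, bool]:
    """Minimal enclosing circle of a pixel region.

    ``region`` is (n, 2) in (row, col); the returned center is (x, y)
    with x = column.  A single pixel gets radius 0.5 by convention; a
    two-pixel region falls back to its bounding box and is flagged
    degenerate.  Returns ``(center, radius, degenerate)``.
    """
    region = np.asarray(region)
    if region.ndim != 2 or region.shape[1] != 2 or len(region) == 0:
        raise ValueError("region must be a non-empty (n, 2) pixel array")
    if len(region) == 1:
        r0, c0 = region[0]
        return (float(c0), float(r0)), 0.5, True
    pts = region[:, ::-1].astype(float)  # -> (x, y)
    if len(region) == 2:
        span = pts.max(axis=0) - pts.min(axis=0)
        c = pts.mean(axis=0)
        return (float(c[0]), float(c[1])), float(np.hypot(*span) / 2.0 + 0.5), True
    # hull vertices suffice and keep Welzl cheap on big regions
    if len(pts) > 16:
        from scipy.spatial import ConvexHull

        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass  # collinear etc.: fall through with all points
    c, r = _welzl(pts)
    return (float(c[0]), float(c[1])), float(r), False


# ---------------------------------------------------------------------------
# spherical fluorescence model
# ---------------------------------------------------------------------------

def representative_intensity(
    image: np.ndarray,
    center: tuple[float, float],
    radius: float,
) -> tuple[float, float, bool]:
    """Peak-equivalent bead intensity above local background.

    Least-squares amplitude A of the projected-sphere profile
    ``I = A * sqrt(1 - (r/R)^2) + bg`` over interior pixels (r < R),
    with bg estimated from the annulus r in [1.1 R, 1.5 R] as its lower
    quartile — robust against neighbouring beads intruding into the
    annulus in crowded monolayers.  When the annulus lies fully outside
    the image the global median is used and flagged.  Returns
    ``(A, background, background_fallback)``.
    """
    img = image if image.dtype == np.float64 else np.asarray(image, dtype=float)
    h, w = img.shape
    cx, cy = center
    r_out = 1.5 * radius
    x0, x1 = max(int(cx - r_out) - 1, 0), min(int(cx + r_out) + 2, w)
    y0, y1 = max(int(cy - r_out) - 1, 0), min(int(cy + r_out) + 2, h)
    if x0 >= x1 or y0 >= y1:
        return math.nan, float(np.median(img)), True
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(xx - cx, yy - cy)
    patch = img[y0:y1, x0:x1]
    ann = patch[(d >= 1.1 * radius) & (d <= 1.5 * radius)]
    fallback = ann.size == 0
    bg = float(np.median(img)) if fallback else float(np.percentile(ann, 25))
    inner = d < radius
    if not inner.any():
        return 0.0, bg, fallback
    prof = np.sqrt(1.0 - (d[inner] / radius) ** 2)
    amp = float((patch[inner] - bg) @ prof / (prof @ prof))
    return amp, bg, fallback


# ---------------------------------------------------------------------------
# validity filters
# ---------------------------------------------------------------------------

def _circle_overlap_area(c1, r1, c2, r2) -> float:
    d = math.hypot(c1[0] - c2[0], c1[1] - c2[1])
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return math.pi * r * r
    a1 = r1 * r1 * math.acos((d * d + r1 * r1 - r2 * r2) / (2 * d * r1))
    a2 = r2 * r2 * math.acos((d * d + r2 * r2 - r1 * r1) / (2 * d * r2))
    tri = 0.5 * math.sqrt(
        max((-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2), 0.0)
    )
    return a1 + a2 - tri


def apply_validity_filters(
    detections: list[BeadDetection],
    params: SegmentationParams,
    image_shape: tuple[int, int],
) -> list[BeadDetection]:
    """Mark each detection valid or invalid with a single primary reason.

    Order of precedence: size (radius outside bounds), shape (region
    area over circle area below threshold), edge (circle crosses the
    image border margin), overlap (> ``max_overlap`` of own circle area
    shared with an already-accepted larger-region circle; the larger
    region wins).
    """
    h, w = image_shape
    for det in detections:
        cx, cy = det.center
        r = det.radius
        if not params.min_radius_px <= r <= params.max_radius_px:
            det.valid, det.reason = False, "size"
        elif det.shape_score < params.min_shape_score:
            det.valid, det.reason = False, "shape"
        elif (
            cx - r < params.edge_margin_px
            or cy - r < params.edge_margin_px
            or cx + r > w - 1 - params.edge_margin_px
            or cy + r > h - 1 - params.edge_margin_px
        ):
            det.valid, det.reason = False, "edge"
        else:
            det.valid, det.reason = True, ""
    # overlap pass: larger regions take precedence; only neighbours
    # within the largest possible pair distance need checking
    order = sorted(
        range(len(detections)),
        key=lambda i: (-detections[i].region_area, i),
    )
    neighbours: dict[int, list[int]] = {i: [] for i in range(len(detections))}
    if len(detections) > 1:
        from scipy.spatial import cKDTree

        pts = np.array([d.center for d in detections])
        r_hi = max(d.radius for d in detections)
        tree = cKDTree(pts)
        for i, j in tree.query_pairs(2.0 * r_hi, output_type="ndarray"):
            neighbours[int(i)].append(int(j))
            neighbours[int(j)].append(int(i))
    accepted: set[int] = set()
    for i in order:
        det = detections[i]
        if not det.valid:
            continue
        own = math.pi * det.radius**2
        for j in neighbours[i]:
            if j not in accepted:
                continue
            o = _circle_overlap_area(
                det.center, det.radius, detections[j].center, detections[j].radius
            )
            if o > params.max_overlap * own:
                det.valid, det.reason = False, "overlap"
                break
        if det.valid:
            accepted.add(i)
    return detections


# ---------------------------------------------------------------------------
# per-image drivers
# ---------------------------------------------------------------------------

def detect_beads(
    image: np.ndarray,
    params: SegmentationParams,
    channel: str = "marker",
) -> list[BeadDetection]:
    """Detect, circle-fit, measure, and validity-filter beads in one image."""
    regions = detect_regions(image, params)
    image = np.asarray(image, dtype=np.float64)
    detections: list[BeadDetection] = []
    for reg in regions:
        center, radius, degenerate = fit_circle(reg.pixels)
        amp, bg, fb = representative_intensity(image, center, radius)
        # The region is the superlevel set at reg.level, so the fitted
        # circle bounds that set, not the bead: under the sphere model
        # the true radius is r_T / sqrt(1 - u^2) with u the threshold
        # height relative to the peak.  Iterate once or twice since the
        # amplitude fit itself depends on the radius.
        r_mec = radius
        for _ in range(3):
            if not (amp > 0 and not degenerate):
                break
            u = (reg.level - bg) / amp
            if not 0.0 < u < 0.95:
                break
            r_new = r_mec / math.sqrt(1.0 - u * u)
            amp_new, bg, fb = representative_intensity(image, center, r_new)
            if amp_new > 0:
                amp = amp_new
            converged = abs(r_new - radius) < 0.05
            radius = r_new
            if converged:
                break
        shape = len(reg) / (math.pi * radius**2) if radius > 0 else 0.0
        detections.append(
            BeadDetection(
                center=center,
                radius=radius,
                intensities={channel: amp},
                shape_score=min(shape, 1.0),
                region_area=len(reg),
                degenerate_circle=degenerate,
                background_fallback=fb,
            )
        )
    return apply_validity_filters(detections, params, image.shape)


def measure_channel(
    detections: list[BeadDetection], image: np.ndarray, channel: str
) -> list[BeadDetection]:
    """Measure representative intensity in another channel's image.

    Detection runs on the bead-marker channel (every bead fluoresces
    there, PCR-positive or not); this adds the detection-channel signal
    within the same circles.
    """
    image = np.asarray(image, dtype=np.float64)
    for det in detections:
        amp, _bg, fb = representative_intensity(image, det.center, det.radius)
        det.intensities[channel] = amp
        det.background_fallback = det.background_fallback or fb
    return detections


def count_beads(
    images: list[np.ndarray],
    params: SegmentationParams,
    input_volume_ul: float | None = None,
) -> tuple[int, float | None]:
    """Valid-bead count over images; concentration if a volume is given."""
    if not images:
        raise ValueError("need at least one image")
    total = 0
    for img in images:
        dets = detect_beads(img, params)
        total += sum(d.valid for d in dets)
    conc = None
    if input_volume_ul is not None:
        if input_volume_ul <= 0:
            raise ValueError("input volume must be positive")
        conc = total / input_volume_ul
    return total, conc
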