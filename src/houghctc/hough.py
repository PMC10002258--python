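"""Circular Hough detection of cell profiles and free/cluster classification.

The detector is a gradient-directed circular Hough transform with a
geometric verification stage, tuned for the small cell radii (2-10 px at
0.75 pixel/um) this assay produces:

1.  The weighted plane (mask x CK intensity) is upsampled 2x; Canny edges
    and Sobel gradient orientations are extracted.
2.  Every edge pixel casts one vote per candidate radius at the point
    ``p + r * g_hat`` along its (inward) gradient direction; accumulator
    local maxima above a permissive floor become circle proposals.
3.  Each proposal is refined to sub-pixel center/radius by iteratively
    re-fitting a least-squares circle (Kasa fit) to its consistent edge
    pixels.
4.  Each refined circle is scored by *support*: the fraction of its
    circumference backed by an edge pixel whose directional vote lands on
    the circle's own (center, radius).
5.  Circles are selected greedily by marginal support against the not yet
    explained edge pixels, stopping when the best marginal support falls
    below ``1 - sensitivity``; a split-refinement pass can replace one
    accepted circle by a pair that explains strictly more edge evidence
    (this resolves strongly overlapping cluster members).

Raising ``sensitivity`` only lowers the stopping threshold, so the number
of detections is monotone non-decreasing in it.  Everything is
deterministic for fixed input and parameters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from skimage import feature as skfeature

from .components import Component, Fate
from .errors import ConfigurationError, DimensionError

log = logging.getLogger(__name__)


@dataclass
class CircleDetection:
    """One detected cell profile."""

    center: tuple[float, float]  # (row, col), original pixel scale
    radius_px: float
    score: float                 # circumference support in [0, 1]
    accumulator: float = 0.0
    component_label: int | None = None


@dataclass
class CellEvent:
    """A counted cell: free CTC or one member of a cluster."""

    kind: str                    # "free" | "clustered"
    center: tuple[float, float]
    radius_px: float
    diameter_um: float
    component_label: int
    score: float = 0.0


@dataclass
class ClusterEvent:
    """A component holding two or more detected cell centers."""

    component_label: int
    n_cells: int
    area_px: int
    area_um2: float
    member_circles: list[CircleDetection] = dc_field(default_factory=list)


def radius_range_from_physical(
    cell_diameter_um_min: float,
    cell_diameter_um_max: float,
    resolution: float,
) -> tuple[int, int]:
    """Hough radius window (px) from the physical cell-diameter range.

    ``r_min = floor(0.5 * d_min * resolution)`` clamped to >= 2;
    ``r_max = ceil(0.5 * d_max * resolution)``.  The defaults (5-25 um at
    0.75 pixel/um) give (2, 10).
    """
    if not (0 < cell_diameter_um_min < cell_diameter_um_max):
        raise ConfigurationError(
            f"need 0 < d_min < d_max, got ({cell_diameter_um_min}, {cell_diameter_um_max})"
        )
    if resolution <= 0:
        raise ConfigurationError("resolution must be positive")
    r_min = max(2, math.floor(0.5 * cell_diameter_um_min * resolution))
    r_max = math.ceil(0.5 * cell_diameter_um_max * resolution)
    return r_min, r_max


def intensity_weight(mask: np.ndarray, green_plane: np.ndarray) -> np.ndarray:
    """Pixelwise product of a binary mask with the CK (green) intensities."""
    mask = np.asarray(mask)
    green = np.asarray(green_plane)
    if mask.shape != green.shape:
        raise DimensionError(f"mask {mask.shape} vs green plane {green.shape}")
    return (mask > 0) * green.astype(float)


def convert_sizes(radius_px: float, area_px: float, resolution: float) -> tuple[float, float]:
    """(diameter in um, area in um^2) from pixel measurements."""
    if resolution <= 0:
        raise ConfigurationError("resolution must be positive")
    diameter_um = 2.0 * radius_px / resolution
    area_um2 = area_px / resolution**2
    if radius_px == 0:
        log.warning("degenerate zero radius converted to 0 um diameter")
    return diameter_um, area_um2


def _kasa_fit(ys: np.ndarray, xs: np.ndarray) -> tuple[float, float, float] | None:
    """Algebraic least-squares circle through the points, or None."""
    a_mat = np.column_stack([2 * ys, 2 * xs, np.ones(len(ys))])
    b_vec = ys**2 + xs**2
    try:
        sol, *_ = np.linalg.lstsq(a_mat, b_vec, rcond=None)
    except np.linalg.LinAlgError:  # pragma: no cover
        return None
    cy, cx, c = sol
    r2 = c + cy**2 + cx**2
    if r2 <= 0:
        return None
    return float(cy), float(cx), float(np.sqrt(r2))


def _detect_window(
    w: np.ndarray,
    r_min: int,
    r_max: int,
    sensitivity: float,
    min_center_distance: float,
    grad_sigma: float,
    accum_sigma: float,
    propose_thr: float,
    n_arc: int,
    match_tol: float,
    support_tol: float,
    dir_tol_deg: float,
    canny_lo: float,
    canny_hi: float,
    split_refine: bool,
) -> list[tuple[float, float, float, float, float]]:
    """Core detector on one normalized window; returns (score, acc, y, x, r)."""
    if w.max() <= 0:
        return []
    w = w / w.max()
    sm = ndimage.gaussian_filter(w, grad_sigma)
    gy = ndimage.sobel(sm, axis=0) / 8.0
    gx = ndimage.sobel(sm, axis=1) / 8.0
    mag = np.hypot(gy, gx)
    if mag.max() == 0:
        return []
    edge = skfeature.canny(w, sigma=grad_sigma, low_threshold=canny_lo, high_threshold=canny_hi)
    eys, exs = np.nonzero(edge)
    if len(eys) == 0:
        return []
    m = mag[eys, exs]
    m[m == 0] = 1.0
    uy = gy[eys, exs] / m
    ux = gx[eys, exs] / m
    h, wd = w.shape
    feys = eys.astype(float)
    fexs = exs.astype(float)

    # --- stage 2: directional voting, one accumulator slice per radius
    props: list[tuple[float, float, float, float]] = []
    for r in range(r_min, r_max + 1):
        cy = np.rint(eys + r * uy).astype(int)
        cx = np.rint(exs + r * ux).astype(int)
        ok = (cy >= 0) & (cy < h) & (cx >= 0) & (cx < wd)
        acc = np.zeros((h, wd))
        np.add.at(acc, (cy[ok], cx[ok]), 1.0)
        acc = ndimage.gaussian_filter(acc, accum_sigma)
        acc *= accum_sigma**2 / r  # ~1 for a fully visible circle rim
        mx = ndimage.maximum_filter(acc, size=3, mode="constant")
        for y, x in zip(*np.nonzero((acc >= mx) & (acc >= propose_thr))):
            props.append((float(acc[y, x]), float(y), float(x), float(r)))
    if not props:
        return []

    # --- stage 3: sub-pixel refinement
    cos_tol = np.cos(np.radians(dir_tol_deg))
    refined: list[tuple[float, float, float, float]] = []
    for a, y, x, r in props:
        cy, cx, cr = y, x, r
        inliers = None
        for _ in range(3):
            d = np.hypot(feys - cy, fexs - cx)
            d[d == 0] = 1e-9
            inward = (uy * (cy - feys) + ux * (cx - fexs)) / d
            inliers = (np.abs(d - cr) <= match_tol) & (inward >= cos_tol)
            if inliers.sum() < 5:
                break
            fit = _kasa_fit(feys[inliers], fexs[inliers])
            if fit is None:
                break
            cy, cx, cr = fit
        if inliers is None or inliers.sum() < 5:
            continue
        if not (r_min - 0.75 <= cr <= r_max + 0.75):
            continue
        if not (0 <= cy < h and 0 <= cx < wd):
            continue
        refined.append((a, cy, cx, cr))
    if not refined:
        return []

    # drop proposals that converged onto the same circle
    deduped: list[tuple[float, float, float, float]] = []
    for a, cy, cx, cr in sorted(refined, key=lambda t: (-t[0], t[1], t[2], t[3])):
        if all(
            np.hypot(cy - dy, cx - dx) > 0.8 or abs(cr - dr) > 0.8
            for _, dy, dx, dr in deduped
        ):
            deduped.append((a, cy, cx, cr))

    # --- stage 4: circumference support and consumable rim pixels
    phis = np.arange(n_arc) * 2 * np.pi / n_arc
    sin_p, cos_p = np.sin(phis), np.cos(phis)
    mats: list[np.ndarray] = []
    covers: list[np.ndarray] = []
    scored: list[tuple[float, float, float, float, float]] = []
    for a, cy, cx, cr in deduped:
        py = cy + cr * sin_p
        px = cx + cr * cos_p
        d_all = np.hypot(feys - cy, fexs - cx)
        d_all[d_all == 0] = 1e-9
        inward = (uy * (cy - feys) + ux * (cx - fexs)) / d_all
        consistent = (np.abs(d_all - cr) <= match_tol) & (inward >= cos_tol)
        idx = np.nonzero(consistent)[0]
        if len(idx) == 0:
            continue
        ids = np.full(n_arc, -1, int)
        for mi in range(n_arc):
            dd = np.hypot(feys[idx] - py[mi], fexs[idx] - px[mi])
            j = int(np.argmin(dd))
            if dd[j] <= support_tol:
                ids[mi] = idx[j]
        rim = np.nonzero((np.abs(d_all - cr) <= support_tol) & (inward >= cos_tol))[0]
        mats.append(ids)
        covers.append(np.union1d(rim, ids[ids >= 0]))
        scored.append(((ids >= 0).mean(), a, cy, cx, cr))
    if not scored:
        return []

    n_cand = len(scored)
    thr = 1.0 - sensitivity

    def dyn_support(i: int, covered: np.ndarray) -> float:
        ids = mats[i]
        return np.count_nonzero((ids >= 0) & ~covered[np.clip(ids, 0, None)]) / len(ids)

    # --- stage 5: greedy selection by marginal support
    covered = np.zeros(len(eys), bool)
    alive = list(range(n_cand))
    kept: list[int] = []
    while alive:
        best_i, best_s = -1, -1.0
        for i in alive:
            s = dyn_support(i, covered)
            if s > best_s + 1e-12:
                best_i, best_s = i, s
        if best_i < 0 or best_s < thr:
            break
        _, a, cy, cx, cr = scored[best_i]
        if all(
            np.hypot(cy - scored[k][2], cx - scored[k][3]) > min_center_distance
            for k in kept
        ):
            kept.append(best_i)
            covered[covers[best_i]] = True
        alive.remove(best_i)

    if split_refine and kept:
        kept = _split_refine(
            kept, scored, mats, covers, dyn_support, len(eys), thr, min_center_distance
        )

    out = [(scored[i][0], scored[i][1], scored[i][2], scored[i][3], scored[i][4]) for i in kept]
    out.sort(key=lambda t: (-t[0], t[2], t[3]))
    return out


def _split_refine(kept, scored, mats, covers, dyn_support, n_edge, thr, min_cd):
    """Replace one kept circle by a pair explaining strictly more evidence."""
    kept = list(kept)
    changed = True
    guard = 0
    while changed and guard < 20:
        changed = False
        guard += 1
        for pos, ci in enumerate(kept):
            others = [k for p, k in enumerate(kept) if p != pos]
            cov_others = np.zeros(n_edge, bool)
            for oi in others:
                cov_others[covers[oi]] = True
            gain_c = int(np.count_nonzero(~cov_others[covers[ci]]))
            cy0, cx0, cr0 = scored[ci][2], scored[ci][3], scored[ci][4]
            pool = [
                i
                for i in range(len(scored))
                if i not in kept
                and i != ci
                and np.hypot(scored[i][2] - cy0, scored[i][3] - cx0) <= cr0 + 2
            ]
            best = None
            for ii in pool:
                if dyn_support(ii, cov_others) < thr:
                    continue
                cov_i = cov_others.copy()
                cov_i[covers[ii]] = True
                for jj in pool:
                    if jj == ii:
                        continue
                    if (
                        np.hypot(
                            scored[ii][2] - scored[jj][2], scored[ii][3] - scored[jj][3]
                        )
                        <= min_cd
                    ):
                        continue
                    if dyn_support(jj, cov_i) < thr:
                        continue
                    gain = int(
                        np.count_nonzero(
                            ~cov_others[np.union1d(covers[ii], covers[jj])]
                        )
                    )
                    if gain > gain_c and (best is None or gain > best[0]):
                        best = (gain, ii, jj)
            if best is not None:
                kept[pos] = best[1]
                kept.append(best[2])
                changed = True
                break
    return kept


def find_circles(
    weighted: np.ndarray,
    r_min: int,
    r_max: int,
    sensitivity: float = 0.65,
    min_center_distance: float = 2.0,
    upsample: int = 2,
    grad_sigma: float = 1.0,
    accum_sigma: float = 0.8,
    propose_thr: float = 0.12,
    n_arc: int = 64,
    match_tol: float = 1.5,
    support_tol: float = 0.8,
    dir_tol_deg: float = 35.0,
    canny_lo: float = 0.05,
    canny_hi: float = 0.12,
    split_refine: bool = True,
    per_region: bool = True,
) -> list[CircleDetection]:
    """Detect circular cell profiles in an intensity-weighted plane.

    Parameters mirror the pipeline configuration; see the module docstring
    for the algorithm.  ``upsample`` runs the detector on a bicubically
    upsampled copy (sub-pixel tolerances scale with it), which is
    essential for radii below ~6 px.  With ``per_region`` (default) each
    connected patch of nonzero intensity is processed in its own cropped
    window, which keeps large sparse fields fast without changing results.

    Returns circles sorted by descending support score; deterministic for
    fixed input and parameters.
    """
    if r_min < 1 or r_max < r_min:
        raise ConfigurationError(f"invalid radius range ({r_min}, {r_max})")
    if not 0.0 <= sensitivity <= 1.0:
        raise ConfigurationError("sensitivity must lie in [0, 1]")
    w = np.asarray(weighted, dtype=float)
    if w.max() <= 0:
        return []
    u = max(1, int(upsample))

    def run_window(win: np.ndarray, oy: int, ox: int) -> list[CircleDetection]:
        big = ndimage.zoom(win, u, order=3) if u > 1 else win
        raw = _detect_window(
            big,
            r_min * u,
            r_max * u,
            sensitivity,
            min_center_distance * u,
            grad_sigma,
            accum_sigma,
            propose_thr,
            n_arc,
            match_tol,
            support_tol,
            dir_tol_deg,
            canny_lo,
            canny_hi,
            split_refine,
        )
        return [
            CircleDetection(
                center=(oy + y / u, ox + x / u),
                radius_px=r / u,
                score=s,
                accumulator=a,
            )
            for s, a, y, x, r in raw
        ]

    circles: list[CircleDetection] = []
    if per_region:
        lab, n_lab = ndimage.label(w > 0, structure=np.ones((3, 3), int))
        if n_lab == 0:
            return []
        margin = r_max + 2
        slices = ndimage.find_objects(lab)
        for i, sl in enumerate(slices, start=1):
            if sl is None:
                continue
            r0 = max(0, sl[0].start - margin)
            r1 = min(w.shape[0], sl[0].stop + margin)
            c0 = max(0, sl[1].start - margin)
            c1 = min(w.shape[1], sl[1].stop + margin)
            win = np.where(lab[r0:r1, c0:c1] == i, w[r0:r1, c0:c1], 0.0)
            circles.extend(run_window(win, r0, c0))
    else:
        circles = run_window(w, 0, 0)

    circles.sort(key=lambda c: (-c.score, c.center[0], c.center[1]))
    return circles


def assign_circles(
    circles: list[CircleDetection],
    components: list[Component],
    shape: tuple[int, int],
) -> list[CircleDetection]:
    """Attach each circle to the component containing its center pixel.

    Circles whose (rounded) center lies on background are dropped and
    logged; the returned list keeps input order minus the dropped ones.
    """
    label_img = np.zeros(shape, dtype=np.int32)
    for c in components:
        label_img[c.rows, c.cols] = c.label
    assigned: list[CircleDetection] = []
    for circ in circles:
        y = int(round(circ.center[0]))
        x = int(round(circ.center[1]))
        if not (0 <= y < shape[0] and 0 <= x < shape[1]):
            log.info("dropping circle with out-of-bounds center %s", circ.center)
            continue
        lab = int(label_img[y, x])
        if lab == 0:
            log.info("dropping circle at %s: center on background", circ.center)
            continue
        circ.component_label = lab
        assigned.append(circ)
    return assigned


def classify_events(
    components: list[Component],
    assigned_circles: list[CircleDetection],
    resolution: float,
) -> tuple[list[CellEvent], list[ClusterEvent], list[Component]]:
    """Turn per-component circle counts into counted events.

    Per component: 0 centers -> rejected (not counted); 1 center -> one
    free CTC; k >= 2 centers -> one cluster with ``n_cells = k`` plus k
    clustered cell events.
    """
    by_label: dict[int, list[CircleDetection]] = {}
    for circ in assigned_circles:
        if circ.component_label is not None:
            by_label.setdefault(circ.component_label, []).append(circ)

    cells: list[CellEvent] = []
    clusters: list[ClusterEvent] = []
    rejected: list[Component] = []
    for comp in components:
        if comp.fate not in (Fate.CELL_MASK, Fate.CLUSTER_MASK):
            continue
        circs = by_label.get(comp.label, [])
        if not circs:
            rejected.append(comp)
            log.info("component %d rejected: no Hough center (no CK-consistent circle)", comp.label)
            continue
        if len(circs) == 1:
            c = circs[0]
            d_um, _ = convert_sizes(c.radius_px, comp.area_px, resolution)
            cells.append(
                CellEvent(
                    kind="free",
                    center=c.center,
                    radius_px=c.radius_px,
                    diameter_um=d_um,
                    component_label=comp.label,
                    score=c.score,
                )
            )
        else:
            area_um2 = comp.area_px / resolution**2
            clusters.append(
                ClusterEvent(
                    component_label=comp.label,
                    n_cells=len(circs),
                    area_px=comp.area_px,
                    area_um2=area_um2,
                    member_circles=list(circs),
                )
            )
            for c in circs:
                d_um, _ = convert_sizes(c.radius_px, comp.area_px, resolution)
                cells.append(
                    CellEvent(
                        kind="clustered",
                        center=c.center,
                        radius_px=c.radius_px,
                        diameter_um=d_um,
                        component_label=comp.label,
                        score=c.score,
                    )
                )
    return cells, clusters, rejected
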