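"""Per-channel binarization and the CK+/Hoechst+/CD45- mask logic.

Each channel is thresholded globally with Otsu's criterion (minimum
intra-class variance) and binarized with a strict greater-than rule.  The
candidate-CTC mask is the pixelwise product ``blue AND green AND NOT red``:
a pixel must be nucleated and CK-positive, and must not carry leukocyte
CD45 signal.  User-designated artifact regions can then be blanked out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from skimage import draw as skdraw

from .errors import ConfigurationError, DegenerateHistogramError, DimensionError


def intensity_histogram(plane: np.ndarray, n_levels: int | None = None) -> np.ndarray:
    """Counts per integer intensity level (length ``n_levels``)."""
    plane = np.asarray(plane)
    if n_levels is None:
        n_levels = 65536 if plane.dtype.itemsize > 1 else 256
    return np.bincount(plane.ravel().astype(np.int64), minlength=n_levels)


def otsu_threshold(plane: np.ndarray) -> int:
    """Global Otsu threshold over the full-bit-depth histogram.

    Returns the integer level ``t`` maximizing the between-class variance
    (equivalently minimizing the intensity-weighted intra-class variance)
    of the split ``{<= t} / {> t}``.  Binarization downstream is strictly
    greater-than ``t``.  Ties break toward the lowest threshold.

    Raises
    ------
    DegenerateHistogramError
        If the plane is constant (fewer than two distinct values); the
        caller may substitute a manual threshold.
    """
    hist = intensity_histogram(plane).astype(np.float64)
    levels = np.arange(hist.size, dtype=np.float64)
    total = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("plane has fewer than 2 distinct intensities")
    w0 = np.cumsum(hist)                      # mass of class {<= t}
    m0 = np.cumsum(hist * levels)             # first moment of class {<= t}
    w1 = total - w0
    mu_total = m0[-1]
    valid = (w0 > 0) & (w1 > 0)               # both classes nonempty
    mu0 = np.where(valid, m0 / np.maximum(w0, 1), 0.0)
    mu1 = np.where(valid, (mu_total - m0) / np.maximum(w1, 1), 0.0)
    sigma_b = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -1.0)
    return int(np.argmax(sigma_b))            # argmax takes the lowest tie


def binarize(plane: np.ndarray, threshold: float) -> np.ndarray:
    """Mask with 1 where ``plane > threshold`` (strict), else 0."""
    return (np.asarray(plane) > threshold).astype(np.uint8)


@dataclass
class ThresholdReport:
    """Outcome of the (scriptable) manual threshold review step."""

    threshold: int
    otsu_value: int
    override_used: bool
    histogram: np.ndarray
    separability: float = 1.0     # Otsu's eta = sigma_between^2 / sigma_total^2
    channel_empty: bool = False   # channel judged unstained (noise only)

    def histogram_csv(self, path: Path | str) -> None:
        lv = np.arange(self.histogram.size)
        np.savetxt(
            str(path),
            np.column_stack([lv, self.histogram]),
            fmt="%d",
            delimiter=",",
            header="level,count",
            comments="",
        )


def manual_threshold_review(
    plane: np.ndarray,
    otsu_value: int,
    override: int | None = None,
) -> ThresholdReport:
    """Emit the intensity histogram and resolve the effective threshold.

    The original workflow let an operator inspect the histogram and raise
    the threshold when Otsu's value was not high enough; here the override
    comes from configuration so batch runs stay reproducible.  An override
    always wins when present.
    """
    hist = intensity_histogram(plane)
    if override is None:
        return ThresholdReport(int(otsu_value), int(otsu_value), False, hist)
    lim = hist.size - 1
    if not 0 <= override <= lim:
        raise ConfigurationError(f"manual threshold {override} outside [0, {lim}]")
    return ThresholdReport(int(override), int(otsu_value), True, hist)


def combine_masks(blue_mask: np.ndarray, green_mask: np.ndarray, red_mask: np.ndarray) -> np.ndarray:
    """Pixelwise ``blue AND green AND NOT red``."""
    b, g, r = (np.asarray(m) for m in (blue_mask, green_mask, red_mask))
    if not (b.shape == g.shape == r.shape):
        raise DimensionError(
            f"mask shapes differ: {b.shape}, {g.shape}, {r.shape}"
        )
    return ((b > 0) & (g > 0) & ~(r > 0)).astype(np.uint8)


@dataclass
class ExclusionRegion:
    """A rectangle or polygon to blank out of the combined mask.

    Rectangles are ``(top, left, height, width)``; polygons a list of
    ``(row, col)`` vertices.  Regions extending beyond the image are
    clipped.
    """

    rect: tuple[int, int, int, int] | None = None
    polygon: Sequence[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if (self.rect is None) == (self.polygon is None):
            raise ConfigurationError("region needs exactly one of rect / polygon")
        if self.rect is not None:
            top, left, h, w = self.rect
            if h <= 0 or w <= 0:
                raise ConfigurationError(f"rectangle extent must be positive: {self.rect}")
        else:
            if len(self.polygon) < 3:
                raise ConfigurationError("polygon needs at least 3 vertices")

    def rasterize(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of covered pixels, clipped to ``shape``."""
        if self.rect is not None:
            top, left, h, w = self.rect
            r0, r1 = max(0, top), min(shape[0], top + h)
            c0, c1 = max(0, left), min(shape[1], left + w)
            if r0 >= r1 or c0 >= c1:
                return np.empty(0, int), np.empty(0, int)
            rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
            return rr.ravel(), cc.ravel()
        verts = np.asarray(self.polygon, dtype=float)
        return skdraw.polygon(verts[:, 0], verts[:, 1], shape=shape)


def load_exclusion_regions(path: Path | str) -> list[ExclusionRegion]:
    """Read a JSON sidecar: a list of ``{"rect": [...]}`` / ``{"polygon": [...]}``."""
    with open(path) as fh:
        raw = json.load(fh)
    regions = []
    for entry in raw:
        if "rect" in entry:
            regions.append(ExclusionRegion(rect=tuple(entry["rect"])))
        elif "polygon" in entry:
            regions.append(ExclusionRegion(polygon=[tuple(v) for v in entry["polygon"]]))
        else:
            raise ConfigurationError(f"region entry needs 'rect' or 'polygon': {entry}")
    return regions


def remove_artifacts(mask: np.ndarray, regions: Iterable[ExclusionRegion] | None) -> np.ndarray:
    """Zero all pixels inside the given regions; empty list is the identity."""
    mask = np.asarray(mask)
    out = mask.copy()
    for region in regions or ():
        rr, cc = region.rasterize(mask.shape)
        out[rr, cc] = 0
    return out


def otsu_separability(plane: np.ndarray, threshold: int) -> float:
    """Otsu's eta: between-class variance over total variance at ``threshold``.

    eta is ~0.64 when a channel holds pure Gaussian read noise and rises
    above ~0.8 as soon as a genuinely stained population is present; it
    is the classic separability ("goodness") measure of the Otsu split.
    """
    x = np.asarray(plane, dtype=float).ravel()
    var = x.var()
    if var == 0:
        return 0.0
    fg = x > threshold
    w1 = fg.mean()
    if w1 in (0.0, 1.0):
        return 0.0
    w0 = 1.0 - w1
    return float(w0 * w1 * (x[fg].mean() - x[~fg].mean()) ** 2 / var)


#: below this separability an unstained (noise-only) channel is assumed
SEPARABILITY_FLOOR = 0.75


def threshold_field_channel(
    plane: np.ndarray,
    manual: int | None = None,
    separability_floor: float = SEPARABILITY_FLOOR,
) -> tuple[np.ndarray, ThresholdReport]:
    """Otsu + review for one channel; returns (mask, report).

    Two guard rails replace the operator's histogram inspection:

    * a constant plane cannot be auto-thresholded — a manual value is
      used if configured, otherwise the channel is empty;
    * a plane whose Otsu split has separability (eta) below
      ``separability_floor`` holds no stained population — Otsu would be
      splitting read noise — so the channel is treated as empty unless a
      manual threshold overrides.
    """
    plane = np.asarray(plane)
    try:
        otsu = otsu_threshold(plane)
    except DegenerateHistogramError:
        if manual is not None:
            report = manual_threshold_review(plane, int(plane.flat[0]), manual)
            return binarize(plane, report.threshold), report
        const = int(plane.flat[0])
        report = ThresholdReport(
            const, const, False, intensity_histogram(plane), 0.0, True
        )
        return binarize(plane, const), report
    eta = otsu_separability(plane, otsu)
    if manual is None and eta < separability_floor:
        lim = intensity_histogram(plane).size - 1
        report = ThresholdReport(
            lim, otsu, False, intensity_histogram(plane), eta, True
        )
        return np.zeros_like(plane, dtype=np.uint8), report
    report = manual_threshold_review(plane, otsu, manual)
    report.separability = eta
    return binarize(plane, report.threshold), report
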