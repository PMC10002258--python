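"""Seeded synthetic spiked-blood fields with known ground truth.

The generator emulates the validation design of spiking cultured
pancreatic cancer cells into healthy-donor blood before enrichment and
staining: tumor cells render in blue (Hoechst) and green (CK) only,
leukocytes in blue and red (CD45), and debris in a single channel with
irregular shape.  Fluorescence adds in projection, so overlapping cells
are rendered additively (the overlap lens is brighter); each channel then
receives a Gaussian PSF blur, a constant background level and Gaussian
read noise before quantization.

Cluster members are placed as a chain — each cell at 0.8-1.3x the mean
radius from the previous one with a bounded turning angle — which yields
the grape/strand-like aggregates seen in enriched samples and guarantees
chain-overlap (center spacing below the sum of radii).

Everything is driven by a single integer seed; the same seed reproduces
the field and its truth table bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, asdict, replace
from pathlib import Path
import json
import math

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as skdraw

from .errors import CapacityError
from .field import MultichannelField


@dataclass
class SceneConfig:
    """Parameters of one synthetic field.

    Radii are in micrometres and converted with ``resolution``; intensity
    medians are 8-bit counts (lognormal per-object brightness with
    ``intensity_sigma`` spread of the log).
    """

    shape: tuple[int, int] = (512, 512)
    resolution: float = 0.75           # pixel/um
    n_free_tumor: int = 20
    n_clusters: int = 2
    cluster_sizes: tuple[int, ...] | None = None   # explicit sizes; else drawn from 2..4
    n_leukocytes: int = 30
    n_debris: int = 5
    tumor_radius_um: tuple[float, float] = (3.5, 6.0)
    leukocyte_radius_um: tuple[float, float] = (3.0, 4.5)
    cluster_spacing: tuple[float, float] = (0.8, 1.3)  # x mean radius
    tumor_intensity: float = 140.0      # blue and green median
    leukocyte_intensity: float = 140.0  # blue median; red uses 160
    debris_intensity: float = 110.0
    intensity_sigma: float = 0.25       # lognormal sigma of per-object brightness
    blur_sigma: float = 0.5             # PSF, px
    background: float = 8.0
    noise_sd: float = 2.0
    bit_depth: int = 8
    seed: int = 0

    def to_json(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=list)


@dataclass
class GroundTruth:
    """Per-object truth table plus field-level counts."""

    objects: pd.DataFrame   # object_id, cls, row, col, radius_px, cluster_id
    n_tumor: int
    n_leukocyte: int
    n_debris: int
    n_clusters: int
    cluster_sizes: list[int]

    @property
    def tumor_centers(self) -> list[tuple[float, float]]:
        t = self.objects[self.objects["cls"] == "tumor"]
        return list(zip(t["row"], t["col"]))

    def to_csv(self, path: Path | str) -> None:
        self.objects.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Path | str) -> "GroundTruth":
        df = pd.read_csv(path)
        tumor = df[df["cls"] == "tumor"]
        sizes = [
            int(n)
            for _, n in tumor.dropna(subset=["cluster_id"]).groupby("cluster_id").size().items()
        ]
        return cls(
            objects=df,
            n_tumor=int((df["cls"] == "tumor").sum()),
            n_leukocyte=int((df["cls"] == "leukocyte").sum()),
            n_debris=int((df["cls"] == "debris").sum()),
            n_clusters=len(sizes),
            cluster_sizes=sizes,
        )


def _render_disk(plane: np.ndarray, row: float, col: float, radius: float, amp: float) -> None:
    """Additively render an anti-aliased disk (coverage-weighted rim)."""
    h, w = plane.shape
    r0 = max(0, int(math.floor(row - radius - 2)))
    r1 = min(h, int(math.ceil(row + radius + 3)))
    c0 = max(0, int(math.floor(col - radius - 2)))
    c1 = min(w, int(math.ceil(col + radius + 3)))
    rr = np.arange(r0, r1)[:, None]
    cc = np.arange(c0, c1)[None, :]
    d = np.hypot(rr - row, cc - col)
    plane[r0:r1, c0:c1] += amp * np.clip(radius + 0.5 - d, 0.0, 1.0)


def _render_polygon(plane: np.ndarray, verts_r: np.ndarray, verts_c: np.ndarray, amp: float) -> None:
    rr, cc = skdraw.polygon(verts_r, verts_c, shape=plane.shape)
    plane[rr, cc] += amp


class _Placer:
    """Rejection sampler keeping disk objects from colliding."""

    def __init__(self, shape: tuple[int, int], rng: np.random.Generator, margin: float = 3.0):
        self.shape = shape
        self.rng = rng
        self.margin = margin
        self.centers: list[tuple[float, float]] = []
        self.radii: list[float] = []

    def place(self, radius: float, max_attempts: int = 300) -> tuple[float, float]:
        h, w = self.shape
        lo = radius + 3.0
        for _ in range(max_attempts):
            row = self.rng.uniform(lo, h - lo)
            col = self.rng.uniform(lo, w - lo)
            if self._free(row, col, radius):
                self.register(row, col, radius)
                return row, col
        raise CapacityError(
            f"could not place an object of radius {radius:.1f} px after {max_attempts} attempts"
        )

    def _free(self, row: float, col: float, radius: float) -> bool:
        for (r0, c0), rad0 in zip(self.centers, self.radii):
            if math.hypot(row - r0, col - c0) < radius + rad0 + self.margin:
                return False
        return True

    def register(self, row: float, col: float, radius: float) -> None:
        self.centers.append((row, col))
        self.radii.append(radius)


def generate_field(config: SceneConfig) -> tuple[MultichannelField, GroundTruth]:
    """Render one field and its ground truth; fully determined by the seed."""
    rng = np.random.default_rng(config.seed)
    h, w = config.shape
    planes = {ch: np.zeros((h, w), dtype=float) for ch in ("blue", "green", "red")}
    placer = _Placer((h, w), rng)
    res = config.resolution

    records: list[dict] = []
    oid = 0

    def lognorm(median: float) -> float:
        return float(rng.lognormal(math.log(median), config.intensity_sigma))

    # --- clusters first (they need the most room)
    if config.cluster_sizes is not None:
        sizes = list(config.cluster_sizes)
    else:
        sizes = [int(rng.integers(2, 5)) for _ in range(config.n_clusters)]
    if config.cluster_sizes is not None and config.n_clusters:
        sizes = sizes[: config.n_clusters] if len(sizes) >= config.n_clusters else sizes
    for cid, k in enumerate(sizes):
        radii = rng.uniform(*config.tumor_radius_um, size=k) * res
        extent = float(radii.sum() * 1.4 + 4)
        crow, ccol = placer.place(extent)
        pts = [(crow, ccol)]
        ang = rng.uniform(0, 2 * math.pi)
        for j in range(1, k):
            for _ in range(60):
                turn = rng.uniform(-math.pi / 3, math.pi / 3)
                a = ang + turn
                d = rng.uniform(*config.cluster_spacing) * 0.5 * (radii[j] + radii[j - 1])
                cand = (pts[-1][0] + d * math.sin(a), pts[-1][1] + d * math.cos(a))
                far_enough = all(
                    math.hypot(cand[0] - p[0], cand[1] - p[1]) > 1.8 for p in pts[:-1]
                )
                inside = (
                    radii[j] + 2 < cand[0] < h - radii[j] - 2
                    and radii[j] + 2 < cand[1] < w - radii[j] - 2
                )
                if far_enough and inside:
                    break
            pts.append(cand)
            ang = a
        for j, (prow, pcol) in enumerate(pts):
            amp_b, amp_g = lognorm(config.tumor_intensity), lognorm(config.tumor_intensity)
            _render_disk(planes["blue"], prow, pcol, radii[j], amp_b)
            _render_disk(planes["green"], prow, pcol, radii[j], amp_g)
            records.append(
                dict(object_id=oid, cls="tumor", row=prow, col=pcol,
                     radius_px=float(radii[j]), cluster_id=cid)
            )
            oid += 1

    # --- free tumor cells
    for _ in range(config.n_free_tumor):
        radius = rng.uniform(*config.tumor_radius_um) * res
        row, col = placer.place(radius)
        _render_disk(planes["blue"], row, col, radius, lognorm(config.tumor_intensity))
        _render_disk(planes["green"], row, col, radius, lognorm(config.tumor_intensity))
        records.append(
            dict(object_id=oid, cls="tumor", row=row, col=col,
                 radius_px=float(radius), cluster_id=None)
        )
        oid += 1

    # --- leukocytes: nucleated, CD45+; red membrane extends past the nucleus
    for _ in range(config.n_leukocytes):
        radius = rng.uniform(*config.leukocyte_radius_um) * res
        row, col = placer.place(radius * 1.2)
        _render_disk(planes["blue"], row, col, radius, lognorm(config.leukocyte_intensity))
        _render_disk(planes["red"], row, col, radius * 1.2, lognorm(160.0))
        records.append(
            dict(object_id=oid, cls="leukocyte", row=row, col=col,
                 radius_px=float(radius), cluster_id=None)
        )
        oid += 1

    # --- debris: irregular single-channel polygons
    for _ in range(config.n_debris):
        radius = rng.uniform(2.0, 6.0)
        row, col = placer.place(radius + 2)
        n_vert = int(rng.integers(5, 10))
        angles = np.sort(rng.uniform(0, 2 * math.pi, n_vert))
        rad = radius * rng.uniform(0.5, 1.3, n_vert)
        channel = "green" if rng.random() < 0.5 else "blue"
        _render_polygon(
            planes[channel], row + rad * np.sin(angles), col + rad * np.cos(angles),
            lognorm(config.debris_intensity),
        )
        records.append(
            dict(object_id=oid, cls="debris", row=row, col=col,
                 radius_px=float(radius), cluster_id=None)
        )
        oid += 1

    # --- optics and camera
    lim = (1 << config.bit_depth) - 1
    for ch in planes:
        img = planes[ch]
        if config.blur_sigma > 0:
            img = ndimage.gaussian_filter(img, config.blur_sigma)
        img = img + config.background
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, img.shape)
        planes[ch] = np.clip(np.rint(img), 0, lim).astype(
            np.uint8 if config.bit_depth == 8 else np.uint16
        )

    df = pd.DataFrame.from_records(
        records, columns=["object_id", "cls", "row", "col", "radius_px", "cluster_id"]
    )
    truth = GroundTruth(
        objects=df,
        n_tumor=int((df["cls"] == "tumor").sum()) if len(df) else 0,
        n_leukocyte=int((df["cls"] == "leukocyte").sum()) if len(df) else 0,
        n_debris=int((df["cls"] == "debris").sum()) if len(df) else 0,
        n_clusters=len(sizes),
        cluster_sizes=list(sizes),
    )
    fld = MultichannelField(
        blue=planes["blue"], green=planes["green"], red=planes["red"],
        resolution=res, bit_depth=config.bit_depth,
        field_id=f"synthetic_seed{config.seed}",
    )
    return fld, truth


def dilution_base_config(seed: int = 0) -> SceneConfig:
    """Study conditions for the spiked dilution series (100/300/1000 cells).

    A 768 x 768 px field (~1 mm^2 at 0.75 pixel/um) holding the full
    spiked population, with residual leukocyte contamination and debris.
    """
    return SceneConfig(
        shape=(768, 768),
        n_free_tumor=0,
        n_clusters=0,
        n_leukocytes=150,
        n_debris=10,
        seed=seed,
    )


def generate_dilution_series(
    densities: list[int],
    replicates: int = 3,
    base_config: SceneConfig | None = None,
) -> list[tuple[MultichannelField, "GroundTruth", int]]:
    """One field per (density, replicate) with derived deterministic seeds.

    The tumor count equals the requested density exactly (the wet-lab
    "approximately" is not simulated).  A small number of clusters —
    one per 100 spiked cells, sizes 2-4 — is included, mirroring the
    cluster loads observed in spiked samples; the remainder are free
    cells.  Density 0 yields a pure negative-control field (leukocytes
    and debris only).  Returns (field, truth, density) triples.
    """
    if not densities:
        raise ValueError("densities must be nonempty")
    base = base_config if base_config is not None else dilution_base_config()
    out = []
    for di, density in enumerate(densities):
        for rep in range(replicates):
            seed = (int(base.seed) * 1000003 + 7919 * di + 104729 * rep + 17) % (2**31)
            rng = np.random.default_rng(seed + 1)
            n_clusters = int(density) // 100
            sizes = [int(rng.integers(2, 5)) for _ in range(n_clusters)]
            while sum(sizes) > density:
                sizes.pop()
            cfg = replace(
                base,
                seed=seed,
                n_clusters=len(sizes),
                cluster_sizes=tuple(sizes),
                n_free_tumor=int(density) - sum(sizes),
            )
            fld, truth = generate_field(cfg)
            fld.field_id = f"dilution_d{density}_rep{rep}"
            out.append((fld, truth, int(density)))
    return out
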