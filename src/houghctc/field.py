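"""Reading, writing and the in-memory representation of stained fields.

A *field* is one microscope frame of an IsoFlux-enriched sample stained
with Hoechst 33342 (nucleus, blue), anti-cytokeratin (CK, green) and
anti-CD45 (leukocyte, red).  Channels are held by biological role, not by
file plane order; a ``channel_map`` makes the binding explicit when
loading multi-plane files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

from .errors import ConfigurationError, DimensionError, FormatError

#: channel roles in canonical order
ROLES = ("blue", "green", "red")

#: ITU-R BT.601 luma weights used when a true color image must be collapsed
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class MultichannelField:
    """Three aligned intensity planes plus acquisition metadata.

    Attributes
    ----------
    blue, green, red:
        2-D integer arrays holding the raw Hoechst 33342, CK and CD45
        intensities.  Planes are never rescaled on load.
    resolution:
        Sampling density in pixel/um.  Required; size filters depend on it.
    bit_depth:
        8 or 16.
    field_id:
        Free-text identifier used in reports.
    """

    blue: np.ndarray
    green: np.ndarray
    red: np.ndarray
    resolution: float
    bit_depth: int = 8
    field_id: str = "field"

    def __post_init__(self) -> None:
        self.blue = np.asarray(self.blue)
        self.green = np.asarray(self.green)
        self.red = np.asarray(self.red)
        shapes = {p.shape for p in (self.blue, self.green, self.red)}
        if len(shapes) != 1 or self.blue.ndim != 2:
            raise DimensionError(f"channel planes differ in shape: {sorted(shapes)}")
        if self.resolution is None or not self.resolution > 0:
            raise ConfigurationError("resolution (pixel/um) must be a positive number")
        if self.bit_depth not in (8, 16):
            raise FormatError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        lim = self.intensity_max
        for role in ROLES:
            plane = getattr(self, role)
            if plane.min() < 0 or plane.max() > lim:
                raise FormatError(
                    f"{role} plane intensities outside [0, {lim}] for {self.bit_depth}-bit data"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.blue.shape

    @property
    def height(self) -> int:
        return self.blue.shape[0]

    @property
    def width(self) -> int:
        return self.blue.shape[1]

    @property
    def intensity_max(self) -> int:
        return (1 << self.bit_depth) - 1

    def plane(self, role: str) -> np.ndarray:
        if role not in ROLES:
            raise KeyError(f"unknown channel role {role!r}")
        return getattr(self, role)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an image to a single luminance plane.

    Single-plane input is returned unchanged (each stain is already one
    track).  For an ``(h, w, 3)`` color image the fixed BT.601 weighting
    (0.299 R + 0.587 G + 0.114 B, summing to 1) is applied and the result
    rounded back to the input dtype.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 3:
        w = np.asarray(LUMA_WEIGHTS, dtype=float)
        lum = image.astype(float) @ w
        if np.issubdtype(image.dtype, np.integer):
            return np.rint(lum).astype(image.dtype)
        return lum
    raise FormatError(f"expected (h, w) or (h, w, 3) image, got shape {image.shape}")


def _read_plane(path: Path | str) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        raise FormatError(
            f"{path}: color image given where a single-plane file was expected; "
            "pass it as paths_or_rgb with a channel_map instead"
        )
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single-plane image, got shape {arr.shape}")
    return arr


def _bit_depth_of(planes: Sequence[np.ndarray]) -> int:
    for p in planes:
        if p.dtype.itemsize > 1:
            return 16
    return 8


def load_field(
    paths_or_rgb,
    channel_map: Mapping[str, str] | None = None,
    resolution: float | None = None,
    field_id: str | None = None,
) -> MultichannelField:
    """Load a field from three single-plane TIFFs or one 3-plane TIFF.

    Parameters
    ----------
    paths_or_rgb:
        Either a mapping ``{"blue": path, "green": path, "red": path}``,
        a sequence of three paths in blue/green/red order, or a single
        path to a multi-plane / RGB TIFF (``channel_map`` then names which
        plane carries which stain, e.g. ``{"R": "red", "G": "green",
        "B": "blue"}`` or ``{0: "blue", 1: "green", 2: "red"}``).
    resolution:
        pixel/um.  Mandatory — there is no silent default.
    """
    if resolution is None:
        raise ConfigurationError("resolution (pixel/um) is required; refusing to guess")

    planes: dict[str, np.ndarray] = {}
    if isinstance(paths_or_rgb, Mapping):
        missing = set(ROLES) - set(paths_or_rgb)
        if missing:
            raise FormatError(f"missing channel files for: {sorted(missing)}")
        for role in ROLES:
            planes[role] = _read_plane(paths_or_rgb[role])
        name = Path(str(paths_or_rgb["blue"])).stem
    elif isinstance(paths_or_rgb, (str, Path)):
        arr = tifffile.imread(str(paths_or_rgb))
        if arr.ndim != 3:
            raise FormatError(
                f"{paths_or_rgb}: single file must hold 3 planes, got shape {arr.shape}"
            )
        # accept (3, h, w) or (h, w, 3)
        if arr.shape[0] == 3 and arr.shape[2] != 3:
            stack = {i: arr[i] for i in range(3)}
            letters = {"R": 0, "G": 1, "B": 2}
        elif arr.shape[2] == 3:
            stack = {i: arr[..., i] for i in range(3)}
            letters = {"R": 0, "G": 1, "B": 2}
        else:
            raise FormatError(f"{paths_or_rgb}: cannot map {arr.shape} onto 3 channels")
        cmap = channel_map or {"R": "red", "G": "green", "B": "blue"}
        for key, role in cmap.items():
            idx = letters[key] if isinstance(key, str) else int(key)
            if role not in ROLES:
                raise FormatError(f"channel_map target {role!r} is not one of {ROLES}")
            planes[role] = stack[idx]
        if set(planes) != set(ROLES):
            raise FormatError(f"channel_map does not cover all of {ROLES}: {channel_map}")
        name = Path(str(paths_or_rgb)).stem
    else:
        paths = list(paths_or_rgb)
        if len(paths) != 3:
            raise FormatError(f"expected 3 per-channel files, got {len(paths)}")
        for role, path in zip(ROLES, paths):
            planes[role] = _read_plane(path)
        name = Path(str(paths[0])).stem

    depth = _bit_depth_of(list(planes.values()))
    return MultichannelField(
        blue=planes["blue"],
        green=planes["green"],
        red=planes["red"],
        resolution=float(resolution),
        bit_depth=depth,
        field_id=field_id if field_id is not None else name,
    )


def write_field(field: MultichannelField, directory: Path | str, stem: str | None = None) -> list[Path]:
    """Write the three planes as ``<stem>_{blue,green,red}.tif``; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or field.field_id
    out = []
    for role in ROLES:
        p = directory / f"{stem}_{role}.tif"
        tifffile.imwrite(str(p), field.plane(role))
        out.append(p)
    return out


def write_mask(mask: np.ndarray, path: Path | str) -> None:
    """Persist a binary mask as an 8-bit TIFF (0 background, 1 foreground)."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise DimensionError(f"mask must be 2-D, got shape {mask.shape}")
    tifffile.imwrite(str(path), mask.astype(np.uint8))


def read_mask(path: Path | str) -> np.ndarray:
    """Read a mask written by :func:`write_mask`; any nonzero pixel is foreground."""
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise FormatError(f"{path}: mask file must be single-plane, got {arr.shape}")
    return (arr > 0).astype(np.uint8)
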