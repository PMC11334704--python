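"""Core containers for en face OCT-angiography data.

An *en face* angiogram is a 2-D frontal projection of a retinal vascular
slab — here either the superficial capillary plexus (SCP) or the deep
capillary plexus (DCP) — stored as an 8-bit grayscale grid with a physical
pixel scale.  The foveal avascular zone (FAZ) is delimited by a manually
drawn polygon in pixel coordinates.

Coordinate convention: 0-based, x to the right, y down, pixel centers at
integer coordinates.  Polygons use (x, y) vertex order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path as FsPath
from typing import Sequence

import numpy as np
import tifffile
from matplotlib.path import Path as MplPath
from PIL import Image as PILImage

__all__ = [
    "EnFaceImage",
    "VesselMask",
    "PolygonROI",
    "read_image",
    "write_image",
    "read_roi",
    "write_roi",
]


@dataclass(frozen=True)
class EnFaceImage:
    """8-bit grayscale en face angiogram with acquisition metadata.

    Parameters
    ----------
    pixels
        2-D ``uint8`` intensity array (y down, x right).
    mm_per_px
        Physical pixel pitch in millimetres.  A 6 x 6 mm scan sampled at
        512 px per side has ``mm_per_px = 6 / 512``.
    plexus
        Vascular slab label, ``"SCP"`` or ``"DCP"``.
    eye_id, visit_id
        Free-form identifiers used when assembling cohort tables.
    """

    pixels: np.ndarray
    mm_per_px: float = 6.0 / 512.0
    plexus: str = "SCP"
    eye_id: str = ""
    visit_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        if self.plexus not in ("SCP", "DCP"):
            raise ValueError("plexus must be 'SCP' or 'DCP'")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "EnFaceImage":
        """Copy of this image with new pixel data, metadata preserved."""
        return replace(self, pixels=pixels)

    def astype_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64)


@dataclass(frozen=True)
class VesselMask:
    """Binary vessel map: True where a pixel is classified as vessel."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("mask must be a non-empty 2-D array")
        object.__setattr__(self, "pixels", px.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def foreground_count(self) -> int:
        return int(self.pixels.sum())

    @property
    def density(self) -> float:
        """Foreground fraction of the full grid, in [0, 1]."""
        return self.foreground_count / self.pixels.size


class ROIError(ValueError):
    """Raised for malformed region-of-interest polygons."""


@dataclass(frozen=True)
class PolygonROI:
    """Simple (non-self-intersecting) polygon in pixel coordinates.

    Vertices are ordered (x, y) pairs; at least 3 are required.  Used to
    delimit the manually outlined FAZ.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ROIError("polygon needs >= 3 (x, y) vertices")
        object.__setattr__(self, "vertices", v)
        if _self_intersects(v):
            raise ROIError("polygon is self-intersecting")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def shoelace_area(self) -> float:
        """Analytic polygon area (px^2) by the shoelace formula."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    def centroid(self) -> tuple[float, float]:
        """Area centroid of the polygon."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = cross.sum() / 2.0
        if abs(a) < 1e-12:  # degenerate: fall back to vertex mean
            return float(x.mean()), float(y.mean())
        cx = ((x + xn) * cross).sum() / (6.0 * a)
        cy = ((y + yn) * cross).sum() / (6.0 * a)
        return float(cx), float(cy)

    def scaled(self, factor: float) -> "PolygonROI":
        """Polygon scaled about its centroid; area scales by factor^2."""
        if factor <= 0:
            raise ROIError("scale factor must be positive")
        cx, cy = self.centroid()
        c = np.array([cx, cy])
        return PolygonROI((self.vertices - c) * factor + c)

    def raster(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean grid of pixels whose centers fall inside the polygon.

        Pixel centers sit at integer coordinates; points exactly on the
        boundary count as inside (matplotlib's small positive radius).
        """
        h, w = shape
        yy, xx = np.mgrid[0:h, 0:w]
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        path = MplPath(self.vertices)
        inside = path.contains_points(pts, radius=1e-9)
        return inside.reshape(h, w)

    def raster_area(self, shape: tuple[int, int]) -> int:
        """Pixel-count area: number of pixel centers inside the polygon."""
        return int(self.raster(shape).sum())


def _self_intersects(v: np.ndarray) -> bool:
    """O(n^2) segment-pair crossing test on non-adjacent polygon edges."""
    n = v.shape[0]
    segs = [(v[i], v[(i + 1) % n]) for i in range(n)]

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    def proper_intersect(p1, p2, p3, p4):
        d1 = cross(p3, p4, p1)
        d2 = cross(p3, p4, p2)
        d3 = cross(p1, p2, p3)
        d4 = cross(p1, p2, p4)
        return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))

    for i in range(n):
        for j in range(i + 1, n):
            if j == i or (j + 1) % n == i or (i + 1) % n == j:
                continue  # shared-vertex neighbours
            if proper_intersect(*segs[i], *segs[j]):
                return True
    return False


# ---------------------------------------------------------------------------
# File I/O — 8-bit grayscale PNG/TIFF for images and masks, JSON for ROIs.
# ---------------------------------------------------------------------------

def read_image(path: str | FsPath, *, mm_per_px: float = 6.0 / 512.0,
               plexus: str = "SCP", eye_id: str = "",
               visit_id: str = "") -> EnFaceImage:
    """Read an 8-bit grayscale PNG or TIFF as an :class:`EnFaceImage`."""
    path = FsPath(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(PILImage.open(path).convert("L"))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return EnFaceImage(arr.astype(np.uint8), mm_per_px=mm_per_px,
                       plexus=plexus, eye_id=eye_id, visit_id=visit_id)


def write_image(image: EnFaceImage | VesselMask, path: str | FsPath) -> None:
    """Write an image or mask as 8-bit grayscale PNG or TIFF.

    Masks are written with vessel pixels at 255 on a 0 background.
    """
    path = FsPath(path)
    px = image.pixels
    if px.dtype == bool:
        px = (px * np.uint8(255))
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, px)
    else:
        PILImage.fromarray(px, mode="L").save(path)


def read_roi(path: str | FsPath) -> PolygonROI:
    """Read a polygon ROI from a JSON vertex list ``[[x, y], ...]``."""
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, dict):
        data = data.get("vertices", data)
    verts = np.asarray(data, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise ROIError(
            f"{path}: ROI JSON must be a list of >= 3 [x, y] vertices")
    return PolygonROI(verts)


def write_roi(roi: PolygonROI, path: str | FsPath) -> None:
    with open(path, "w") as fh:
        json.dump([[float(x), float(y)] for x, y in roi.vertices], fh)
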