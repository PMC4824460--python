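"""Adhesive micropattern generation, mask I/O and barrier handling.

Patterns are defined as exact planar geometries (shapely) in micrometres,
centered on the origin, and rasterized onto the simulation lattice by testing
site centers.  ``grid[x, y]`` follows the package-wide axis convention: first
index is x, second is y; the physical position of site ``(i, j)`` is
``((i + 0.5 - nx / 2) * beta, (j + 0.5 - ny / 2) * beta)``, so mirror and
90-degree symmetries of a geometry are exact pixel symmetries of its mask.

Pattern dimensions that were never published (arm widths, openings, star
proportions, ...) are free parameters with documented defaults chosen to
resemble the published thumbnails; they are configuration, not ground truth.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import shapely
from scipy import ndimage
from shapely import affinity
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union

__all__ = [
    "AdhesiveMask", "Barrier", "PatternSpec", "make_pattern",
    "read_mask", "write_mask", "distance_to_adhesive", "PATTERN_NAMES",
]


# --------------------------------------------------------------------------
@dataclass
class AdhesiveMask:
    """Boolean adhesive lattice plus its Euclidean distance map (um)."""

    grid: np.ndarray                  # bool, indexed [x, y]
    beta: float                       # um per site
    _distance_map: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def distance_map(self) -> np.ndarray:
        """Shortest distance (um) from each site to the nearest adhesive site.

        Exact Euclidean distance transform; 0 on adhesive sites, infinite if
        the mask is empty.  Cached after first use.
        """
        if self._distance_map is None:
            self._distance_map = distance_to_adhesive(self.grid, self.beta)
        return self._distance_map

    @property
    def adhesive_area(self) -> float:
        """Total adhesive area in um^2."""
        return float(self.grid.sum()) * self.beta ** 2

    @property
    def empty(self) -> bool:
        return not bool(self.grid.any())


def distance_to_adhesive(grid: np.ndarray, beta: float) -> np.ndarray:
    """Euclidean distance (um) between site centers and the nearest adhesive
    site center.  Exact (not a chamfer approximation) because the effective
    protrusion strength depends exponentially on this distance."""
    grid = np.asarray(grid, dtype=bool)
    if not grid.any():
        return np.full(grid.shape, np.inf)
    return ndimage.distance_transform_edt(~grid) * beta


@dataclass
class Barrier:
    """Region forbidden to cells until a release sweep.

    Before ``release_mcs`` any flip that would put a cell site inside the
    region is invalid; from ``release_mcs`` on, the region imposes nothing.
    ``release_mcs = 0`` means the barrier is never active.
    """

    region: np.ndarray    # bool, [x, y]
    release_mcs: int

    def active(self, mcs: int) -> bool:
        return mcs < self.release_mcs

    def blocks(self, x: int, y: int, mcs: int) -> bool:
        return self.active(mcs) and bool(self.region[x, y])


# --------------------------------------------------------------------------
# pattern geometries (in um, centered at origin)

def _disc(r, cx=0.0, cy=0.0):
    return Point(cx, cy).buffer(r, quad_segs=96)


def _wedge(angle_deg, direction_deg, radius):
    """Open wedge (triangle fan) of the given opening, pointing outward."""
    a0 = math.radians(direction_deg - angle_deg / 2.0)
    a1 = math.radians(direction_deg + angle_deg / 2.0)
    n = 32
    pts = [(0.0, 0.0)]
    for t in np.linspace(a0, a1, n):
        pts.append((2.0 * radius * math.cos(t), 2.0 * radius * math.sin(t)))
    return Polygon(pts)


def _h_shape(width, aspect, bar):
    h = width * aspect
    left = box(-width / 2, -h / 2, -width / 2 + bar, h / 2)
    right = box(width / 2 - bar, -h / 2, width / 2, h / 2)
    cross = box(-width / 2, -bar / 2, width / 2, bar / 2)
    return unary_union([left, right, cross])


def _star(width, n_points=5):
    ro = width / 2.0
    ri = ro * 0.42
    pts = []
    for i in range(2 * n_points):
        r = ro if i % 2 == 0 else ri
        a = math.pi / 2 + i * math.pi / n_points  # one point straight up
        pts.append((r * math.cos(a), r * math.sin(a)))
    return Polygon(pts)


def _geometry(name: str, d: Dict[str, float]) -> shapely.Geometry:
    g = lambda key, default: float(d.get(key, default))
    if name == "square":
        w = g("width", 36.0)
        return box(-w / 2, -w / 2, w / 2, w / 2)
    if name == "circle":
        return _disc(g("width", 32.0) / 2.0)
    if name == "dot":
        return _disc(g("diameter", 6.0) / 2.0)
    if name == "ellipse":
        w = g("width", 40.0)
        a = g("aspect", 0.83)
        return affinity.scale(_disc(w / 2.0), 1.0, a)
    if name == "bar":
        w, h = g("width", 12.0), g("height", 44.0)
        return box(-w / 2, -h / 2, w / 2, h / 2)
    if name == "bar_dot":
        bar = _geometry("bar", d)
        dd = g("dot_diameter", 6.0)
        gap = g("dot_gap", 10.0)
        dot = _disc(dd / 2.0, g("width", 12.0) / 2.0 + gap, 0.0)
        return unary_union([bar, dot])
    if name == "two_bar":
        w = g("width", 30.0)
        h = g("height", 30.0)
        t = g("bar_width", 7.0)
        return unary_union([box(-w / 2, -h / 2, -w / 2 + t, h / 2),
                            box(w / 2 - t, -h / 2, w / 2, h / 2)])
    if name == "H":
        return _h_shape(g("width", 36.0), g("aspect", 1.0), g("bar_width", 7.0))
    if name == "H3":
        # wide variant of H (aspect ratio below the 90-degree switch)
        return _h_shape(g("width", 36.0), g("aspect", 0.63), g("bar_width", 7.0))
    if name == "L":
        al = g("arm_length", 34.0)
        aw = g("arm_width", 11.0)
        # corner at lower-left, arms along +x and +y; recentered below
        geom = unary_union([box(0, 0, al, aw), box(0, 0, aw, al)])
        cx, cy = geom.centroid.x, geom.centroid.y
        return affinity.translate(geom, -cx, -cy)
    if name == "L_dot":
        al = g("arm_length", 34.0)
        aw = g("arm_width", 11.0)
        dd = g("dot_diameter", 6.0)
        geom = unary_union([box(0, 0, al, aw), box(0, 0, aw, al),
                            _disc(dd / 2.0, al - dd / 2.0, al - dd / 2.0)])
        cx, cy = geom.centroid.x, geom.centroid.y
        return affinity.translate(geom, -cx, -cy)
    if name == "X":
        w = g("width", 40.0)
        t = g("bar_width", 10.0)
        b = box(-w / 2, -t / 2, w / 2, t / 2)
        return unary_union([affinity.rotate(b, 45), affinity.rotate(b, -45)])
    if name == "pacman":
        w = g("width", 36.0)
        ang = g("wedge_angle", 90.0)
        return _disc(w / 2.0).difference(_wedge(ang, 90.0, w))
    if name == "C":
        w = g("width", 36.0)
        t = g("ring_width", 8.0)
        ang = g("opening_angle", 60.0)
        ring = _disc(w / 2.0).difference(_disc(w / 2.0 - t))
        return ring.difference(_wedge(ang, 0.0, w))
    if name == "C2":
        dd = dict(d)
        dd.setdefault("opening_angle", 160.0)
        return _geometry("C", dd)
    if name == "crossbow":
        w = g("width", 38.0)
        t = g("ring_width", 7.0)
        ring = _disc(w / 2.0).difference(_disc(w / 2.0 - t))
        arc = ring.intersection(box(-w, 0, w, w))
        stem = box(-t / 2, -w / 2, t / 2, 0)
        return unary_union([arc, stem])
    if name == "arrow":
        w = g("width", 48.0)
        t = g("bar_width", 7.0)
        b = box(0, -t / 2, w / 1.6, t / 2)
        left = affinity.rotate(b, 230, origin=(0, 0))
        right = affinity.rotate(b, 310, origin=(0, 0))
        geom = unary_union([left, right])  # chevron, tip up at origin
        cx, cy = geom.centroid.x, geom.centroid.y
        return affinity.translate(geom, -cx, -cy)
    if name == "star":
        return _star(g("width", 40.0))
    if name == "hourglass":
        w = g("width", 36.0)
        h = g("height", 36.0)
        waist = g("waist", 10.0)
        return Polygon([(-w / 2, -h / 2), (w / 2, -h / 2), (waist / 2, 0),
                        (w / 2, h / 2), (-w / 2, h / 2), (-waist / 2, 0)])
    if name == "triangle":
        s = g("side", 42.0)
        hgt = s * math.sqrt(3) / 2
        return Polygon([(-s / 2, -hgt / 3), (s / 2, -hgt / 3), (0, 2 * hgt / 3)])
    if name == "reuleaux":
        s = g("width", 40.0)
        hgt = s * math.sqrt(3) / 2
        centers = [(-s / 2, -hgt / 3), (s / 2, -hgt / 3), (0, 2 * hgt / 3)]
        geom = _disc(s, *centers[0])
        for cx, cy in centers[1:]:
            geom = geom.intersection(_disc(s, cx, cy))
        cx, cy = geom.centroid.x, geom.centroid.y
        return affinity.translate(geom, -cx, -cy)
    if name == "two_circle":
        r = g("radius", 14.0)
        sep = g("separation", 20.0)
        return unary_union([_disc(r, -sep / 2, 0), _disc(r, sep / 2, 0)])
    if name == "asymmetric":
        # an arbitrary convex-hull-breaking layout: offset disc + bar + dot
        w = g("width", 40.0)
        return unary_union([
            _disc(w * 0.3, -w * 0.15, w * 0.1),
            box(-w * 0.1, -w * 0.45, w * 0.5, -w * 0.15),
            _disc(w * 0.1, w * 0.38, w * 0.3),
        ])
    if name == "ellipse_pacman":
        w = g("width", 44.0)
        a = g("aspect", 0.83)
        ang = g("wedge_angle", 72.0)
        ell = affinity.scale(_disc(w / 2.0), 1.0, a)
        return ell.difference(_wedge(ang, 90.0, w))
    if name == "comb":
        rw = g("reservoir_width", 120.0)
        rh = g("reservoir_height", 240.0)
        sw = g("stripe_width", 10.0)
        sl = g("stripe_length", 200.0)
        pitch = g("stripe_pitch", 120.0)
        n = int(g("n_stripes", max(1, math.floor((rh - sw) / pitch) + 1)))
        total = (n - 1) * pitch
        res = box(-rw, -rh / 2, 0, rh / 2)
        stripes = [box(0, -total / 2 + i * pitch - sw / 2,
                       sl, -total / 2 + i * pitch + sw / 2) for i in range(n)]
        geom = unary_union([res] + stripes)
        cx, cy = geom.centroid.x, geom.centroid.y
        return affinity.translate(geom, -cx, -cy)
    raise ValueError(f"unknown pattern name {name!r}")


PATTERN_NAMES = (
    "L", "L_dot", "bar", "bar_dot", "two_bar", "H", "H3", "square", "X",
    "circle", "ellipse", "pacman", "crossbow", "arrow", "star", "C", "C2",
    "hourglass", "triangle", "reuleaux", "two_circle", "asymmetric",
    "ellipse_pacman", "comb", "dot", "uniform",
)


@dataclass
class PatternSpec:
    """Named pattern with dimensions (um) and a lattice scale."""

    name: str
    dims: Dict[str, float] = field(default_factory=dict)
    beta: float = 1.0
    margin: float = 16.0     # um of medium added around the geometry

    def __post_init__(self):
        if self.name not in PATTERN_NAMES:
            raise ValueError(
                f"unknown pattern name {self.name!r}; known: {PATTERN_NAMES}")
        if self.beta <= 0 or self.margin < 0:
            raise ValueError("beta must be > 0 and margin >= 0")
        for k, v in self.dims.items():
            if v <= 0:
                raise ValueError(f"pattern dimension {k} must be positive")

    @classmethod
    def from_json(cls, path) -> "PatternSpec":
        data = json.loads(Path(path).read_text())
        return cls(name=data["name"], dims=data.get("dims", {}),
                   beta=float(data.get("beta", 1.0)),
                   margin=float(data.get("margin", 16.0)))


def make_pattern(spec: PatternSpec) -> AdhesiveMask:
    """Rasterize a named pattern; deterministic in the spec (no randomness)."""
    if spec.name == "uniform":
        w = spec.dims.get("width", 100.0)
        h = spec.dims.get("height", w)
        nx = int(round(w / spec.beta))
        ny = int(round(h / spec.beta))
        return AdhesiveMask(np.ones((nx, ny), dtype=bool), spec.beta)
    if spec.name == "pacman":
        # analytic rasterization keeps the mirror symmetry exact pixel-wise
        w = float(spec.dims.get("width", 36.0))
        ang = math.radians(float(spec.dims.get("wedge_angle", 90.0)))
        half = w / 2.0 + spec.margin
        n = 2 * int(math.ceil(half / spec.beta))
        idx = np.arange(n)
        X = (idx[:, None] + 0.5 - n / 2) * spec.beta + 0.0 * idx[None, :]
        Y = 0.0 * idx[:, None] + (idx[None, :] + 0.5 - n / 2) * spec.beta
        disc = X * X + Y * Y <= (w / 2.0) ** 2
        wedge = (Y > 0) & (np.abs(X) <= Y * math.tan(ang / 2.0))
        return AdhesiveMask(disc & ~wedge, spec.beta)
    geom = _geometry(spec.name, spec.dims)
    minx, miny, maxx, maxy = geom.bounds
    half = max(abs(minx), abs(maxx), abs(miny), abs(maxy)) + spec.margin
    n = 2 * int(math.ceil(half / spec.beta))
    idx = np.arange(n)
    X = (idx[:, None] + 0.5 - n / 2) * spec.beta + 0 * idx[None, :]
    Y = 0 * idx[:, None] + (idx[None, :] + 0.5 - n / 2) * spec.beta
    inside = shapely.contains_xy(geom, X.ravel(), Y.ravel()).reshape(n, n)
    if not inside.any():
        raise ValueError(f"pattern {spec.name!r} rasterized to an empty mask")
    return AdhesiveMask(inside, spec.beta)


# --------------------------------------------------------------------------
# mask I/O: lossless boolean round trip as PNG/PGM + beta sidecar JSON

def write_mask(mask: AdhesiveMask, path) -> None:
    import imageio.v3 as iio

    path = Path(path)
    img = (mask.grid.T[::-1].astype(np.uint8)) * 255  # image rows = -y
    iio.imwrite(path, img)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({"beta": mask.beta}))


def read_mask(path, beta: Optional[float] = None) -> AdhesiveMask:
    """Read a raster mask (PNG/PGM); nonzero pixels are adhesive.

    Grayscale images are thresholded at half intensity (>= 128) with a
    warning.  ``beta`` defaults to the value in the sidecar JSON, else 1.
    """
    import imageio.v3 as iio

    path = Path(path)
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    vals = np.unique(img)
    if not np.isin(vals, (0, 255)).all():
        warnings.warn("non-binary mask image; thresholding at 50% intensity")
    grid = (img >= 128)[::-1].T
    if beta is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        beta = json.loads(sidecar.read_text())["beta"] if sidecar.exists() else 1.0
    mask = AdhesiveMask(grid, float(beta))
    if mask.empty:
        warnings.warn("mask is empty (all non-adhesive); unusable for seeding")
    return mask
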