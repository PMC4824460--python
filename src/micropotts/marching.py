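"""Refined marching squares for sub-pixel cell geometry.

Cell geometry (area, perimeter, contour polygons) is measured on a smoothed
indicator field rather than on the raw binary lattice: the indicator of a cell
is averaged onto the lattice-vertex grid (each vertex takes the mean of the
four surrounding sites) and the 0.5 level set of that field is extracted with
marching squares using linear interpolation.  On a rasterized disc of radius
56 sites this puts the area within 0.1% and the perimeter within 1.5% of the
analytic values, so line tensions act on physically meaningful lengths and no
calibration between computed and actual perimeter is required.

Conventions
-----------
* ``grid[x, y]`` holds integer cell ids, 0 = medium.  Site ``(x, y)`` occupies
  the unit square ``[x, x+1] x [y, y+1]``; its center is ``(x+0.5, y+0.5)``.
* Vertex ``(a, b)`` sits at lattice corner ``(a, b)`` and averages sites
  ``(a-1, b-1), (a, b-1), (a-1, b), (a, b)``.
* A point is inside the cell when the interpolated field is >= 0.5.  The
  ambiguous saddle cases resolve, through the boundary walk used below, toward
  keeping the cell connected.

All lengths/areas here are in lattice units; callers scale by the lattice
constant beta (and beta**2) to obtain micrometres.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "cell_vertex_field",
    "measure_cell",
    "extract_contours",
    "polygon_area",
    "polygon_length",
]


@njit(cache=True, inline="always")
def _site_is(grid, cid, a, b):
    if a < 0 or b < 0 or a >= grid.shape[0] or b >= grid.shape[1]:
        return 0.0
    return 1.0 if grid[a, b] == cid else 0.0


@njit(cache=True, inline="always")
def _vertex_val(grid, cid, a, b, ox, oy, ov):
    """Vertex-averaged indicator with one site (ox, oy) overridden to ov.

    Pass ox = -1 for no override.
    """
    v = 0.0
    for da in range(-1, 1):
        for db in range(-1, 1):
            sa = a + da
            sb = b + db
            if sa == ox and sb == oy:
                v += ov
            else:
                v += _site_is(grid, cid, sa, sb)
    return 0.25 * v


@njit(cache=True)
def _block_metrics(g00, g10, g11, g01):
    """Area of {g >= 0.5} and contour length inside one unit block.

    Corners counter-clockwise: g00=(0,0), g10=(1,0), g11=(1,1), g01=(0,1).
    """
    b0 = g00 >= 0.5
    b1 = g10 >= 0.5
    b2 = g11 >= 0.5
    b3 = g01 >= 0.5
    case = (1 if b0 else 0) | (2 if b1 else 0) | (4 if b2 else 0) | (8 if b3 else 0)
    if case == 0:
        return 0.0, 0.0
    if case == 15:
        return 1.0, 0.0

    # edge crossings (linear interpolation at 0.5)
    # E0: c0->c1 along y=0; E1: c1->c2 along x=1; E2: c2->c3 along y=1; E3: c3->c0 along x=0
    ex = np.empty(4)
    ey = np.empty(4)
    ex[0] = (0.5 - g00) / (g10 - g00) if b0 != b1 else 0.0
    ey[0] = 0.0
    ex[1] = 1.0
    ey[1] = (0.5 - g10) / (g11 - g10) if b1 != b2 else 0.0
    ex[2] = 1.0 - ((0.5 - g11) / (g01 - g11) if b2 != b3 else 0.0)
    ey[2] = 1.0
    ex[3] = 0.0
    ey[3] = 1.0 - ((0.5 - g01) / (g00 - g01) if b3 != b0 else 0.0)

    # polygon of the inside region: walk the square boundary, keeping inside
    # corners and inserting crossings (this joins diagonal corners -> the
    # connected resolution of the saddle cases)
    px = np.empty(8)
    py = np.empty(8)
    n = 0
    cx = (0.0, 1.0, 1.0, 0.0)
    cy = (0.0, 0.0, 1.0, 1.0)
    ins = (b0, b1, b2, b3)
    for i in range(4):
        if ins[i]:
            px[n] = cx[i]
            py[n] = cy[i]
            n += 1
        if ins[i] != ins[(i + 1) % 4]:
            px[n] = ex[i]
            py[n] = ey[i]
            n += 1
    area = 0.0
    for i in range(n):
        j = (i + 1) % n
        area += px[i] * py[j] - px[j] * py[i]
    area = 0.5 * abs(area)

    # contour length from the marching-squares segment table
    length = 0.0
    if case == 1 or case == 14:
        length = np.hypot(ex[0] - ex[3], ey[0] - ey[3])
    elif case == 2 or case == 13:
        length = np.hypot(ex[1] - ex[0], ey[1] - ey[0])
    elif case == 4 or case == 11:
        length = np.hypot(ex[2] - ex[1], ey[2] - ey[1])
    elif case == 8 or case == 7:
        length = np.hypot(ex[3] - ex[2], ey[3] - ey[2])
    elif case == 3 or case == 12:
        length = np.hypot(ex[1] - ex[3], ey[1] - ey[3])
    elif case == 6 or case == 9:
        length = np.hypot(ex[2] - ex[0], ey[2] - ey[0])
    elif case == 5:  # saddle, connect c0 and c2
        length = (np.hypot(ex[1] - ex[0], ey[1] - ey[0])
                  + np.hypot(ex[3] - ex[2], ey[3] - ey[2]))
    elif case == 10:  # saddle, connect c1 and c3
        length = (np.hypot(ex[0] - ex[3], ey[0] - ey[3])
                  + np.hypot(ex[2] - ex[1], ey[2] - ey[1]))
    return area, length


@njit(cache=True)
def _block_of_cell(grid, cid, i, j, ox, oy, ov):
    """Metrics of block (i, j); block corners are vertices (i..i+1, j..j+1)."""
    g00 = _vertex_val(grid, cid, i, j, ox, oy, ov)
    g10 = _vertex_val(grid, cid, i + 1, j, ox, oy, ov)
    g11 = _vertex_val(grid, cid, i + 1, j + 1, ox, oy, ov)
    g01 = _vertex_val(grid, cid, i, j + 1, ox, oy, ov)
    return _block_metrics(g00, g10, g11, g01)


@njit(cache=True)
def measure_cell_raw(grid, cid, x0, x1, y0, y1):
    """Total marching-squares area and perimeter of cell ``cid``.

    The bounding box [x0, x1] x [y0, y1] (inclusive, site indices) must contain
    all sites of the cell; scanned blocks extend one site beyond it.
    """
    area = 0.0
    per = 0.0
    for i in range(x0 - 1, x1 + 2):
        for j in range(y0 - 1, y1 + 2):
            a, p = _block_of_cell(grid, cid, i, j, -1, -1, 0.0)
            area += a
            per += p
    return area, per


@njit(cache=True)
def ms_delta(grid, cid, x, y, adding):
    """Change of (area, perimeter) of cell ``cid`` when site (x, y) is toggled.

    ``adding`` True: site becomes part of the cell; False: site leaves it.
    ``grid`` is read in its pre-flip state; membership of (x, y) is overridden.
    Only the nine blocks whose corner vertices touch the site are affected;
    the toggle shifts the four vertices at the site's corners by +/- 1/4.
    """
    before = 1.0 if not adding else 0.0
    # 4x4 vertex patch covering blocks (x-1..x+1, y-1..y+1):
    # vertex (x-1+a, y-1+b) for a, b in 0..3
    patch = np.empty((4, 4))
    for a in range(4):
        for b in range(4):
            patch[a, b] = _vertex_val(grid, cid, x - 1 + a, y - 1 + b,
                                      x, y, before)
    da = 0.0
    dp = 0.0
    shift = 0.25 if adding else -0.25
    for i in range(3):
        for j in range(3):
            g00 = patch[i, j]
            g10 = patch[i + 1, j]
            g11 = patch[i + 1, j + 1]
            g01 = patch[i, j + 1]
            if max(g00, g10, g11, g01) >= 0.5:
                a0, p0 = _block_metrics(g00, g10, g11, g01)
                da -= a0
                dp -= p0
    # toggle: vertices at the site's corners are patch[1..2, 1..2]
    patch[1, 1] += shift
    patch[2, 1] += shift
    patch[1, 2] += shift
    patch[2, 2] += shift
    for i in range(3):
        for j in range(3):
            g00 = patch[i, j]
            g10 = patch[i + 1, j]
            g11 = patch[i + 1, j + 1]
            g01 = patch[i, j + 1]
            if max(g00, g10, g11, g01) >= 0.5:
                a1, p1 = _block_metrics(g00, g10, g11, g01)
                da += a1
                dp += p1
    return da, dp


# --------------------------------------------------------------------------
# midpoint marching squares on the binary indicator: the energy discretization
#
# The Hamiltonian prices the contour with the standard 16-case marching
# squares applied directly to the binary lattice (crossings at edge
# midpoints, saddles resolved toward keeping the cell connected).  This
# charges a single-site excursion on a flat edge its full diagonal detour,
# which sets the membrane stiffness relative to the fluctuation allowance
# (T ~ 0.2 lambda_s beta): membranes stay locally smooth and free contours
# are stalled by the line tension as intended.  The smoothed vertex-averaged
# contour above underprices such roughness (a bump costs ~0.24 lattice units
# instead of ~0.83), which at the calibrated T makes membranes entropically
# floppy; it is therefore used only for *reported* geometry, where its
# sub-pixel accuracy matters.

# per-case area enclosed and contour length inside one 2x2 block; bit i set
# means corner i is inside, corners (c0, c1, c2, c3) = ((0,0),(1,0),(1,1),(0,1))
_SQ2 = float(np.sqrt(2.0) / 2.0)
_PLAIN_AREA = np.array([
    0.0, 0.125, 0.125, 0.5, 0.125, 0.5, 0.5, 0.875,
    0.125, 0.5, 0.5, 0.875, 0.5, 0.875, 0.875, 1.0])
_PLAIN_LEN = np.array([
    0.0, _SQ2, _SQ2, 1.0, _SQ2, 2 * _SQ2, 1.0, _SQ2,
    _SQ2, 1.0, 2 * _SQ2, _SQ2, 1.0, _SQ2, _SQ2, 0.0])


@njit(cache=True, inline="always")
def _plain_case(grid, cid, i, j, ox, oy, ov):
    c = 0
    if _gid_is(grid, cid, i, j, ox, oy, ov):
        c |= 1
    if _gid_is(grid, cid, i + 1, j, ox, oy, ov):
        c |= 2
    if _gid_is(grid, cid, i + 1, j + 1, ox, oy, ov):
        c |= 4
    if _gid_is(grid, cid, i, j + 1, ox, oy, ov):
        c |= 8
    return c


@njit(cache=True, inline="always")
def _gid_is(grid, cid, a, b, ox, oy, ov):
    if a < 0 or b < 0 or a >= grid.shape[0] or b >= grid.shape[1]:
        return False
    if a == ox and b == oy:
        return ov > 0.5
    return grid[a, b] == cid


@njit(cache=True)
def measure_cell_plain(grid, cid, x0, x1, y0, y1, area_tab, len_tab):
    """Midpoint marching-square (area, length) of a cell, lattice units."""
    area = 0.0
    per = 0.0
    for i in range(x0 - 1, x1 + 1):
        for j in range(y0 - 1, y1 + 1):
            c = _plain_case(grid, cid, i, j, -1, -1, 0.0)
            area += area_tab[c]
            per += len_tab[c]
    return area, per


@njit(cache=True)
def ms_delta_plain(grid, cid, x, y, adding, area_tab, len_tab):
    """Midpoint marching-square (area, length) change when one site toggles.

    Only the four blocks containing the site are affected; the pre-flip grid
    is read with the site's membership overridden.
    """
    before = 0.0 if adding else 1.0
    after = 1.0 - before
    da = 0.0
    dp = 0.0
    for i in range(x - 1, x + 1):
        for j in range(y - 1, y + 1):
            c0 = _plain_case(grid, cid, i, j, x, y, before)
            c1 = _plain_case(grid, cid, i, j, x, y, after)
            da += area_tab[c1] - area_tab[c0]
            dp += len_tab[c1] - len_tab[c0]
    return da, dp


def cell_vertex_field(indicator: np.ndarray) -> np.ndarray:
    """Vertex-averaged field of a binary indicator (shape grows by one)."""
    ind = np.asarray(indicator, dtype=float)
    g = np.zeros((ind.shape[0] + 1, ind.shape[1] + 1))
    g[:-1, :-1] += ind
    g[1:, :-1] += ind
    g[:-1, 1:] += ind
    g[1:, 1:] += ind
    return 0.25 * g


def polygon_area(poly: np.ndarray) -> float:
    """Shoelace area of a closed polygon given as (n, 2) ``(x, y)`` rows."""
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)))


def polygon_length(poly: np.ndarray, closed: bool = True) -> float:
    d = np.diff(poly, axis=0)
    total = float(np.hypot(d[:, 0], d[:, 1]).sum())
    if closed and not np.allclose(poly[0], poly[-1]):
        total += float(np.hypot(*(poly[0] - poly[-1])))
    return total


def _block_contour_segments(g00, g10, g11, g01, ox, oy):
    """Oriented contour segments of one block (inside kept on the left).

    Walks the unit-square boundary counter-clockwise inserting crossings; a
    contour chord runs from each inside->outside crossing to the following
    outside->inside crossing.  Mirrors the conventions of
    :func:`_block_metrics` exactly (same crossings, connected saddles).
    """
    corners = ((0.0, 0.0, g00), (1.0, 0.0, g10), (1.0, 1.0, g11),
               (0.0, 1.0, g01))
    walk = []  # (x, y, kind): kind 1 = exit crossing, 2 = entry crossing
    for i in range(4):
        x0, y0, v0 = corners[i]
        x1, y1, v1 = corners[(i + 1) % 4]
        in0 = v0 >= 0.5
        in1 = v1 >= 0.5
        if in0:
            walk.append((x0, y0, 0))
        if in0 != in1:
            t = (0.5 - v0) / (v1 - v0)
            walk.append((x0 + t * (x1 - x0), y0 + t * (y1 - y0),
                         1 if in0 else 2))
    segs = []
    n = len(walk)
    for i in range(n):
        x0, y0, k0 = walk[i]
        x1, y1, k1 = walk[(i + 1) % n]
        if k0 == 1 and k1 == 2 and (x0 != x1 or y0 != y1):
            segs.append(((ox + x0, oy + y0), (ox + x1, oy + y1)))
    return segs


def extract_contours(indicator: np.ndarray):
    """Marching-squares contour polylines of a binary indicator.

    Returns a list of (n, 2) closed polygons of ``(x, y)`` points in lattice
    units, oriented with the cell interior on the left, extracted from the
    same vertex-averaged field and block conventions as :func:`measure_cell`
    (so shoelace areas of the polygons reproduce the block-sum area exactly).
    """
    ind = np.asarray(indicator, dtype=float)
    g = cell_vertex_field(ind)
    segs = []
    for i in range(ind.shape[0]):
        for j in range(ind.shape[1]):
            g00 = g[i, j]
            g10 = g[i + 1, j]
            g11 = g[i + 1, j + 1]
            g01 = g[i, j + 1]
            if max(g00, g10, g11, g01) < 0.5 or min(g00, g10, g11, g01) >= 0.5:
                continue
            segs.extend(_block_contour_segments(g00, g10, g11, g01, i, j))
    # chain oriented segments into closed loops
    def key(p):
        return (round(p[0] * 2097152), round(p[1] * 2097152))

    outgoing = {}
    for a, b in segs:
        outgoing.setdefault(key(a), []).append((a, b))
    polys = []
    for a0, b0 in segs:
        k0 = key(a0)
        if k0 not in outgoing or not outgoing[k0]:
            continue
        start = outgoing[k0].pop()
        loop = [start[0], start[1]]
        while True:
            k = key(loop[-1])
            nxt = outgoing.get(k)
            if not nxt:
                break
            _, end = nxt.pop()
            if key(end) == key(loop[0]):
                break
            loop.append(end)
        polys.append(np.asarray(loop))
    return [p for p in polys if p.shape[0] >= 3]


def measure_cell(indicator: np.ndarray, beta: float = 1.0):
    """(area, perimeter) of a binary cell indicator, in physical units.

    Falls back to the raw site outline for cells so small that the smoothed
    field never reaches the 0.5 level (e.g. a single isolated site), so a cell
    always has a nonempty polygonal footprint.
    """
    ind = np.ascontiguousarray(np.asarray(indicator) != 0).astype(np.int32)
    xs, ys = np.nonzero(ind)
    if xs.size == 0:
        return 0.0, 0.0
    a, p = measure_cell_raw(ind, 1, int(xs.min()), int(xs.max()),
                            int(ys.min()), int(ys.max()))
    if a <= 0.0:
        # degenerate cluster invisible to the smoothed field: midpoint
        # marching squares of the raw indicator (a diamond per lone site)
        n = float(ind.sum())
        a, p = 0.5 * n, n * 2.0 * np.sqrt(2.0)
    return a * beta * beta, p * beta
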