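"""Arc detection, circle and ellipse fitting, contour normals.

Free-spanning arcs are the concave stretches of a cell contour that bridge
non-adhesive substrate while facing medium; under the tension-elasticity
picture they are reinforced by peripheral actin bundles and stay circular, so
each detected arc is summarized by its chord (= rest length), contour length
and a least-squares circle radius.

The division axis is extracted from an ellipse fitted to the filled site set
of the contracting mitotic cell via second central moments; a moment fit is
robust against the strong contour noise at the rescaled fluctuation allowance
of the contraction phase, where a contour-only fit would not be.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import kernel as K

__all__ = ["Arc", "EllipseFit", "detect_free_arcs", "fit_circle_arc",
           "fit_ellipse", "estimate_normal"]


@dataclass
class Arc:
    """One free-spanning contour segment (all lengths in um)."""

    endpoints: Tuple[Tuple[float, float], Tuple[float, float]]
    contour_length: float        # L
    chord: float                 # d = L0, the rest length
    fitted_radius: float         # R, least-squares circle (inf if straight)
    points: np.ndarray           # member contour points, (n, 2) um

    @property
    def strain(self) -> float:
        return (self.contour_length - self.chord) / self.chord


@dataclass
class EllipseFit:
    center: Tuple[float, float]  # um
    major_axis: float            # um, full axis length
    minor_axis: float            # um
    orientation: float           # degrees in (-90, 90], polar angle of major axis
    degenerate: bool             # axis ratio below 1.05


def fit_circle_arc(points: np.ndarray,
                   endpoints: Optional[np.ndarray] = None,
                   endpoint_weight: float = 100.0):
    """Weighted algebraic least-squares circle through sample points.

    Minimizes ``sum w_i (x_i^2 + y_i^2 + D x_i + E y_i + F)^2``; endpoint
    samples are weighted by ``endpoint_weight`` so the fitted circle runs
    through them.  Returns ``(center, radius)``; collinear inputs give
    ``radius = inf`` with the center at infinity along the normal.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points to fit a circle")
    cov = np.cov(pts.T)
    evals = np.linalg.eigvalsh(cov)
    if evals[0] <= 1e-10 * max(evals[1], 1e-30):
        return (math.nan, math.nan), math.inf  # collinear: straight segment
    w = np.ones(pts.shape[0])
    if endpoints is not None:
        ep = np.asarray(endpoints, dtype=float)
        for e in ep:
            d2 = np.sum((pts - e) ** 2, axis=1)
            w[int(np.argmin(d2))] = endpoint_weight
    x, y = pts[:, 0], pts[:, 1]
    A = np.stack([x, y, np.ones_like(x)], axis=1)
    b = -(x * x + y * y)
    sw = np.sqrt(w)
    sol, *_ = np.linalg.lstsq(A * sw[:, None], b * sw, rcond=None)
    D, E, F = sol
    cx, cy = -D / 2.0, -E / 2.0
    r2 = cx * cx + cy * cy - F
    if not np.isfinite(r2) or r2 <= 0:
        return (math.nan, math.nan), math.inf
    # collinearity check: residual curvature of the normal equations
    r = math.sqrt(r2)
    span = max(x.max() - x.min(), y.max() - y.min())
    if span > 0 and r > 1e6 * span:
        return (cx, cy), math.inf
    return (cx, cy), r


def fit_ellipse(sites: np.ndarray, beta: float = 1.0) -> EllipseFit:
    """Moment-based ellipse of a filled site set.

    ``sites`` are integer lattice coordinates (n, 2).  Second central moments
    (with the 1/12 per-site square term) give the equivalent solid ellipse;
    the major-axis polar angle, folded to (-90, 90], is the division axis of
    a mitotic cell.
    """
    s = np.asarray(sites, dtype=float)
    if s.shape[0] < 5:
        raise ValueError("need at least 5 sites for an ellipse fit")
    c = s.mean(axis=0)
    d = s - c
    m20 = np.mean(d[:, 0] ** 2) + 1.0 / 12.0
    m02 = np.mean(d[:, 1] ** 2) + 1.0 / 12.0
    m11 = np.mean(d[:, 0] * d[:, 1])
    tr = m20 + m02
    det = math.sqrt(max((m20 - m02) ** 2 + 4 * m11 * m11, 0.0))
    l1 = (tr + det) / 2.0
    l2 = (tr - det) / 2.0
    ang = 0.5 * math.degrees(math.atan2(2 * m11, m20 - m02))
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0
    major = 4.0 * math.sqrt(max(l1, 0.0)) * beta
    minor = 4.0 * math.sqrt(max(l2, 1e-12)) * beta
    return EllipseFit(center=((c[0] + 0.5) * beta, (c[1] + 0.5) * beta),
                      major_axis=major, minor_axis=minor, orientation=ang,
                      degenerate=(major / minor) < 1.05)


def estimate_normal(grid: np.ndarray, cell_id: int, site: Tuple[int, int],
                    mask_radius: int = 9) -> np.ndarray:
    """Outward unit normal at a boundary site by the circular-mask rule.

    A circular mask of the given pixel radius is applied to the boundary
    pixel; the normal is the unit vector from the center of mass of the
    occupied pixels in the mask toward the mask center, i.e. pointing out of
    the cell.  For an isolated site the direction from the cell's center of
    mass to the site is used instead.
    """
    x, y = int(site[0]), int(site[1])
    nx, ny = K.outward_normal(np.ascontiguousarray(grid, dtype=np.int32),
                              cell_id, x, y, mask_radius)
    if nx == 0.0 and ny == 0.0:
        pts = np.argwhere(grid == cell_id)
        if pts.size == 0:
            raise ValueError("cell has no sites")
        com = pts.mean(axis=0)
        v = np.array([x, y], dtype=float) - com
        n = np.hypot(*v)
        if n < 1e-12:
            return np.array([1.0, 0.0])
        return v / n
    return np.array([nx, ny])


def detect_free_arcs(state, cell_id: int,
                     min_run: Optional[int] = None) -> List[Arc]:
    """Free-spanning arcs of one cell.

    Maximal runs of the traced cell contour that lie over non-adhesive
    substrate and face medium (not another cell), of at least ``min_run``
    contour sites (default from the parameter set), become arcs: endpoints
    are the run termini, the chord is their Euclidean distance and a weighted
    least-squares circle provides the radius.  A boundary that is free along
    its entire length has no anchoring endpoints and yields no arcs.
    """
    if min_run is None:
        min_run = state.params.min_arc_run
    beta = state.beta
    contour = state.contour_sites(cell_id)
    n = contour.shape[0]
    if n < min_run:
        return []
    elig = np.array([
        K._site_arc_eligible(state.grid, state.mask, cell_id,
                             int(p[0]), int(p[1]))
        for p in contour])
    if elig.all():
        return []
    start = int(np.argmin(elig))
    order = [(start + i) % n for i in range(1, n + 1)]
    arcs: List[Arc] = []
    run: List[int] = []

    def close_run(run_idx):
        if len(run_idx) < min_run:
            return
        pts = (contour[run_idx] + 0.5) * beta
        d = np.diff(pts, axis=0)
        L = float(np.hypot(d[:, 0], d[:, 1]).sum())
        chord = float(np.hypot(*(pts[-1] - pts[0])))
        if chord < 0.5 * beta:
            return
        _, radius = fit_circle_arc(pts, endpoints=pts[[0, -1]])
        arcs.append(Arc(endpoints=(tuple(pts[0]), tuple(pts[-1])),
                        contour_length=max(L, chord), chord=chord,
                        fitted_radius=radius, points=pts))

    for idx in order:
        if elig[idx]:
            run.append(idx)
        else:
            if run:
                close_run(run)
            run = []
    if run:
        close_run(run)
    return arcs


def arc_table(state, cell_ids=None):
    """Free-arc summary of the given cells (default: all) as a DataFrame
    with columns cell_id, chord, contour_length, fitted_radius (um)."""
    import pandas as pd

    if cell_ids is None:
        cell_ids = state.cell_ids()
    rows = []
    for cid in cell_ids:
        for a in detect_free_arcs(state, cid):
            rows.append({"cell_id": cid, "chord": a.chord,
                         "contour_length": a.contour_length,
                         "fitted_radius": a.fitted_radius})
    return pd.DataFrame(rows, columns=["cell_id", "chord", "contour_length",
                                       "fitted_radius"])
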