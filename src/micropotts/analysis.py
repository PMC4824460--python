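"""Output statistics: orientation histograms, trajectory persistence,
vorticity fields and stripe-front displacement.

Orientations of undirected axes (division axes, COM-COM axes) live on the
half-circle (-90, 90] and are histogrammed in 6-degree bins.  Persistence is
quantified by the decay of heading autocorrelations of the COM trajectory;
the vorticity field measures rotational tissue flow around each cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "OrientationHistogram", "orientation_histogram", "axis_mode",
    "l2_distance", "Trajectory", "persistence_stats", "vorticity_field",
    "front_displacement",
]


@dataclass
class OrientationHistogram:
    bin_edges: np.ndarray      # degrees
    probabilities: np.ndarray  # normalized, sums to 1
    wrapped: bool = False      # True when the first bin wraps across +/-90

    @property
    def bin_centers(self) -> np.ndarray:
        c = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        if self.wrapped:
            c = np.concatenate([[90.0], c])
        return c


def fold_axis(angles_deg: np.ndarray) -> np.ndarray:
    """Fold undirected-axis angles to (-90, 90]."""
    a = np.mod(np.asarray(angles_deg, dtype=float) + 90.0, 180.0) - 90.0
    a[a == -90.0] = 90.0
    return a


def orientation_histogram(angles_deg: Sequence[float], bin_width: float = 6.0,
                          center_on_axes: bool = False) -> OrientationHistogram:
    """Histogram of undirected-axis orientations on (-90, 90].

    With ``center_on_axes`` the bins are centered on multiples of the bin
    width (0, +/-6, ..., 90), the 90-degree bin wrapping circularly across
    the fold at +/-90; otherwise bin edges sit at -90 + k * width.
    """
    a = fold_axis(np.atleast_1d(np.asarray(angles_deg, dtype=float)))
    if a.size == 0:
        raise ValueError("need at least one angle")
    if center_on_axes:
        half = bin_width / 2.0
        edges = np.arange(-90.0 + half, 90.0 + half / 2, bin_width)
        inner, _ = np.histogram(a, bins=edges)
        wrap = int(((a > 90.0 - half) | (a <= -90.0 + half)).sum())
        counts = np.concatenate([[wrap], inner])
        probs = counts / counts.sum()
        return OrientationHistogram(bin_edges=edges, probabilities=probs,
                                    wrapped=True)
    edges = np.arange(-90.0, 90.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(a, bins=edges)
    # the fold maps -90 to +90: values exactly at 90 belong to the top bin
    counts[-1] += int((a == 90.0).sum())
    probs = counts / counts.sum()
    return OrientationHistogram(bin_edges=edges, probabilities=probs)


def axis_mode(angles_deg: Sequence[float], bin_width: float = 6.0) -> float:
    """Modal axis orientation (degrees): center of the most populated
    axis-centered 6-degree bin on the folded half-circle."""
    h = orientation_histogram(angles_deg, bin_width, center_on_axes=True)
    return float(h.bin_centers[int(np.argmax(h.probabilities))])


def l2_distance(p_exp: np.ndarray, p_sim: np.ndarray) -> float:
    """Relative squared histogram distance
    ``L2 = sum_i (p_exp,i - p_sim,i)^2 / p_exp,i^2`` (plain sum, no root).

    Bins with zero reference probability are excluded from the sum.
    """
    import warnings

    p_exp = np.asarray(p_exp, dtype=float)
    p_sim = np.asarray(p_sim, dtype=float)
    if p_exp.shape != p_sim.shape:
        raise ValueError("histograms must have equal bin counts")
    ok = p_exp > 0
    if not ok.all():
        warnings.warn(f"excluding {int((~ok).sum())} zero-probability "
                      "reference bins from the L2 sum")
    return float((((p_exp - p_sim)[ok]) ** 2 / p_exp[ok] ** 2).sum())


# --------------------------------------------------------------------------
@dataclass
class Trajectory:
    """Per-sweep COM positions (um) of one cell."""

    positions: np.ndarray  # (n, 2)

    @property
    def n_sweeps(self) -> int:
        return self.positions.shape[0]


def persistence_stats(traj: Trajectory, stride: int = 100,
                      max_lag: Optional[int] = None,
                      cap: float = 1e6) -> Tuple[float, float, float]:
    """(speed, persistence time, persistence length) of a COM trajectory.

    Headings are taken from displacements over ``stride`` sweeps (suppressing
    lattice noise); the angular autocorrelation ``<cos(theta_{t+d} -
    theta_t)>`` is fitted by ``exp(-d / tau_p)``.  Speed is the mean step
    length per unit time (um/MCS); persistence length = tau_p x speed.  A
    trajectory that never decorrelates reports the cap; an immobile cell
    raises.
    """
    pos = traj.positions
    if pos.shape[0] < 10 * stride:
        raise ValueError("trajectory too short for persistence analysis")
    steps = pos[stride::stride] - pos[:-stride:stride]
    lens = np.hypot(steps[:, 0], steps[:, 1])
    if np.median(lens) < 1e-9:
        raise ValueError("immobile cell: persistence undefined")
    theta = np.arctan2(steps[:, 1], steps[:, 0])
    n = theta.size
    if max_lag is None:
        max_lag = min(n // 4, 200)
    lags = np.arange(1, max_lag + 1)
    corr = np.empty(lags.size)
    for i, d in enumerate(lags):
        corr[i] = np.mean(np.cos(theta[d:] - theta[:-d]))
    # fit of log-correlation over the leading reliably-positive range
    good = corr > 0.05
    if not good[0] or good.sum() < 2:
        tau_steps = 0.5  # decorrelated within one step
    else:
        upto = int(np.argmin(good)) if not good.all() else good.size
        upto = max(upto, 2)
        ll = np.log(corr[:upto])
        slope = np.sum(lags[:upto] * ll) / np.sum(lags[:upto] ** 2)
        if slope >= 0:
            tau_steps = cap / stride
        else:
            tau_steps = -1.0 / slope
    tau_p = min(tau_steps * stride, cap)
    speed = float(np.mean(lens)) / stride
    return speed, float(tau_p), float(min(tau_p * speed, cap))


# --------------------------------------------------------------------------
def vorticity_field(grid: np.ndarray, cell_area: np.ndarray,
                    centers: np.ndarray, velocities: np.ndarray,
                    beta: float) -> np.ndarray:
    """Vorticity (1/MCS) at every lattice site.

    For a site occupied by a central cell of area A (um^2), neighbors up to
    second order are gathered in a disc of radius ``R = 4 sqrt(A / pi)``
    around the site and ``omega = (1/A) sum_cells (v_y r_x - v_x r_y)`` is
    accumulated over cells whose centers lie in the disc, with r the vector
    from the site to the cell center (um) and v the cell velocity (um/MCS,
    averaged over the caller's window).  The sign convention makes a
    counterclockwise rigid rotation positive.  Sites without a central cell
    have omega = 0.

    ``cell_area[cid]``, ``centers[cid]``, ``velocities[cid]`` are indexed by
    cell id; id 0 is medium.
    """
    nx, ny = grid.shape
    omega = np.zeros((nx, ny))
    for i in range(nx):
        for j in range(ny):
            cid = grid[i, j]
            if cid <= 0:
                continue
            A = cell_area[cid]
            if A <= 0:
                continue
            R = 4.0 * math.sqrt(A / math.pi)
            sx = (i + 0.5) * beta
            sy = (j + 0.5) * beta
            rx = centers[:, 0] - sx
            ry = centers[:, 1] - sy
            inside = (rx * rx + ry * ry <= R * R) & (cell_area > 0)
            inside[0] = False
            if not inside.any():
                continue
            omega[i, j] = np.sum(velocities[inside, 1] * rx[inside]
                                 - velocities[inside, 0] * ry[inside]) / A
    return omega


def front_displacement(fronts_um: np.ndarray, barrier_front_um: float,
                       times: Optional[np.ndarray] = None,
                       smooth: int = 5) -> Tuple[np.ndarray, np.ndarray]:
    """Displacement and velocity of the migration front along stripes.

    ``fronts_um[t, s]`` is the foremost cell-occupied coordinate along the
    stripe axis for stripe ``s`` at frame ``t``.  Displacement is the mean
    over stripes minus the barrier position; velocity is the smoothed finite
    difference per frame (scaled by ``times`` spacing if given).
    """
    f = np.asarray(fronts_um, dtype=float)
    disp = f.mean(axis=1) - barrier_front_um
    v = np.gradient(disp)
    if times is not None:
        dt = np.gradient(np.asarray(times, dtype=float))
        v = v / dt
    if smooth > 1 and v.size >= smooth:
        kern = np.ones(smooth) / smooth
        v = np.convolve(v, kern, mode="same")
    return disp, v


def stripe_fronts(grid: np.ndarray, mask: np.ndarray, beta: float,
                  barrier_x: int) -> np.ndarray:
    """Foremost occupied coordinate (um) along +x for each adhesive stripe.

    Stripes are the connected adhesive runs in y beyond ``barrier_x``; a
    stripe with no cells reports the barrier position.
    """
    from scipy import ndimage as _ndi

    stripe_cols = mask[min(barrier_x + 2, mask.shape[0] - 1), :]
    lab, n = _ndi.label(stripe_cols)
    fronts = []
    for s in range(1, n + 1):
        ys = np.nonzero(lab == s)[0]
        occ = (grid[barrier_x:, ys] > 0)
        xs = np.nonzero(occ.any(axis=1))[0]
        front = (barrier_x + xs.max() + 1) * beta if xs.size else barrier_x * beta
        fronts.append(front)
    return np.asarray(fronts)
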