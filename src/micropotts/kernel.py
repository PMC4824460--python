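"""Numba Metropolis kernel for the micropattern cellular Potts model.

All state lives in flat arrays so the inner loop compiles:

``grid``      int32[nx, ny], cell ids, 0 = medium
``mask``      uint8[nx, ny], adhesive substrate
``dist``      float64[nx, ny], distance to nearest adhesive site (um)
``barrier``   uint8[nx, ny], confinement region
``cf``        float64[CF_ROWS, n_cells_max], per-cell floats (see indices)
``ci``        int64[CI_ROWS, n_cells_max], per-cell ints
``ncc``       int64[C, C], unit-edge contact lengths per ordered pair
``zlen``      float64[C, C], zipped (cadherin-bearing) junction length, um
``pv``        float64[PV_ROWS], global parameters

Energy bookkeeping (units nN um):

``H = sum_i [ sig_i * A_i + lam_i * (l_ms,i - beta * ncc_i) ] + sum_i E_arc,i
     - sum_i wfrac_i * E0 * A_ad,i / (A_ref + A_ad,i)
     + sum_(a<b) [ (lcc_a + lcc_b) * beta * ncc_ab + c_ab * Z_ab ]``

where ``A_i``/``l_ms,i`` are marching-square area/perimeter, ``ncc`` counts
unit lattice edges shared by two cells (each cell contributes its own reduced
tension ``lcc`` there) and ``Z`` grows/shrinks only through zipper events at
junction termini (deformation of an existing junction is free).  The
migration bias of a flip is added to ``delta H`` but is not part of ``H``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .marching import (ms_delta_plain, measure_cell_plain, _PLAIN_AREA,
                       _PLAIN_LEN)

# per-cell float rows
SUMX, SUMY, MSA, MSP, ARCE, PX, PY, SIG, LAM, LCC, KK, WFRAC, MU, TT, VX, VY, \
    PCOMX, PCOMY = range(18)
CF_ROWS = 18
# per-cell int rows
NSITES, NADH, MINX, MAXX, MINY, MAXY, CON, ALIVE, PHASE = range(9)
CI_ROWS = 9
# global parameter rows
P_BETA, P_E0, P_AREF, P_C, P_ETA, P_D0, P_POLTHR, P_GRADN, P_MINRUN, \
    P_HASGAP, P_TAU, P_BARRIER = range(12)
PV_ROWS = 12

# scratch layout for evaluate/commit handoff
S_DAF, S_DPF, S_DAT, S_DPT, S_NARC, S_ARC0 = range(6)
SCR_LEN = 6 + 2 * 6  # up to six cells' (id, new arc energy) pairs


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


# --------------------------------------------------------------------------
# local topology guard: removing (x, y) from cell f must keep it 4-connected

@njit(cache=True)
def removal_keeps_connected(grid, x, y, f):
    """Simple-point test: 4-connected components of the in-cell 8-ring that
    contain an axial neighbor must number exactly one."""
    rx = (1, 1, 0, -1, -1, -1, 0, 1)
    ry = (0, 1, 1, 1, 0, -1, -1, -1)
    occ = np.zeros(8, np.uint8)
    n_in = 0
    for i in range(8):
        a = x + rx[i]
        b = y + ry[i]
        if 0 <= a < grid.shape[0] and 0 <= b < grid.shape[1] and grid[a, b] == f:
            occ[i] = 1
            n_in += 1
    if n_in == 0:
        return False  # lone site: removal annihilates the cell
    # count cyclic runs of occupied ring positions containing an even (axial) slot
    runs = 0
    # find a gap to anchor the cyclic scan
    start = -1
    for i in range(8):
        if occ[i] == 0:
            start = i
            break
    if start == -1:
        return True  # fully surrounded by itself: interior site, not proposed anyway
    in_run = False
    has_axial = False
    for s in range(start, start + 8):
        i = s % 8
        if occ[i] == 1:
            if not in_run:
                in_run = True
                has_axial = False
            if i % 2 == 0:
                has_axial = True
        else:
            if in_run and has_axial:
                runs += 1
            in_run = False
    if in_run and has_axial:
        runs += 1
    return runs == 1


# --------------------------------------------------------------------------
# contact edges and the zipper rule

@njit(cache=True, inline="always")
def _gid(grid, a, b, ox, oy, ov):
    if a < 0 or b < 0 or a >= grid.shape[0] or b >= grid.shape[1]:
        return -1
    if a == ox and b == oy:
        return ov
    return grid[a, b]


@njit(cache=True, inline="always")
def _is_pair_seg(grid, p, q, ax, ay, bx, by, ox, oy, ov):
    ia = _gid(grid, ax, ay, ox, oy, ov)
    ib = _gid(grid, bx, by, ox, oy, ov)
    return (ia == p and ib == q) or (ia == q and ib == p)


@njit(cache=True)
def _connected_at_corner(grid, p, q, a, b, ox, oy, ov, e1x, e1y, e2x, e2y):
    """Is some contact segment of pair (p, q), other than the one between
    sites (e1) and (e2), incident to lattice corner (a, b)?"""
    # the four segments through corner (a, b), given as their two sites
    s = ((a - 1, b - 1, a, b - 1),     # vertical,  below
         (a - 1, b, a, b),             # vertical,  above
         (a - 1, b - 1, a - 1, b),     # horizontal, left
         (a, b - 1, a, b))             # horizontal, right
    for i in range(4):
        ax_, ay_, bx_, by_ = s[i]
        same = ((ax_ == e1x and ay_ == e1y and bx_ == e2x and by_ == e2y) or
                (ax_ == e2x and ay_ == e2y and bx_ == e1x and by_ == e1y))
        if same:
            continue
        if _is_pair_seg(grid, p, q, ax_, ay_, bx_, by_, ox, oy, ov):
            return True
    return False


@njit(cache=True)
def _edge_is_zip(grid, p, q, x, y, nx_, ny_, ox, oy, ov):
    """True if the contact edge between sites (x, y) and (nx, ny) lies at or
    beyond a junction terminus in the (possibly overridden) grid: it is a
    zipper event unless flanked by other contact of the same pair at both of
    its endpoints (that case is deformation)."""
    if nx_ == x + 1:        # vertical segment at lattice x+1
        c1a, c1b = x + 1, y
        c2a, c2b = x + 1, y + 1
    elif nx_ == x - 1:
        c1a, c1b = x, y
        c2a, c2b = x, y + 1
    elif ny_ == y + 1:      # horizontal segment at lattice y+1
        c1a, c1b = x, y + 1
        c2a, c2b = x + 1, y + 1
    else:
        c1a, c1b = x, y
        c2a, c2b = x + 1, y
    f1 = _connected_at_corner(grid, p, q, c1a, c1b, ox, oy, ov, x, y, nx_, ny_)
    f2 = _connected_at_corner(grid, p, q, c2a, c2b, ox, oy, ov, x, y, nx_, ny_)
    return not (f1 and f2)


@njit(cache=True)
def contact_effects(grid, cf, ci, zlen, pv, x, y, t, c_global):
    """Contact-energy change of flipping site (x, y) to id t (pre-flip grid).

    Returns (dE_contact, n_events, oth, dn, dz) where per event arrays hold
    the partner id, the unit-edge change of ncc and the zipped-length change
    (um).  dE_contact covers the cc-tension replacement of the cell-medium
    line tension and the cadherin term; the marching-square line change is
    accounted separately by the caller.
    """
    f = grid[x, y]
    beta = pv[P_BETA]
    oth = np.zeros(8, np.int64)
    dn = np.zeros(8, np.int64)
    dz = np.zeros(8)
    nev = 0
    dE = 0.0
    for k in range(4):
        nx_ = x + (1 if k == 0 else -1 if k == 1 else 0)
        ny_ = y + (1 if k == 2 else -1 if k == 3 else 0)
        u = _gid(grid, nx_, ny_, -1, -1, 0)
        if u < 0:
            continue
        # destroyed contact edge of pair (f, u)
        if f > 0 and u > 0 and u != f:
            dE -= beta * (cf[LCC, f] + cf[LCC, u] - cf[LAM, f] - cf[LAM, u])
            unzip = _edge_is_zip(grid, f, u, x, y, nx_, ny_, x, y, t)
            ddz = 0.0
            if unzip:
                # cannot unzip more than is zipped
                already = zlen[f, u]
                for e in range(nev):
                    if oth[e] == u and dn[e] < 0:
                        already += dz[e]
                ddz = -min(beta, max(already, 0.0))
                if ci[CON, f] == 1 and ci[CON, u] == 1:
                    dE += c_global * ddz
            oth[nev] = u
            dn[nev] = -1
            dz[nev] = ddz
            nev += 1
        # created contact edge of pair (t, u); no adherens junctions are
        # zipped while either cell has its cadherin machinery disabled
        if t > 0 and u > 0 and u != t:
            dE += beta * (cf[LCC, t] + cf[LCC, u] - cf[LAM, t] - cf[LAM, u])
            zipped = (ci[CON, t] == 1 and ci[CON, u] == 1
                      and _edge_is_zip(grid, t, u, x, y, nx_, ny_, x, y, t))
            ddz = beta if zipped else 0.0
            if zipped:
                dE += c_global * ddz
            oth[nev] = u
            dn[nev] = 1
            dz[nev] = ddz
            nev += 1
    return dE, nev, oth, dn, dz


# --------------------------------------------------------------------------
# free-spanning arcs: boundary tracing and elastic energy

@njit(cache=True)
def _trace_boundary(grid, cid, x0, x1, y0, y1, out_x, out_y):
    """Moore-neighbor boundary trace of cell ``cid``; returns site count.

    The bounding box must contain the cell (a superset is fine).  The trace
    starts at the minimum-x (then minimum-y) site and walks the outer
    boundary; sites may repeat along one-site-wide spurs.  Termination uses
    Jacob's criterion: the walk stops when it leaves the start site a second
    time in the same direction.
    """
    sx = -1
    sy = -1
    for i in range(x0, x1 + 1):
        done = False
        for j in range(y0, y1 + 1):
            if grid[i, j] == cid:
                sx = i
                sy = j
                done = True
                break
        if done:
            break
    if sx < 0:
        return 0
    rx = (1, 1, 0, -1, -1, -1, 0, 1)
    ry = (0, 1, 1, 1, 0, -1, -1, -1)
    # back: direction from the current site toward the last examined outside
    # site.  The West neighbor (index 4) of the start is outside by the scan.
    cx, cy = sx, sy
    back = 4
    n = 0
    cap = out_x.shape[0]
    first_move = -1
    while n < cap:
        out_x[n] = cx
        out_y[n] = cy
        n += 1
        found = -1
        prev = back
        for s in range(1, 9):
            d = (back + s) % 8
            a = cx + rx[d]
            b = cy + ry[d]
            if 0 <= a < grid.shape[0] and 0 <= b < grid.shape[1] \
                    and grid[a, b] == cid:
                found = d
                break
            prev = d
        if found == -1:
            return n  # isolated site
        if cx == sx and cy == sy:
            if first_move == -1:
                first_move = found
            elif found == first_move:
                return n - 1  # full loop: drop the duplicate start record
        # outside site examined just before the move, in absolute coords
        pbx = cx + rx[prev]
        pby = cy + ry[prev]
        cx += rx[found]
        cy += ry[found]
        dx = pbx - cx
        dy = pby - cy
        for d in range(8):
            if rx[d] == dx and ry[d] == dy:
                back = d
                break
    return n


@njit(cache=True)
def _site_arc_eligible(grid, mask, cid, x, y):
    """Arc membership: boundary site over non-adhesive substrate whose foreign
    4-neighbors are all medium (contour facing medium, not another cell)."""
    if mask[x, y] != 0:
        return False
    for k in range(4):
        a = x + (1 if k == 0 else -1 if k == 1 else 0)
        b = y + (1 if k == 2 else -1 if k == 3 else 0)
        g = _gid(grid, a, b, -1, -1, 0)
        if g > 0 and g != cid:
            return False
    return True


@njit(cache=True)
def arc_energy(grid, mask, cid, x0, x1, y0, y1, k_rig, beta, min_run,
               scratch_x, scratch_y):
    """Total elastic arc energy of one cell: sum over maximal free-spanning
    contour runs of k / (2 L0) * (L - L0)^2 with rest length L0 = chord."""
    if k_rig <= 0.0:
        return 0.0
    n = _trace_boundary(grid, cid, x0, x1, y0, y1, scratch_x, scratch_y)
    if n < min_run:
        return 0.0
    # find an ineligible anchor; a fully eligible boundary has no anchoring
    # endpoints and carries no arc energy
    start = -1
    for i in range(n):
        if not _site_arc_eligible(grid, mask, cid, scratch_x[i], scratch_y[i]):
            start = i
            break
    if start == -1:
        return 0.0
    E = 0.0
    run_len = 0
    run_L = 0.0
    fx = fy = lx = ly = 0
    for s in range(start, start + n + 1):
        i = s % n
        x = scratch_x[i]
        y = scratch_y[i]
        if s > start and _site_arc_eligible(grid, mask, cid, x, y):
            if run_len == 0:
                fx, fy = x, y
            else:
                dx = x - lx
                dy = y - ly
                run_L += np.sqrt(dx * dx + dy * dy)
            lx, ly = x, y
            run_len += 1
        else:
            if run_len >= min_run:
                dx = lx - fx
                dy = ly - fy
                chord = np.sqrt(dx * dx + dy * dy)
                if chord > 0.5:
                    L0 = chord * beta
                    L = run_L * beta
                    if L > L0:
                        E += k_rig / (2.0 * L0) * (L - L0) * (L - L0)
            run_len = 0
            run_L = 0.0
    return E


# --------------------------------------------------------------------------
# migration bias

@njit(cache=True)
def outward_normal(grid, cid, x, y, radius):
    """Mask-centroid outward normal at site (x, y) for cell ``cid``.

    A circular mask of the given pixel radius is centered on the site; the
    normal points from the centroid of in-cell pixels toward the mask center.
    Falls back to the COM-to-site direction encoded as (0, 0) if no in-cell
    pixel lies in the mask (caller handles the fallback).
    """
    sx = 0.0
    sy = 0.0
    cnt = 0
    r2 = radius * radius
    for a in range(x - radius, x + radius + 1):
        for b in range(y - radius, y + radius + 1):
            if (a - x) * (a - x) + (b - y) * (b - y) > r2:
                continue
            if 0 <= a < grid.shape[0] and 0 <= b < grid.shape[1] and grid[a, b] == cid:
                sx += a
                sy += b
                cnt += 1
    if cnt == 0:
        return 0.0, 0.0
    nx_ = x - sx / cnt
    ny_ = y - sy / cnt
    nrm = np.sqrt(nx_ * nx_ + ny_ * ny_)
    if nrm < 1e-12:
        return 0.0, 0.0
    return nx_ / nrm, ny_ / nrm


@njit(cache=True)
def migration_term(grid, dist, cf, ci, pv, x, y, cid, gaining, displaces_cell):
    """Graded-tension energy bias for one affected cell.

    ``gaining`` True: the cell acquires site (x, y) (protrusion, dA = +beta^2),
    else it loses it (retraction, dA = -beta^2).  Contact inhibition zeroes
    protrusive bias into another cell; retraction is never inhibited.
    """
    mu = cf[MU, cid]
    if mu <= 0.0:
        return 0.0
    px = cf[PX, cid]
    py = cf[PY, cid]
    pn = np.sqrt(px * px + py * py)
    if pn < pv[P_POLTHR]:
        return 0.0
    n = ci[NSITES, cid]
    if n <= 0:
        return 0.0
    if pv[P_GRADN] > 0.5:
        dx, dy = outward_normal(grid, cid, x, y, 9)
        if dx == 0.0 and dy == 0.0:
            dx = x + 0.5 - (cf[SUMX, cid] / n + 0.5)
            dy = y + 0.5 - (cf[SUMY, cid] / n + 0.5)
    else:
        dx = x + 0.5 - (cf[SUMX, cid] / n + 0.5)
        dy = y + 0.5 - (cf[SUMY, cid] / n + 0.5)
    rn = np.sqrt(dx * dx + dy * dy)
    if rn < 1e-12:
        return 0.0
    cosa = (dx * px + dy * py) / (rn * pn)
    if cosa > 1.0:
        cosa = 1.0
    elif cosa < -1.0:
        cosa = -1.0
    if cosa == 0.0:
        return 0.0
    front = cosa > 0.0
    if gaining and front and displaces_cell:
        return 0.0  # contact inhibition of locomotion
    beta = pv[P_BETA]
    dA = beta * beta if gaining else -beta * beta
    d = dist[x, y]
    mu_eff = mu * np.exp(-d / pv[P_D0]) if np.isfinite(d) else 0.0
    s = 1.0 if front else -1.0
    return -dA * np.abs(cosa) ** pv[P_ETA] * s * mu_eff


# --------------------------------------------------------------------------
# flip evaluation and commit

@njit(cache=True)
def evaluate_flip(grid, mask, dist, barrier, cf, ci, ncc, zlen, pv,
                  x, y, t, c_global, scr, tr_x, tr_y):
    """Validate a flip of site (x, y) to id ``t`` and compute its energy cost.

    Returns (valid, dH_energy, dH_migration).  ``scr`` receives the geometry
    deltas and new arc energies so a subsequent commit can reuse them.  The
    grid is left unchanged.
    """
    f = grid[x, y]
    if f == t:
        return False, 0.0, 0.0
    if t > 0:
        if x < 2 or y < 2 or x >= grid.shape[0] - 2 or y >= grid.shape[1] - 2:
            return False, 0.0, 0.0
        if pv[P_BARRIER] > 0.5 and barrier[x, y] != 0:
            return False, 0.0, 0.0
    if f > 0:
        if ci[NSITES, f] <= 1:
            return False, 0.0, 0.0
        if not removal_keeps_connected(grid, x, y, f):
            return False, 0.0, 0.0

    beta = pv[P_BETA]
    b2 = beta * beta
    dH = 0.0

    # marching-square geometry deltas (pre-flip grid with override)
    daf = dpf = dat = dpt = 0.0
    if f > 0:
        daf, dpf = ms_delta_plain(grid, f, x, y, False, _PLAIN_AREA, _PLAIN_LEN)
        dH += cf[SIG, f] * daf * b2 + cf[LAM, f] * dpf * beta
    if t > 0:
        dat, dpt = ms_delta_plain(grid, t, x, y, True, _PLAIN_AREA, _PLAIN_LEN)
        dH += cf[SIG, t] * dat * b2 + cf[LAM, t] * dpt * beta
    scr[S_DAF] = daf
    scr[S_DPF] = dpf
    scr[S_DAT] = dat
    scr[S_DPT] = dpt

    # adhesion (saturating)
    if mask[x, y] != 0:
        E0 = pv[P_E0]
        aref = pv[P_AREF]
        if f > 0:
            a0 = ci[NADH, f] * b2
            a1 = a0 - b2
            dH -= cf[WFRAC, f] * E0 * (a1 / (aref + a1) - a0 / (aref + a0))
        if t > 0:
            a0 = ci[NADH, t] * b2
            a1 = a0 + b2
            dH -= cf[WFRAC, t] * E0 * (a1 / (aref + a1) - a0 / (aref + a0))

    # contact tension replacement + zipper term
    dEc, nev, oth, dn, dz = contact_effects(grid, cf, ci, zlen, pv, x, y, t,
                                            c_global)
    dH += dEc

    # free-spanning arc elasticity.  A flip changes the arc energies of the
    # two cells party to it and possibly of cells adjacent to the site (arc
    # eligibility of their boundary depends on facing medium, not another
    # cell), so all of them are recomputed on the flipped grid.
    scr[S_NARC] = 0.0
    if pv[P_HASGAP] > 0.5:
        minrun = int(pv[P_MINRUN])
        aff = np.zeros(6, np.int64)
        cands = np.empty(6, np.int64)
        cands[0] = f
        cands[1] = t
        cands[2] = _gid(grid, x + 1, y, -1, -1, 0)
        cands[3] = _gid(grid, x - 1, y, -1, -1, 0)
        cands[4] = _gid(grid, x, y + 1, -1, -1, 0)
        cands[5] = _gid(grid, x, y - 1, -1, -1, 0)
        naff = 0
        for ci_ in range(6):
            cand = cands[ci_]
            if cand <= 0 or cf[KK, cand] <= 0.0:
                continue
            dup = False
            for e_ in range(naff):
                if aff[e_] == cand:
                    dup = True
                    break
            if not dup:
                aff[naff] = cand
                naff += 1
        grid[x, y] = t
        for e_ in range(naff):
            c_ = aff[e_]
            x0 = min(ci[MINX, c_], x)
            x1 = max(ci[MAXX, c_], x)
            y0 = min(ci[MINY, c_], y)
            y1 = max(ci[MAXY, c_], y)
            e = arc_energy(grid, mask, c_, x0, x1, y0, y1, cf[KK, c_], beta,
                           minrun, tr_x, tr_y)
            dH += e - cf[ARCE, c_]
            scr[S_ARC0 + 2 * e_] = c_
            scr[S_ARC0 + 2 * e_ + 1] = e
        scr[S_NARC] = naff
        grid[x, y] = f

    # graded-tension migration bias (not part of H)
    dHm = 0.0
    if t > 0:
        dHm += migration_term(grid, dist, cf, ci, pv, x, y, t, True, f > 0)
    if f > 0:
        dHm += migration_term(grid, dist, cf, ci, pv, x, y, f, False, False)

    return True, dH, dHm


@njit(cache=True)
def commit_flip(grid, mask, cf, ci, ncc, zlen, pv, x, y, t, c_global, scr):
    """Apply a validated flip and update all incremental caches."""
    f = grid[x, y]
    # contact ledger first (rules read the pre-flip grid)
    _, nev, oth, dn, dz = contact_effects(grid, cf, ci, zlen, pv, x, y, t,
                                          c_global)
    for e in range(nev):
        u = oth[e]
        a = f if dn[e] < 0 else t
        ncc[a, u] += dn[e]
        ncc[u, a] += dn[e]
        z = zlen[a, u] + dz[e]
        if z < 0.0:
            z = 0.0
        zlen[a, u] = z
        zlen[u, a] = z
    grid[x, y] = t
    if f > 0:
        ci[NSITES, f] -= 1
        if mask[x, y] != 0:
            ci[NADH, f] -= 1
        cf[SUMX, f] -= x
        cf[SUMY, f] -= y
        cf[MSA, f] += scr[S_DAF]
        cf[MSP, f] += scr[S_DPF]
    if t > 0:
        ci[NSITES, t] += 1
        if mask[x, y] != 0:
            ci[NADH, t] += 1
        cf[SUMX, t] += x
        cf[SUMY, t] += y
        cf[MSA, t] += scr[S_DAT]
        cf[MSP, t] += scr[S_DPT]
        if x < ci[MINX, t]:
            ci[MINX, t] = x
        if x > ci[MAXX, t]:
            ci[MAXX, t] = x
        if y < ci[MINY, t]:
            ci[MINY, t] = y
        if y > ci[MAXY, t]:
            ci[MAXY, t] = y
    for e_ in range(int(scr[S_NARC])):
        cf[ARCE, int(scr[S_ARC0 + 2 * e_])] = scr[S_ARC0 + 2 * e_ + 1]


# --------------------------------------------------------------------------
# sweeps

@njit(cache=True)
def run_sweeps(grid, mask, dist, barrier, cf, ci, ncc, zlen, pv, n_ids,
               n_sweeps, c_global, cand_x, cand_y, tr_x, tr_y,
               log_ids, log_com):
    """Run ``n_sweeps`` Monte Carlo sweeps.

    Each sweep performs n flip attempts (n = contour sites of all cells) on
    sites drawn from the cell contours and their surrounding sites, then
    advances every cell's velocity and polarity by one velocity-alignment
    step.  ``log_com`` (n_sweeps x len(log_ids) x 2) receives the center of
    mass (um) of the listed cells after each sweep.

    Cell bounding boxes in ``ci`` are refreshed during the candidate scan:
    boxes only grow during a sweep (commits extend them), so the scan window
    derived from the previous sweep's boxes always covers every cell.
    """
    scr = np.zeros(SCR_LEN)
    nx, ny = grid.shape
    nbx0 = np.empty(n_ids + 1, np.int64)
    nbx1 = np.empty(n_ids + 1, np.int64)
    nby0 = np.empty(n_ids + 1, np.int64)
    nby1 = np.empty(n_ids + 1, np.int64)
    for sweep in range(n_sweeps):
        # active window = union of (stale, superset) cell boxes grown by 2
        wx0, wx1, wy0, wy1 = nx, -1, ny, -1
        for c in range(1, n_ids + 1):
            nbx0[c] = nx
            nbx1[c] = -1
            nby0[c] = ny
            nby1[c] = -1
            if ci[ALIVE, c] == 0 or ci[MAXX, c] < 0:
                continue
            if ci[MINX, c] < wx0:
                wx0 = ci[MINX, c]
            if ci[MAXX, c] > wx1:
                wx1 = ci[MAXX, c]
            if ci[MINY, c] < wy0:
                wy0 = ci[MINY, c]
            if ci[MAXY, c] > wy1:
                wy1 = ci[MAXY, c]
        if wx1 < 0:
            return
        wx0 = max(wx0 - 2, 1)
        wy0 = max(wy0 - 2, 1)
        wx1 = min(wx1 + 2, nx - 2)
        wy1 = min(wy1 + 2, ny - 2)
        ncand = 0
        ncontour = 0
        for i in range(wx0, wx1 + 1):
            for j in range(wy0, wy1 + 1):
                g = grid[i, j]
                if g > 0:
                    if i < nbx0[g]:
                        nbx0[g] = i
                    if i > nbx1[g]:
                        nbx1[g] = i
                    if j < nby0[g]:
                        nby0[g] = j
                    if j > nby1[g]:
                        nby1[g] = j
                differs = False
                any_cell = g > 0
                for k in range(4):
                    a = i + (1 if k == 0 else -1 if k == 1 else 0)
                    b = j + (1 if k == 2 else -1 if k == 3 else 0)
                    h = _gid(grid, a, b, -1, -1, 0)
                    if h != g and h >= 0:
                        differs = True
                        if h > 0:
                            any_cell = True
                if differs and any_cell:
                    cand_x[ncand] = i
                    cand_y[ncand] = j
                    ncand += 1
                    if g > 0:
                        ncontour += 1
        for c in range(1, n_ids + 1):
            if ci[ALIVE, c] != 0 and nbx1[c] >= 0:
                ci[MINX, c] = nbx0[c]
                ci[MAXX, c] = nbx1[c]
                ci[MINY, c] = nby0[c]
                ci[MAXY, c] = nby1[c]
        if ncand == 0:
            return
        # one sweep = one attempt per selectable site on average (the cell
        # contours plus the sites surrounding them)
        for _ in range(ncand):
            ii = np.random.randint(ncand)
            x = cand_x[ii]
            y = cand_y[ii]
            f = grid[x, y]
            # propose the value of one of the differing neighbors (an attempt
            # always proposes an actual change)
            nd = 0
            v0 = v1 = v2 = v3 = 0
            for d in range(4):
                a = x + (1 if d == 0 else -1 if d == 1 else 0)
                b = y + (1 if d == 2 else -1 if d == 3 else 0)
                if a < 0 or b < 0 or a >= nx or b >= ny:
                    continue
                h = grid[a, b]
                if h != f:
                    if nd == 0:
                        v0 = h
                    elif nd == 1:
                        v1 = h
                    elif nd == 2:
                        v2 = h
                    else:
                        v3 = h
                    nd += 1
            if nd == 0:
                continue
            pick = np.random.randint(nd)
            t = v0 if pick == 0 else v1 if pick == 1 else v2 if pick == 2 else v3
            ok, dH, dHm = evaluate_flip(grid, mask, dist, barrier, cf, ci,
                                        ncc, zlen, pv, x, y, t, c_global,
                                        scr, tr_x, tr_y)
            if not ok:
                continue
            tot = dH + dHm
            if tot > 0.0:
                if f > 0 and t > 0:
                    T = 0.5 * (cf[TT, f] + cf[TT, t])
                else:
                    T = cf[TT, t] if t > 0 else cf[TT, f]
                if np.random.random() >= np.exp(-tot / T):
                    continue
            commit_flip(grid, mask, cf, ci, ncc, zlen, pv, x, y, t,
                        c_global, scr)
        # velocity and polarity update, once per sweep
        beta = pv[P_BETA]
        tau = pv[P_TAU]
        for c in range(1, n_ids + 1):
            if ci[ALIVE, c] == 0 or ci[NSITES, c] == 0:
                continue
            comx = (cf[SUMX, c] / ci[NSITES, c] + 0.5) * beta
            comy = (cf[SUMY, c] / ci[NSITES, c] + 0.5) * beta
            cf[VX, c] = comx - cf[PCOMX, c]
            cf[VY, c] = comy - cf[PCOMY, c]
            cf[PCOMX, c] = comx
            cf[PCOMY, c] = comy
            if tau >= 1.0:
                cf[PX, c] += (cf[VX, c] - cf[PX, c]) / tau
                cf[PY, c] += (cf[VY, c] - cf[PY, c]) / tau
        for kk_ in range(log_ids.shape[0]):
            c = log_ids[kk_]
            if ci[NSITES, c] > 0:
                log_com[sweep, kk_, 0] = (cf[SUMX, c] / ci[NSITES, c] + 0.5) * beta
                log_com[sweep, kk_, 1] = (cf[SUMY, c] / ci[NSITES, c] + 0.5) * beta


@njit(cache=True)
def remeasure_cell(grid, mask, cf, ci, x0, x1, y0, y1, cid, beta, min_run,
                   tr_x, tr_y):
    """Recompute every per-cell cache of ``cid`` from scratch."""
    n = 0
    nad = 0
    sx = 0.0
    sy = 0.0
    mnx, mxx, mny, mxy = grid.shape[0], -1, grid.shape[1], -1
    for i in range(x0, x1 + 1):
        for j in range(y0, y1 + 1):
            if grid[i, j] == cid:
                n += 1
                sx += i
                sy += j
                if mask[i, j] != 0:
                    nad += 1
                if i < mnx:
                    mnx = i
                if i > mxx:
                    mxx = i
                if j < mny:
                    mny = j
                if j > mxy:
                    mxy = j
    ci[NSITES, cid] = n
    ci[NADH, cid] = nad
    cf[SUMX, cid] = sx
    cf[SUMY, cid] = sy
    if n == 0:
        ci[ALIVE, cid] = 0
        cf[MSA, cid] = 0.0
        cf[MSP, cid] = 0.0
        cf[ARCE, cid] = 0.0
        return
    ci[MINX, cid] = mnx
    ci[MAXX, cid] = mxx
    ci[MINY, cid] = mny
    ci[MAXY, cid] = mxy
    a, p = measure_cell_plain(grid, cid, mnx, mxx, mny, mxy,
                              _PLAIN_AREA, _PLAIN_LEN)
    cf[MSA, cid] = a
    cf[MSP, cid] = p
    cf[ARCE, cid] = arc_energy(grid, mask, cid, mnx, mxx, mny, mxy,
                               cf[KK, cid], beta, min_run, tr_x, tr_y)
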