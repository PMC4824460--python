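"""Hamiltonian terms and energy accounting.

The effective energy of a configuration is::

    H = sum_cells [ sigma A + lambda_s l_cm ] + sum_arcs k/(2 L0) (L - L0)^2
        - sum_cells E0 A_ad / (A_ref + A_ad)
        + sum_junctions [ (lambda_cc,a + lambda_cc,b) l_cc + c Z ]

with marching-square area A and cell-medium contour length l_cm, unit-edge
junction lengths l_cc (one lattice edge = beta um), and zipped junction
length Z that only changes through zipper events at junction termini.  The
migration bias (graded-tension term) enters flip decisions but is not part
of H.

:func:`total_energy` evaluates everything from scratch and is the oracle
against which the incremental kernel deltas are audited.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from . import kernel as K
from .lattice import FlipProposal, LatticeState

__all__ = ["EnergyBreakdown", "total_energy", "delta_energy",
           "contact_delta", "migration_delta", "ContactLedger"]


@dataclass
class EnergyBreakdown:
    """Energy terms in nN um."""

    surface: float
    line: float       # lambda_s on the cell-medium contour only
    arcs: float
    adhesion: float   # in (-E0, 0]
    contact: float    # junction tension + cadherin term
    total: float


@dataclass
class ContactLedger:
    """Per-pair junction state: unit-edge contact length and zipped length.

    Thin typed view over the matrices the kernel updates in place.
    """

    ncc: np.ndarray      # unit-edge counts, symmetric
    zlen: np.ndarray     # zipped length, um, symmetric
    beta: float

    def contact_length(self, a: int, b: int) -> float:
        return float(self.ncc[a, b]) * self.beta

    def zipped_length(self, a: int, b: int) -> float:
        return float(self.zlen[a, b])


def total_energy(state: LatticeState) -> EnergyBreakdown:
    """From-scratch evaluation of every energy term (the audit oracle)."""
    p = state.params
    beta = p.beta
    b2 = beta * beta
    surface = line = arcs = adhesion = contact = 0.0
    ids = state.cell_ids()
    # fresh contact recount
    ncc = np.zeros_like(state.ncc)
    g = state.grid
    for axis in (0, 1):
        a = g[:-1, :] if axis == 0 else g[:, :-1]
        b = g[1:, :] if axis == 0 else g[:, 1:]
        sel = (a > 0) & (b > 0) & (a != b)
        if sel.any():
            np.add.at(ncc, (a[sel], b[sel]), 1)
            np.add.at(ncc, (b[sel], a[sel]), 1)
    for cid in ids:
        area_ms, per_ms = state.measure_energy_geometry(cid)
        xs = state.sites_of(cid)
        x0, x1 = int(xs[:, 0].min()), int(xs[:, 0].max())
        y0, y1 = int(xs[:, 1].min()), int(xs[:, 1].max())
        surface += state.cf[K.SIG, cid] * area_ms
        l_cc = float(ncc[cid, 1:].sum()) * beta
        line += state.cf[K.LAM, cid] * (per_ms - l_cc)
        arcs += K.arc_energy(state.grid, state.mask, cid, x0, x1, y0, y1,
                             state.cf[K.KK, cid], beta, p.min_arc_run,
                             state._tr_x, state._tr_y)
        a_ad = float(state.ci[K.NADH, cid]) * b2
        adhesion += -state.cf[K.WFRAC, cid] * p.E0 * a_ad / (p.A_ref + a_ad)
    for i in ids:
        for j in ids:
            if j <= i or ncc[i, j] == 0 and state.zlen[i, j] == 0.0:
                continue
            contact += (state.cf[K.LCC, i] + state.cf[K.LCC, j]) * ncc[i, j] * beta
            if state.ci[K.CON, i] and state.ci[K.CON, j]:
                contact += p.c * state.zlen[i, j]
    total = surface + line + arcs + adhesion + contact
    return EnergyBreakdown(surface=surface, line=line, arcs=arcs,
                           adhesion=adhesion, contact=contact, total=total)


def delta_energy(state: LatticeState, prop: FlipProposal
                 ) -> Tuple[bool, float, float]:
    """Incremental energy change of one flip, without applying it.

    Returns ``(valid, dH, dH_m)``: the change of H and the migration bias.
    On every audited flip ``dH`` equals ``total_energy(after) -
    total_energy(before)`` to within floating tolerance.
    """
    x, y = prop.site
    if state.grid[x, y] != prop.from_id:
        raise ValueError("proposal is stale: from_id does not match grid")
    return K.evaluate_flip(state.grid, state.mask, state.dist, state.barrier,
                           state.cf, state.ci, state.ncc, state.zlen,
                           state.param_vector(), x, y, prop.to_id,
                           state.params.c, state._scr, state._tr_x,
                           state._tr_y)


def migration_delta(state: LatticeState, prop: FlipProposal) -> float:
    """Graded-tension migration bias of a flip (Delta H_m).

    The angle alpha locates the flipped site relative to the cell's polarity
    direction (from the COM in polar-angle mode, via the outward contour
    normal in contour-normal mode); the bias is
    ``-dA |cos a|^eta sign(cos a) mu exp(-d/d0)``, zeroed for protrusions
    that would invade another cell (contact inhibition of locomotion) and
    never zeroed for retractions at the rear.
    """
    x, y = prop.site
    pv = state.param_vector()
    dHm = 0.0
    if prop.to_id > 0:
        dHm += K.migration_term(state.grid, state.dist, state.cf, state.ci,
                                pv, x, y, prop.to_id, True, prop.from_id > 0)
    if prop.from_id > 0:
        dHm += K.migration_term(state.grid, state.dist, state.cf, state.ci,
                                pv, x, y, prop.from_id, False, False)
    return dHm


def contact_delta(grid: np.ndarray, site: Tuple[int, int], to_id: int,
                  params, zlen: Optional[np.ndarray] = None) -> float:
    """Unit-edge interface bookkeeping of a single flip, as drawn in the
    zipper picture of junction formation.

    The flipping cell's cell-medium boundary change is charged at lambda_s
    per unit edge; every created or destroyed cell-cell unit edge carries the
    tensions of both cells (2 lambda_cc); the cadherin line density c is
    charged only for zipper events, i.e. contact edges created beyond a
    junction terminus or where no junction existed (and symmetrically for
    breakage).  Deformation of an existing junction is free.

    This is the illustrative lattice-edge accounting of junction energetics;
    the full Hamiltonian prices the cell-medium contour with marching-square
    lengths instead (see :func:`total_energy`).
    """
    x, y = int(site[0]), int(site[1])
    g = np.ascontiguousarray(grid, dtype=np.int32)
    f = int(g[x, y])
    t = int(to_id)
    if f == t:
        raise ValueError("flip must change the site id")
    lam = params.lambda_s
    lcc = params.lambda_cc
    c = params.c
    moving = t if t > 0 else f
    dE = 0.0
    d_medium = 0
    for k in range(4):
        a = x + (1 if k == 0 else -1 if k == 1 else 0)
        b = y + (1 if k == 2 else -1 if k == 3 else 0)
        if a < 0 or b < 0 or a >= g.shape[0] or b >= g.shape[1]:
            continue
        u = int(g[a, b])
        # cell-medium edges of the moving cell
        pre_med = (f == moving and u == 0) or (u == moving and f == 0)
        post_u = u if (a, b) != (x, y) else t
        post_here = t
        post_med = (post_here == moving and post_u == 0) or \
                   (post_u == moving and post_here == 0)
        d_medium += int(post_med) - int(pre_med)
        # cell-cell edges
        if f > 0 and u > 0 and u != f:
            dE -= 2.0 * lcc
            if zlen is None or zlen[f, u] > 0:
                if K._edge_is_zip(g, f, u, x, y, a, b, x, y, t):
                    dE -= c  # unzip: breaking junctions costs energy
        if t > 0 and u > 0 and u != t:
            dE += 2.0 * lcc
            if K._edge_is_zip(g, t, u, x, y, a, b, x, y, t):
                dE += c
    dE += lam * d_medium
    return dE
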