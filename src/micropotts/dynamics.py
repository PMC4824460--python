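"""Metropolis dynamics, polarity, mitosis and simulation orchestration.

Time is measured in Monte Carlo sweeps (MCS).  One sweep performs n flip
attempts, n being the number of contour sites of all cells; candidate sites
are drawn from the cell contours and the sites surrounding them, a random
4-neighbor's index is copied, validity (connectivity, barrier) is checked and
the move is accepted if it lowers the total energy change ``dH`` (including
the migration bias) and with probability ``exp(-dH / T)`` otherwise.

After every sweep each cell's velocity ``v`` (COM displacement per sweep) is
measured and its polarity relaxes toward it: ``p <- p + (v - p) / tau``
(velocity alignment).  This makes the polarity an exponentially weighted
memory of past displacements with lag ``tau``.

Cell division follows the contraction protocol: at mitosis onset the surface
tension is inverted (it then resists contraction like an osmotic pressure),
the line tension is raised to ``2 sigma sqrt(A_b / pi)`` (twice the Laplace
value of the pre-division disc, guaranteeing net contraction), adhesion and
arc rigidity are switched off, the fluctuation allowance is rescaled by the
tension ratio and the cell's cadherin bonds disassemble.  When the area has
contracted to 0.36 of the pre-division area A_b an ellipse is fitted to the
cell; its major axis is the division axis, and the cell is split through its
COM perpendicular to that axis.  Interphase cells divide stochastically with
the Hill rate ``r(A) = r0 A^m / (A^m + A0^m)``, which suppresses
proliferation in crowded tissue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from . import kernel as K
from .geometry import fit_ellipse
from .lattice import LatticeState
from .params import ParameterSet
from .patterns import AdhesiveMask, Barrier

__all__ = ["Simulation", "update_polarity", "division_rate", "Schedule"]


def update_polarity(p: np.ndarray, v: np.ndarray, tau: float) -> np.ndarray:
    """One velocity-alignment step: p <- p + (v - p) / tau."""
    if tau < 1:
        raise ValueError("tau must be >= 1 MCS")
    p = np.asarray(p, dtype=float)
    v = np.asarray(v, dtype=float)
    return p + (v - p) / tau


def division_rate(A: float, params: ParameterSet) -> float:
    """Hill proliferation rate r(A) = r0 A^m / (A^m + A0^m), per MCS."""
    if A < 0:
        raise ValueError("area must be >= 0")
    if A == 0 or params.r0 == 0:
        return 0.0
    am = A ** params.m
    return params.r0 * am / (am + params.A0 ** params.m)


@dataclass
class Schedule:
    """Run phases: spreading, then (optionally) division and migration."""

    spread_mcs: int = 2000
    total_mcs: int = 2000
    division: bool = False
    seed: int = 0


class Simulation:
    """A reproducible cellular Potts run on one adhesive mask.

    Identical seed and configuration give bit-identical trajectories.
    """

    def __init__(self, params: ParameterSet, mask: AdhesiveMask,
                 seed: int = 0, max_cells: int = 512,
                 barrier: Optional[Barrier] = None):
        self.params = params
        self.state = LatticeState(mask, params, max_cells=max_cells,
                                  barrier=barrier)
        self.rng = np.random.default_rng(seed)
        K.seed_rng(int(self.rng.integers(2 ** 31 - 1)))
        self.division_log: List[dict] = []

    # -- seeding -------------------------------------------------------------
    def default_seed_radius(self) -> float:
        return 0.5 * math.sqrt(self.params.A0 / math.pi)

    def seed_cell(self, center_um: Optional[Tuple[float, float]] = None,
                  radius_um: Optional[float] = None) -> int:
        """Seed one round cell, by default at the adhesive centroid."""
        st = self.state
        if center_um is None:
            pts = np.argwhere(st.mask > 0)
            c = pts.mean(axis=0)
            center_um = ((c[0] + 0.5) * st.beta, (c[1] + 0.5) * st.beta)
        if radius_um is None:
            radius_um = self.default_seed_radius()
        rec = st.rasterize_disc(center_um, radius_um)
        return rec.id

    def seed_cells(self, n: int, radius_um: Optional[float] = None,
                   region: Optional[np.ndarray] = None,
                   max_tries: int = 20000) -> List[int]:
        """Seed n non-overlapping round cells at random positions.

        Positions are drawn uniformly over ``region`` (default: the adhesive
        mask, restricted to the confinement region while a barrier is set).
        """
        st = self.state
        if radius_um is None:
            radius_um = self.default_seed_radius()
        if region is None:
            region = st.mask > 0
            if st.barrier_release > 0:
                region = region & (st.barrier == 0)
        cand = np.argwhere(region)
        if cand.shape[0] == 0:
            raise ValueError("no seedable sites in region")
        r_l = radius_um / st.beta
        placed: List[Tuple[float, float]] = []
        ids: List[int] = []
        tries = 0
        while len(ids) < n and tries < max_tries:
            tries += 1
            i, j = cand[self.rng.integers(cand.shape[0])]
            if i < r_l + 3 or j < r_l + 3 or i > st.width - r_l - 4 \
                    or j > st.height - r_l - 4:
                continue
            ok = all((i - a) ** 2 + (j - b) ** 2 > (2 * r_l + 1) ** 2
                     for a, b in placed)
            if not ok:
                continue
            rec = st.rasterize_disc(((i + 0.5) * st.beta, (j + 0.5) * st.beta),
                                    radius_um)
            placed.append((i, j))
            ids.append(rec.id)
        if len(ids) < n:
            raise RuntimeError(
                f"could not place {n} cells of radius {radius_um} um "
                f"(placed {len(ids)})")
        return ids

    # -- stepping ------------------------------------------------------------
    def _kernel_run(self, n_sweeps: int, log_ids: Optional[np.ndarray] = None,
                    log_com: Optional[np.ndarray] = None) -> None:
        st = self.state
        if log_ids is None:
            log_ids = np.zeros(0, dtype=np.int64)
            log_com = np.zeros((n_sweeps, 0, 2))
        K.run_sweeps(st.grid, st.mask, st.dist, st.barrier, st.cf, st.ci,
                     st.ncc, st.zlen, st.param_vector(), st.n_ids, n_sweeps,
                     st.params.c, st._cand_x, st._cand_y, st._tr_x, st._tr_y,
                     log_ids, log_com)
        st.mcs += n_sweeps

    def run(self, n_sweeps: int, division: bool = False,
            track: Optional[Sequence[int]] = None) -> Optional[np.ndarray]:
        """Advance the simulation.

        With ``track`` set, returns the tracked cells' COM (um) after every
        sweep, shape (n_sweeps, len(track), 2).  With ``division`` enabled,
        each interphase cell divides per sweep with its Hill rate; mitoses
        run inline (all cells keep evolving during a contraction).
        """
        st = self.state
        log_ids = None
        log_com = None
        if track is not None:
            log_ids = np.asarray(list(track), dtype=np.int64)
            log_com = np.zeros((n_sweeps, len(track), 2))
        done = 0
        while done < n_sweeps:
            chunk = n_sweeps - done
            if st.mcs < st.barrier_release:
                chunk = min(chunk, st.barrier_release - st.mcs)
            if division and self.params.r0 > 0:
                chunk = 1
            if log_com is not None:
                self._kernel_run(chunk, log_ids, log_com[done:done + chunk])
            else:
                self._kernel_run(chunk)
            done += chunk
            if division and self.params.r0 > 0:
                for cid in list(self.state.cell_ids()):
                    if self.state.ci[K.PHASE, cid]:
                        continue
                    r = division_rate(self.state.area_um2(cid), self.params)
                    if r > 0 and self.rng.random() < r:
                        self.divide_cell(cid)
        return log_com

    # -- mitosis -------------------------------------------------------------
    def divide_cell(self, cid: int, max_sweeps: int = 20000
                    ) -> Tuple[float, Tuple[int, int]]:
        """Run the full mitotic contraction protocol on one cell.

        Returns the recorded division-axis orientation (degrees, polar angle
        in (-90, 90]) and the two daughter ids.  All other cells continue
        their normal dynamics during the contraction.
        """
        st = self.state
        p = self.params
        A_b = st.area_um2(cid)
        st.born_area[cid] = A_b
        lam_bar = p.contraction_line_tension(A_b)
        st.cf[K.SIG, cid] = -p.sigma
        st.cf[K.LAM, cid] = lam_bar
        st.cf[K.LCC, cid] = p.lambda_cc_factor * lam_bar
        st.cf[K.KK, cid] = 0.0
        st.cf[K.WFRAC, cid] = p.W_contract_fraction
        st.cf[K.MU, cid] = 0.0
        st.cf[K.TT, cid] = p.T * lam_bar / p.lambda_s
        st.ci[K.CON, cid] = 0
        st.ci[K.PHASE, cid] = 1
        st.zlen[cid, :] = 0.0
        st.zlen[:, cid] = 0.0
        st.remeasure(cid)  # arc energy drops to zero with k = 0
        target = p.division_area_ratio * A_b
        sweeps = 0
        while st.area_um2(cid) > target and sweeps < max_sweeps:
            self._kernel_run(2)
            sweeps += 2
        sites = st.sites_of(cid)
        degenerate = False
        try:
            ell = fit_ellipse(sites)
            degenerate = ell.degenerate
            angle = ell.orientation
        except ValueError:
            degenerate = True
            angle = 0.0
        if degenerate:
            # symmetric roundup: the axis is drawn uniformly
            angle = float(self.rng.uniform(-90.0, 90.0))
        daughters = self._split_cell(cid, angle)
        self.division_log.append({"mcs": st.mcs, "parent": cid,
                                  "angle": angle, "degenerate": degenerate,
                                  "A_b": A_b, "contraction_mcs": sweeps})
        return angle, daughters

    def _split_cell(self, cid: int, angle_deg: float) -> Tuple[int, int]:
        """Split a cell through its COM perpendicular to the division axis."""
        st = self.state
        sites = st.sites_of(cid)
        u = np.array([math.cos(math.radians(angle_deg)),
                      math.sin(math.radians(angle_deg))])
        proj = (sites - sites.mean(axis=0)) @ u
        neg = proj < 0
        if not neg.any() or neg.all():
            neg = proj <= np.median(proj)
            if neg.all():
                neg[np.argmax(proj)] = False
        new_id = st.new_cell_id()
        for (i, j), m in zip(sites, neg):
            if m:
                st.grid[i, j] = new_id
        self._reconnect_daughters(cid, new_id)
        for d in (cid, new_id):
            st._init_cell_defaults(d)
            st.ci[K.PHASE, d] = 0
            st.cf[K.PX, d] = 0.0
            st.cf[K.PY, d] = 0.0
            st.remeasure(d)
            if st.ci[K.NSITES, d] > 0:
                st.cf[K.PCOMX, d] = (st.cf[K.SUMX, d] / st.ci[K.NSITES, d]
                                     + 0.5) * st.beta
                st.cf[K.PCOMY, d] = (st.cf[K.SUMY, d] / st.ci[K.NSITES, d]
                                     + 0.5) * st.beta
        st.rebuild_contacts()
        # daughters start with fresh, unzipped junctions
        for d in (cid, new_id):
            st.zlen[d, :] = 0.0
            st.zlen[:, d] = 0.0
        return cid, new_id

    def _reconnect_daughters(self, a: int, b: int, max_iter: int = 4) -> None:
        """Reassign stray fragments so both daughters are 4-connected."""
        st = self.state
        struct = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        for _ in range(max_iter):
            changed = False
            for d, other in ((a, b), (b, a)):
                lab, n = ndimage.label(st.grid == d, structure=struct)
                if n <= 1:
                    continue
                sizes = ndimage.sum_labels(np.ones_like(lab), lab,
                                           index=np.arange(1, n + 1))
                keep = int(np.argmax(sizes)) + 1
                st.grid[(lab > 0) & (lab != keep)] = other
                changed = True
            if not changed:
                return

    def recenter(self, cid: int) -> Tuple[float, float]:
        """Translate a lone cell back to the lattice center (uniform substrate
        only).  Returns the applied offset in um; logged positions from later
        sweeps must be shifted back by it.  Translation leaves every energy
        term invariant, so trajectories on an unbounded adhesive plane can be
        simulated in a finite box.
        """
        st = self.state
        if not st.mask.all():
            raise ValueError("recentering requires a uniform adhesive mask")
        n = st.ci[K.NSITES, cid]
        cx = st.cf[K.SUMX, cid] / n
        cy = st.cf[K.SUMY, cid] / n
        dx = int(round(st.width / 2 - cx))
        dy = int(round(st.height / 2 - cy))
        if dx == 0 and dy == 0:
            return 0.0, 0.0
        st.grid[:] = np.roll(st.grid, (dx, dy), axis=(0, 1))
        st.cf[K.SUMX, cid] += n * dx
        st.cf[K.SUMY, cid] += n * dy
        st.cf[K.PCOMX, cid] += dx * st.beta
        st.cf[K.PCOMY, cid] += dy * st.beta
        st.ci[K.MINX, cid] += dx
        st.ci[K.MAXX, cid] += dx
        st.ci[K.MINY, cid] += dy
        st.ci[K.MAXY, cid] += dy
        return dx * st.beta, dy * st.beta

    def free_migration_trajectory(self, n_sweeps: int,
                                  relax_mcs: int = 2000,
                                  recenter_every: int = 500) -> np.ndarray:
        """COM trajectory (um) of a single cell migrating on an unbounded
        adhesive plane, simulated with periodic recentering.

        The cell is seeded at the lattice center, relaxed for ``relax_mcs``
        sweeps, then tracked for ``n_sweeps``; returns (n_sweeps, 2)
        positions in the unbounded frame.
        """
        cid = self.seed_cell()
        self.spread(relax_mcs)
        pos = np.zeros((n_sweeps, 2))
        offset = np.zeros(2)
        done = 0
        while done < n_sweeps:
            chunk = min(recenter_every, n_sweeps - done)
            log = self.run(chunk, track=[cid])
            pos[done:done + chunk] = log[:, 0, :] + offset
            done += chunk
            dx, dy = self.recenter(cid)
            # the grid moved by (+dx, +dy); later logs are shifted forward
            offset[0] -= dx
            offset[1] -= dy
        return pos

    # -- convenience ---------------------------------------------------------
    def spread(self, n_sweeps: int) -> None:
        """Let cells spread without division bookkeeping."""
        self.run(n_sweeps, division=False)

    def com(self, cid: int) -> Tuple[float, float]:
        return self.state.com_um(cid)


def run_simulation(config, seed: int = 0, snapshot_every: int = 0):
    """Orchestrate one configured run: seed, spread, then the main phase.

    Writes a per-interval geometry log (CSV), the resolved configuration, the
    per-sweep COM trajectories of the initially seeded cells and optional PNG
    snapshots into ``config.output_dir``.  Returns the Simulation.
    """
    import pandas as pd
    from pathlib import Path

    mask = config.build_mask()
    barrier = config.build_barrier(mask)
    sim = Simulation(config.params, mask, seed=seed, barrier=barrier)
    if config.n_cells == 1:
        ids = [sim.seed_cell(radius_um=config.seed_radius_um)]
    else:
        ids = sim.seed_cells(config.n_cells, radius_um=config.seed_radius_um)
    out = None
    rows = []
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.dump(out / "resolved_config.json")
        (out / "seed.json").write_text(f'{{"seed": {seed}}}')
    sim.spread(config.spread_mcs)
    remaining = max(config.total_mcs - config.spread_mcs, 0)
    track = ids if len(ids) <= 8 else None
    coms = None
    if remaining:
        if snapshot_every and out is not None:
            done = 0
            while done < remaining:
                chunk = min(snapshot_every, remaining - done)
                sim.run(chunk, division=config.division)
                done += chunk
                sim.state.snapshot_png(out / f"snap_{sim.state.mcs:07d}.png")
                for cid in sim.state.cell_ids():
                    rows.append(sim.state.geometry_row(cid))
        else:
            coms = sim.run(remaining, division=config.division, track=track)
    if out is not None:
        for cid in sim.state.cell_ids():
            rows.append(sim.state.geometry_row(cid))
        pd.DataFrame(rows).to_csv(out / "geometry.csv", index=False)
        if coms is not None:
            for k, cid in enumerate(track):
                pd.DataFrame(coms[:, k, :], columns=["com_x", "com_y"]) \
                    .to_csv(out / f"trajectory_cell{cid}.csv", index=False)
        if sim.division_log:
            pd.DataFrame(sim.division_log).to_csv(out / "divisions.csv",
                                                  index=False)
        sim.state.snapshot_png(out / "final.png")
    return sim
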