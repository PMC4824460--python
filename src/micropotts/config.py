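"""Run configuration: schema, parsing and batch division driver."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .analysis import orientation_histogram, OrientationHistogram
from .params import ParameterSet, PRESETS, get_preset
from .patterns import AdhesiveMask, Barrier, PatternSpec, make_pattern, read_mask

__all__ = ["RunConfig", "parse_config", "batch_divisions"]

_PARAM_FIELDS = {f.name for f in dataclasses.fields(ParameterSet)}
_TOP_KEYS = {"preset", "parameters", "pattern", "mask_path", "schedule",
             "output_dir", "replicates", "seeds", "seed_radius_um",
             "n_cells", "barrier"}


@dataclass
class RunConfig:
    """Fully resolved configuration of one run or batch."""

    params: ParameterSet
    pattern: Optional[PatternSpec] = None
    mask_path: Optional[str] = None
    spread_mcs: int = 2000
    total_mcs: int = 2000
    division: bool = False
    output_dir: Optional[str] = None
    replicates: int = 1
    seeds: Optional[List[int]] = None
    seed_radius_um: Optional[float] = None
    n_cells: int = 1
    barrier_rect: Optional[Tuple[float, float, float, float]] = None  # um
    barrier_release_mcs: int = 0

    def build_mask(self) -> AdhesiveMask:
        if self.pattern is not None:
            return make_pattern(self.pattern)
        if self.mask_path is not None:
            return read_mask(self.mask_path, beta=self.params.beta)
        raise ValueError("config needs either a pattern or a mask_path")

    def build_barrier(self, mask: AdhesiveMask) -> Optional[Barrier]:
        if self.barrier_rect is None or self.barrier_release_mcs <= 0:
            return None
        x0, y0, x1, y1 = self.barrier_rect
        nx, ny = mask.grid.shape
        b = mask.beta
        region = np.ones((nx, ny), dtype=bool)
        ii = (np.arange(nx)[:, None] + 0.5) * b
        jj = (np.arange(ny)[None, :] + 0.5) * b
        region[(ii >= x0) & (ii <= x1) & (jj >= y0) & (jj <= y1)] = False
        return Barrier(region=region, release_mcs=self.barrier_release_mcs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = dataclasses.asdict(self.params)
        if self.pattern is not None:
            d["pattern"] = {"name": self.pattern.name,
                            "dims": dict(self.pattern.dims),
                            "beta": self.pattern.beta,
                            "margin": self.pattern.margin}
        return d

    def dump(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _schema_error(where: str, msg: str):
    raise ValueError(f"config error at {where}: {msg}")


def parse_config(path) -> RunConfig:
    """Parse a YAML/JSON run configuration.

    Presets inject the published parameter columns verbatim; explicit
    ``parameters`` entries override preset fields.  Unknown keys raise with
    the offending path.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        _schema_error("<root>", "top level must be a mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        _schema_error("<root>", f"unknown keys {sorted(unknown)}")
    overrides = dict(data.get("parameters") or {})
    bad = set(overrides) - _PARAM_FIELDS
    if bad:
        _schema_error("parameters", f"unknown fields {sorted(bad)}")
    preset = data.get("preset")
    if preset is not None:
        if preset not in PRESETS:
            _schema_error("preset", f"unknown preset {preset!r}; "
                                    f"choose from {sorted(PRESETS)}")
        params = get_preset(preset, **overrides)
    elif overrides:
        params = ParameterSet(**overrides)
    else:
        _schema_error("<root>", "need 'preset' or 'parameters'")
    pattern = None
    if "pattern" in data and data["pattern"] is not None:
        pd = data["pattern"]
        if "name" not in pd:
            _schema_error("pattern", "missing 'name'")
        pattern = PatternSpec(name=pd["name"], dims=pd.get("dims", {}),
                              beta=float(pd.get("beta", params.beta)),
                              margin=float(pd.get("margin", 16.0)))
        if abs(pattern.beta - params.beta) > 1e-12:
            _schema_error("pattern.beta", "must equal parameters.beta")
    sched = data.get("schedule") or {}
    barrier = data.get("barrier") or {}
    return RunConfig(
        params=params,
        pattern=pattern,
        mask_path=data.get("mask_path"),
        spread_mcs=int(sched.get("spread_mcs", 2000)),
        total_mcs=int(sched.get("total_mcs", sched.get("spread_mcs", 2000))),
        division=bool(sched.get("division", False)),
        output_dir=data.get("output_dir"),
        replicates=int(data.get("replicates", 1)),
        seeds=data.get("seeds"),
        seed_radius_um=data.get("seed_radius_um"),
        n_cells=int(data.get("n_cells", 1)),
        barrier_rect=tuple(barrier["rect"]) if "rect" in barrier else None,
        barrier_release_mcs=int(barrier.get("release_mcs", 0)),
    )


def batch_divisions(params: ParameterSet, pattern: PatternSpec,
                    n_reps: int, seeds: Optional[List[int]] = None,
                    spread_mcs: int = 1500,
                    base_seed: int = 0) -> Tuple[OrientationHistogram, np.ndarray]:
    """Repeated independent spread-and-divide runs on one pattern.

    Each replicate seeds a round cell, lets it spread to equilibrium and
    runs the mitotic contraction protocol once; the recorded major-axis
    orientations are returned together with their folded 6-degree histogram.
    Distinct seeds give independent replicates; fixed seeds make the batch
    bit-reproducible.
    """
    from .dynamics import Simulation

    if seeds is None:
        seeds = [base_seed + 1000 * i for i in range(n_reps)]
    if len(seeds) != n_reps:
        raise ValueError("need one seed per replicate")
    mask = make_pattern(pattern)
    angles = np.empty(n_reps)
    for i, s in enumerate(seeds):
        sim = Simulation(params, mask, seed=int(s))
        cid = sim.seed_cell()
        sim.spread(spread_mcs)
        ang, _ = sim.divide_cell(cid)
        angles[i] = ang
    return orientation_histogram(angles), angles
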