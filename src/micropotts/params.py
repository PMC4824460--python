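"""Model parameters for the micropattern cellular Potts model.

A :class:`ParameterSet` collects every quantity entering the effective energy,
the graded-tension migration machinery and the division protocol:

==================  ======  =========================================
surface tension     sigma   nN/um, cortical contractility per area
simple line tension lambda_s  nN, contractility of the cell contour
arc rigidity        k       nN, elastic stiffening of free-spanning arcs
adhesive density    W       nN/um, W = E0 / A_ref
target cell size    A0      um^2, sets the adhesion saturation scale
cadherin density    c       nN (<= 0), energy per length of new junction
migratory strength  mu      nN/um, tension asymmetry at the leading edge
alignment lag       tau     MCS, velocity-alignment memory time
gradation width     eta     exponent of |cos(alpha)|
protrusion decay    d0      um, reach of protrusions beyond the pattern
division rate       r0      1/MCS, uninhibited division rate
Hill coefficient    m       density inhibition of proliferation
fluctuation allow.  T       Metropolis temperature analogue
lattice scale       beta    um per lattice site
==================  ======  =========================================

Three named presets ship with the package (``generic``, ``MCF10A``,
``HaCaT``).  When ``T`` is not given it defaults to ``0.2 * lambda_s * beta``,
which keeps membrane fluctuations of similar physical size across lattice
scales and tensions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = ["ParameterSet", "PRESETS", "get_preset", "adhesion_reference_area"]


def adhesion_reference_area(W: float, sigma: float, A0: float) -> float:
    """Reference area A_ref of the saturating adhesion term.

    The adhesion energy is ``-E0 * A_ad / (A_ref + A_ad)`` with
    ``E0 = W * A_ref``.  A_ref is fixed by requiring that the marginal
    adhesion gain balances the surface tension exactly at the target size::

        d/dA_ad [E0 * A_ad / (A_ref + A_ad)] |_(A_ad = A0)  =  sigma
        =>  W * A_ref^2 / (A_ref + A0)^2 = sigma
        =>  A_ref = A0 / (sqrt(W / sigma) - 1)

    so cells spread toward ~A0 and the energetic benefit saturates.  Requires
    ``W > sigma``; otherwise no spreading equilibrium exists.
    """
    if W <= sigma:
        raise ValueError(
            f"adhesive energy density W={W} must exceed surface tension "
            f"sigma={sigma}: otherwise spreading has no equilibrium size"
        )
    return A0 / (math.sqrt(W / sigma) - 1.0)


@dataclass(frozen=True)
class ParameterSet:
    """All simulation parameters; see module docstring for units."""

    sigma: float = 1.0
    lambda_s: float = 10.0
    k: float = 50.0
    W: float = 20.0
    A0: float = 1300.0
    c: float = -10.0
    mu: float = 0.0
    tau: Optional[float] = None
    eta: float = 0.25
    d0: float = 43.0
    r0: float = 0.0
    m: float = 4.0
    T: Optional[float] = None
    beta: float = 0.5
    lambda_cc_factor: float = 0.5   # lambda_cc = factor * lambda_s, per cell
    W_contract_fraction: float = 0.0  # residual adhesion during mitosis
    gradation_mode: str = "polar-angle"  # or "contour-normal"
    division_area_ratio: float = 0.36   # ellipse fitted at A / A_b = 0.36
    min_arc_run: int = 4                # contour sites, suppresses pixel noise
    polarity_threshold: float = 1e-5    # um/MCS; numerical guard: alpha is
    # undefined at |p| = 0.  Kept far below any physical polarity magnitude
    # (per-sweep COM displacements are ~1e-3 um/MCS) so it never gates the
    # migration machinery itself.

    def __post_init__(self):
        for name in ("sigma", "lambda_s", "k", "W", "A0", "d0", "beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.c > 0:
            raise ValueError("cadherin energy line density c must be <= 0")
        if self.mu < 0:
            raise ValueError("migratory strength mu must be >= 0")
        if self.tau is not None and self.tau < 1:
            raise ValueError("alignment lag tau must be >= 1 MCS")
        if self.T is None:
            object.__setattr__(self, "T", 0.2 * self.lambda_s * self.beta)
        if self.T <= 0:
            raise ValueError("fluctuation allowance T must be positive")
        if self.gradation_mode not in ("polar-angle", "contour-normal"):
            raise ValueError(f"unknown gradation mode {self.gradation_mode!r}")

    # -- derived quantities -------------------------------------------------
    @property
    def A_ref(self) -> float:
        return adhesion_reference_area(self.W, self.sigma, self.A0)

    @property
    def E0(self) -> float:
        return self.W * self.A_ref

    @property
    def lambda_cc(self) -> float:
        """Line tension of one cell at a cell-cell interface."""
        return self.lambda_cc_factor * self.lambda_s

    def contraction_line_tension(self, A_b: float) -> float:
        """Mitotic line tension ensuring roundup and net contraction.

        ``lambda_bar = 2 * sigma * A_b / pi`` scales with the pre-division
        cell size A_b, which makes the contraction strongly
        perimeter-dominated (the inverted surface tension is a small
        perturbation at every curvature the cell realizes).  The resulting
        dynamics is a noisy curve-shortening flow that shrinks the area while
        eroding the shape anisotropy only slowly, so the ellipse fitted at
        the 0.36 area ratio still carries the orientation of the spread
        shape.  A tension of only the Laplace scale ``2 sigma sqrt(A_b/pi)``
        would instead let the inverted surface tension inflate the flat sides
        while the high-curvature ends retract, erasing the division-axis
        memory before the fit.
        """
        return 2.0 * self.sigma * A_b / math.pi

    def with_updates(self, **kw) -> "ParameterSet":
        return replace(self, **kw)


# Named presets.  The generic preset ships with beta = 0.5 um (T = 1); the
# other printed generic combinations (beta, T) = (0.1, 0.2) and (0.3, 0.6)
# follow from the T = 0.2 * lambda_s * beta rule via ``with_updates``.
PRESETS = {
    "generic": ParameterSet(
        sigma=1.0, lambda_s=10.0, k=50.0, W=20.0, A0=1300.0, c=-10.0,
        mu=2.0, tau=None, eta=0.25, d0=43.0, r0=0.0, m=4.0,
        T=1.0, beta=0.5,
    ),
    "MCF10A": ParameterSet(
        sigma=0.1, lambda_s=2.3, k=40.0, W=20.0, A0=1000.0, c=-6.3,
        mu=0.19, tau=185.0, eta=0.25, d0=43.0, r0=0.0, m=4.0,
        T=0.15, beta=0.25,
    ),
    "HaCaT": ParameterSet(
        sigma=0.03, lambda_s=2.3, k=40.0, W=0.7, A0=1000.0, c=-3.0,
        mu=0.1, tau=40.0, eta=0.25, d0=43.0, r0=0.0008, m=4.0,
        T=0.5, beta=1.0,
    ),
}


def get_preset(name: str, **overrides) -> ParameterSet:
    """Return a named preset, optionally with field overrides.

    If ``beta`` is overridden and ``T`` is not given explicitly, T is rescaled
    with the lattice scale via ``T = 0.2 * lambda_s * beta``.
    """
    try:
        base = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    if "beta" in overrides and "T" not in overrides:
        overrides["T"] = None
    if not overrides:
        return base
    return replace(base, **overrides)
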