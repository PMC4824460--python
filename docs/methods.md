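# Methods

`micropotts` is a two-dimensional cellular Potts model (CPM) of cells on
adhesive micropatterns. Cells are 4-connected domains of equal index on a
square lattice with scale β (µm per site); the medium has index 0. The state
evolves by Metropolis dynamics on an effective energy, one Monte Carlo sweep
(MCS) being the simulator's time unit.

## Energy function

For non-migrating cells,

    H = Σ_cells [ σ A + λ_s l_cm ] + Σ_arcs k/(2 L0) (L − L0)²
        − Σ_cells E0 A_ad / (A_ref + A_ad)
        + Σ_junctions [ (λ_cc,a + λ_cc,b) l_cc + c Z ]

* **Surface tension σ** (nN/µm) prices the projected cell area A; it models
  cortical actomyosin contractility. There is deliberately *no* harmonic
  area-elasticity term: cells exchange material with the third dimension, so
  the projected area is controlled instead by a saturating adhesion term.
* **Simple line tension λ_s** (nN) prices the cell–medium contour length
  l_cm. Together with σ it produces Laplace-law circular contours.
* **Free-spanning arcs** (tension–elasticity model): maximal contour runs
  over non-adhesive substrate facing medium are reinforced by peripheral
  actin bundles. Each arc carries an elastic energy k/(2 L0) (L − L0)² with
  contour length L and rest length L0 equal to the chord (the spanning
  distance between the run's endpoints). The effective arc tension
  λ = λ_s + k (L − L0)/L0 makes arc radii R = λ/σ grow with spanning
  distance. Runs shorter than `min_arc_run` (default 4 contour sites)
  are treated as fluctuation noise, not arcs; a boundary that is free along
  its entire length has no anchoring endpoints and carries no arc energy.
* **Adhesion**: −E0·A_ad/(A_ref + A_ad), with A_ad the cell area over
  adhesive substrate. W = E0/A_ref is the adhesive energy area density
  (nN/µm). A_ref is fixed by requiring that the marginal adhesion gain
  balances σ exactly at the target size A0: A_ref = A0/(√(W/σ) − 1), so
  cells spread toward ~A0 and the benefit saturates (W > σ is required).
* **Cell–cell contacts** use a zipper picture. Junction length l_cc is
  counted in unit lattice edges (one edge = β µm); each cell contributes a
  reduced tension λ_cc = λ_s/2 there, so a junction carries the same total
  tension as a single cell–medium interface. Adherens junctions release the
  cadherin energy line density c (≤ 0) — but only where previously free
  membranes actually zip together: a created (destroyed) contact edge is a
  zipper event unless contact of the same pair remains incident to both of
  its endpoints, in which case it is deformation of an existing junction and
  carries no cadherin energy. The zipped length Z is tracked per cell pair;
  it changes only through terminus events, is capped by l_cc, and is reset
  when a cell enters mitosis (bond disassembly) and for fresh
  daughter–daughter junctions.

Two contour measures coexist, on purpose. The *energy* prices the contour
with plain midpoint marching squares on the binary indicator (16-case table,
saddles resolved toward keeping the cell connected). This charges a
single-site excursion of a flat edge ≈ 0.83 lattice units, i.e. ≈ 3–4 T at
the calibrated fluctuation allowance (below), which keeps membranes locally
smooth and lets the line tension stall free protrusions. *Reported* geometry
(areas, perimeters, contour polygons, arc endpoints) instead uses a refined
sub-pixel variant — marching squares with linear interpolation on the
vertex-averaged indicator — accurate to ~0.1% in area and ~1.5% in perimeter
on a cell-sized disc (radius 56 sites), so measured tensions need no
calibration mapping. A single smoothed measure for both roles was tried and
rejected: it underprices membrane roughness (≈ 0.24 lattice units per bump,
below T), membranes become entropically floppy, and migrating cells with
leading-edge tension µ > σ balloon instead of being stalled by line tension.

## Metropolis dynamics

One sweep performs n flip attempts, n being the number of selectable sites:
the cell contour sites plus the sites surrounding them. Each attempt picks a
selectable site uniformly and proposes the index of one of its *differing*
4-neighbors (every attempt proposes an actual change; with same-index copies
allowed, the effective kinetics per MCS would be ~2–3× slower and the free
single-cell speed of the MCF10A parameter set would fall well below its
published value). A flip that would disconnect its source cell (local
simple-point test, 4-connectivity), annihilate a last site, enter the 2-site
lattice border, or enter an active barrier region is rejected as invalid
before any energy evaluation. Otherwise ΔH (including the migration bias) is
computed incrementally and the flip is accepted if ΔH < 0, else with
probability exp(−ΔH/T).

The fluctuation allowance T defaults to 0.2·λ_s·β, which keeps the physical
size of membrane fluctuations comparable across lattice scales and tensions;
the named presets ship their published T values. For flips between two
cells, the applied T is the mean of the two cells' values (relevant only
while one cell is mitotic and carries a rescaled T̄).

All incremental caches (marching-square area/perimeter, adhesive area,
center of mass, contact ledger, arc energies) are audited against a
from-scratch recomputation; the test suite keeps them equal to ≤ 1e-6. A
subtlety worth recording: a flip changes the arc energy not only of the two
cells party to it but also of *adjacent* cells, because arc eligibility of a
boundary site requires facing medium rather than another cell — all cells
adjacent to the flipped site are therefore re-evaluated.

## Migration

Polarized actomyosin activity is a graded, direction-dependent tension: a
flip that changes a cell's area by ΔA = ±β² carries the bias

    ΔH_m = −ΔA |cos α|^η sign(cos α) µ_eff,    µ_eff = µ e^{−d/d0}

with α the angle between the cell's polarity direction and the flipped site
(measured from the COM in the default polar-angle mode; the contour-normal
mode measures it against the mask-based outward normal instead, which
produces fibroblast-like rather than keratocyte-like shapes at broad
gradation). η < 1 gives a broad lamellipodium, η > 1 a narrow one. d is the
site's Euclidean distance to the nearest adhesive substrate, so protrusions
die off exponentially beyond the pattern edge with decay length d0.
Contact inhibition of locomotion zeroes the bias for protrusive flips
(|α| < π/2) that would displace another cell's site; retraction at the rear
is never inhibited.

The polarity p follows velocity alignment: after every sweep,
p ← p + (v − p)/τ with v the COM displacement over that sweep, making p an
exponential memory of past displacements with lag τ (MCS). Only the
*direction* of p enters ΔH_m; a numerical guard |p| ≥ 1e-5 µm/MCS merely
avoids an undefined angle at p = 0 and is far below any physical polarity
magnitude. The speed–persistence coupling is emergent: persistence time
rises steeply with µ on the rising branch, saturates, and destabilizes at
very high speeds (side-to-side oscillation), as the tests verify by
monotonicity over three µ values on the rising branch.

## Division

Mitosis follows the observed rounding sequence. At onset (area A_b): the
surface tension is inverted (σ̄ = −σ, acting as an osmotic pressure that
resists contraction), adhesion and arc rigidity are switched off
(W → W·`W_contract_fraction`, default 0; k → 0), the cadherin machinery is
disabled and existing zipped lengths are cleared, and the line tension is
raised to λ̄_s = 2σA_b/π with the fluctuation allowance rescaled by
T̄ = T·λ̄_s/λ_s. The contraction tension scales with the *cell size* A_b,
which makes the contraction perimeter-dominated — a noisy curve-shortening
flow under which the shape anisotropy of the spread cell decays only slowly
while the area shrinks. (With a tension of only the Laplace scale
2σ√(A_b/π), the inverted surface tension inflates the flat sides while
high-curvature ends retract: the shape rounds up at nearly constant area and
the division-axis memory is erased before the fit — division axes on a bar
then come out uniform instead of at ±90°.)

When the area first reaches r = 0.36 of A_b, an ellipse is fitted to the
filled site set via second central moments (robust to the strong contour
noise at T̄; a contour-only fit is not). Its major axis is the division
axis; the cell splits through its COM perpendicular to that axis, stray
fragments are reattached so both daughters are 4-connected, and daughters
restart in interphase with p = 0 and unzipped junctions. A degenerate
ellipse (axis ratio < 1.05) draws the axis uniformly and is logged.
Interphase cells divide per sweep with the Hill rate
r(A) = r0 A^m/(A^m + A0^m), which suppresses proliferation in crowded
tissue. Mitoses run inline: all other cells keep evolving during a
contraction.

## Analysis statistics

* **Orientation histograms**: undirected axes folded to (−90°, 90°],
  6° bins. The default grid has edges at −90° + 6k; the division-axis mode
  is reported on the axis-centered grid (centers 0, ±6, …, 90° with the 90°
  bin wrapping across the fold), because the relevant cardinal orientations
  0° and ±90° would otherwise sit exactly on bin edges and a symmetric peak
  at the fold would be split between the two end bins.
* **Histogram distance**: L2 = Σ_i (p_exp,i − p_sim,i)²/p_exp,i² (plain
  sum, no square root; zero-reference bins are excluded).
* **Persistence**: headings from COM displacements over 100-sweep strides
  (suppressing lattice noise); ⟨cos(θ_{t+Δ} − θ_t)⟩ fitted by exp(−Δ/τ_p);
  persistence length = τ_p × mean speed. Never-decorrelating trajectories
  report a cap; immobile cells are flagged rather than fitted.
* **Vorticity**: around a site occupied by a central cell of area A,
  neighbors up to second order are gathered in a disc of radius
  R = 4√(A/π) and ω = (1/A) Σ (v_y r_x − v_x r_y) is accumulated over cell
  centers in the disc. The sign is fixed so counterclockwise rigid rotation
  gives ω > 0 (the summand as typeset in the source literature gives the
  opposite sign for counterclockwise flow; the interpretation, not the
  printed sign, is implemented).
* **Front displacement**: mean over stripes of the foremost cell-occupied
  coordinate along the stripe axis minus the barrier position; velocity by
  smoothed finite differences.

## Parameters

Three presets ship verbatim (generic / MCF10A / HaCaT); see
`micropotts.params`. Quantities with units: σ nN/µm, λ_s and k and c nN,
W nN/µm, A0 µm², µ nN/µm, τ MCS, d0 µm, r0 1/MCS, β µm/site. The generic
preset has no velocity-alignment lag: its polarity stays wherever it is
put (migration is inactive unless a polarity is pinned), matching its use
for spreading and division studies. 20 000 MCS correspond roughly to one
day of real time; this conversion is documentation only and never enters a
computation.

Pattern dimensions that were never published are free defaults chosen to
resemble the published thumbnails (bar 12×44 µm, L arms 34×11 µm, H width
36 µm with 7-µm bars, etc.); they are configuration, not ground truth. The
division-axis mode on the bar is robust for thin bars (the spread cell must
be clearly elongated; a 16-µm-wide bar already blurs the mode).

## Problem sizes used in tests and the acceptance script

Scaled-down study conditions keep full runs tractable while preserving the
qualitative regimes: division batches use 100 replicates per pattern at
β = 0.5 (the mode identity is stable well below the 20 000-replicate scale
used for full histograms); free-migration runs use ≥ 5×10⁴ MCS per seed
with periodic recentering on a uniform 120-µm box (translation-invariant);
the cell-pair contrast runs at β = 0.5 with MCF10A physical parameters
(T rescaled by the 0.2·λ_s·β rule); the comb scenario uses a 35×90-µm
reservoir, two 10-µm stripes and six cells with division disabled, which
isolates the contribution of active migration to front advance.

## Known limitations

* Junction termini move through rare unzip events (cost |c|β against T), so
  cell-pair rearrangements are slow at coarse lattice scales; the pair
  stability contrast is measured as wander variance rather than full
  revolutions.
* The energy contour (midpoint marching squares) overestimates smooth
  perimeters by ~6%; reported geometry uses the refined measure, so the two
  differ systematically for rough contours. All internal audits compare
  like with like.
* Medium holes enclosed by a cell are not forbidden (only cell connectivity
  is enforced); they are short-lived under the line tension.
* The synthetic scenarios emulate geometry and mechanics only: no cell
  volume growth before division, no explicit nucleus/spindle, no substrate
  elasticity, no biochemical polarity fields. Passing tests show the model
  reproduces the published geometric/statistical regimes, not that it
  predicts any particular experimental dataset.
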