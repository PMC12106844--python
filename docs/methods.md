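# Methods

## Model overview

`colonysim` couples three components on a shared clock:

1. **Agent-based rod mechanics.** Cells are 2D spherocylinders confined to
   the x–z plane. Each cell elongates as `dl/dt = λ l` with its local
   biomass growth rate λ and divides at its midpoint when the cylinder
   length exceeds a per-cell threshold `l_div(1 + u)`, u uniform in
   ±`div_noise`. Daughters receive cylinder length l/2 each (rod material
   is conserved exactly, so a population at constant λ multiplies at
   exactly e^{λt}); the two new hemispherical caps introduce a small
   (0.2·r0) overlap at the split point that the contact mechanics relaxes,
   and each daughter's angle is kicked by up to ±`angle_kick` to break
   collinear symmetry. Forces are (i) Hertz-like repulsion
   F = k·√(r_eff)·δ^{3/2} at the closest points of overlapping rod axes,
   (ii) the same law for caps penetrating the agar plane z = 0, (iii) a
   linear spring pulling caps that protrude above the smoothed colony
   outline back toward it (a coarse surface tension), and (iv) a settling
   force per unit length toward the agar. Motion is overdamped:
   v = F/(ζL), ω = τ/(ζL³/12), L the cap-to-cap length. The explicit
   update is stable below dt* = ζ·(l_div/2)/k_lin with k_lin the Hertz law
   linearized at a 0.3·r0 reference overlap; the driver uses
   stability-sized substeps spanning each macro step.

2. **Metabolic model.** Three growth modes (aerobic on glucose, anaerobic
   on glucose, aerobic on acetate) combine as
   λ = λ₁θ_o + λ₂(1−θ_o) + λ₃(1−θ_g)θ_o with Monod fractions
   θ_x = C_x/(C_x+K_x). Maintenance requires a carbon flux `m_carbon`
   (mmol C/gdw/h, 6 C per glucose, 2 C per acetate). Each mode's Monod
   curve is shifted by the threshold C\* = K·m/(q_max − m) at which maximal
   Monod-limited uptake exactly covers maintenance; the shifted form
   λ_max(C−C\*)/((C−C\*)+K) is continuous at C\*, reduces to plain Monod at
   C\* = 0 and has the correct saturation; continuity alone does not fix
   the shifted form uniquely, so this explicit expression is the package's
   one free functional choice. Carbon uptake pays
   maintenance before growth, glucose before acetate (and acetate only
   under the same (1−θ_g)θ_o gate as acetate growth); a cell whose total
   achievable carbon uptake is below m is starving. Anaerobically consumed
   maintenance glucose excretes `acetate_per_glucose_maint` (= 2) acetate.
   PDE source rates follow the mode fluxes:
   Q_g = q_g,aer λ₁θ_o + q_g,ana λ₂(1−θ_o) + Q_g,maint, and the analogous
   expressions for Q_o, P_a, Q_a; P_g = P_o = 0.

3. **Reaction–diffusion fields.** Uniform cell-centered grid over agar
   (z < 0), colony and air. Cells are rasterized by sampling points along
   each rod; the colony mask is the morphological closing (plus hole
   filling) of occupied grid cells, and the biomass density is
   ρ = rho_cell × area fraction (capped at close packing). Faces between
   active cells carry harmonic-mean diffusivities (flux continuity across
   the agar–colony interface); glucose and acetate see no-flux outer
   boundaries, oxygen a Dirichlet ambient value on air-facing faces
   imposed with a one-sided three-point flux (exact for parabolic
   profiles).

## Numerical scheme

Each macro step (default 2 min full scale, 3 min in the scaled studies):
masks → fields → per-cell rates → nested growth/mechanics loop.

The metabolite update divides the macro step into ~30 s semi-implicit
sub-steps. Within a sub-step the rates are evaluated at the current
concentrations, uptake is applied implicitly through the linearization
Q(C_k)/C_k (keeping the system an M-matrix, so concentrations can never go
negative, and making the "clipping" mass-conservative by construction),
glucose and acetate advance by a direction-split (ADI, batched Thomas)
backward-Euler step whose one-dimensional flux-form solves conserve mass
exactly in closed domains, and oxygen is solved directly to quasi-steady
state on a crop around the colony (agar consumes no oxygen and the air
Dirichlet pins the far field to ambient, so the crop boundary error is
negligible; oxygen equilibrates in seconds, far below the macro step).
Glucose and acetate, whose agar reservoir drains over hours under closed
boundaries, are deliberately *not* solved to steady state — the only
steady state of a closed reservoir with a sink is full depletion. A
whole-step fixed-point (Picard) iteration was tried first and abandoned:
near the Monod constants the growth-mode weights switch fast enough that
the iteration chatters or creeps with contraction ≈ 1; the lagged
sub-step scheme is first-order in time and unconditionally robust.
`pde_tol` allows sub-steps to exit early only when no uptake is draining
the fields (a quasi-steady profile can still carry a steady flux).

Cell-local concentrations are sampled from the fields by bilinear
interpolation at the cell centre. The mechanics loop reuses its KD-tree
candidate-pair list across substeps (rebuilt on division or every 15
substeps, with a 2 µm search skin).

## Parameters

Measured values printed in the primary literature: δ_aer = 0.2/day,
δ_ana = 2/day, growing threshold 0.01/h, K_a ≈ 5 mM, 2:1 acetate:glucose
fermentation stoichiometry, initial acetate 0. All other defaults are
literature-standard E. coli physiology, tagged "literature-default" in the
parameter registry and freely overridable: λ_g,aer = 1.0/h,
λ_g,ana = 0.55/h, λ_a,aer = 0.4/h; K_g = 0.1 mM, K_o = 0.02 mM; yields
give q_g,aer = 11 and q_g,ana = 37 mmol glucose/gdw (0.5 and 0.15 g/g),
q_a,aer = 55 mmol acetate/gdw; oxygen demands q_o,g = 30, q_o,a = 80
mmol/gdw; overflow acetate p_a,aer = 4 ≈ 10% of the fermentative
p_a,ana = 40 mmol/gdw; maintenance m_carbon = 1.5 mmol C/gdw/h
(≈ 0.25 mmol glucose/gdw/h); rho_cell = 300 gdw/L at close packing
(0.3 pg dry weight per µm³ cell volume); ambient oxygen 0.25 mM
(air-saturated water). In-colony effective diffusivities are reduced
relative to agar (glucose 40, oxygen 300, acetate 100 µm²/s vs 600, 2000,
900 in agar) reflecting the densely packed cytoplasmic volume; these
low relative diffusivities are what confine growth to a thin basal
glucose layer and an aerated surface layer at desk-scale colony heights.
Mechanical constants (contact stiffnesses, drag, settling, surface
tension) are model constants chosen so that a crowded monolayer buckles
into verticalized interior cells while the periphery stays flat; they are
tagged "numerical" in the registry.

The anoxia cutoff attributing starvation to the anaerobic death clock is
C_o < K_o. Starvation clocks are cumulative (no reset on re-feeding) by
default, with a reset-on-feed mode available; death is tracked as a
probability per cell (the 4 µm × 4 µm grid estimator multiplies cell count
by mean death probability per box), with a seeded Bernoulli sampling mode
for visualization.

## Scaled study conditions

The reference experiments use mm-scale colonies over ~50 h (10⁶–10⁹
agents), far beyond a desk-scale agent-based run. The package's study
conditions, used by the test suite and `scripts/acceptance.py`, are a
4.8 mm × 1.6 mm agar cross-section (h = 8 µm grid, ~75 µm² per node),
macro step 3 min, 15 h horizon, started from a single cell, at 10 and
20 mM initial glucose. The domain was sized so that the agar glucose
reservoir remains large relative to colony demand over the horizon, as on
a real plate; by 15 h the 10 mM run has drawn the mean agar glucose down
to ~1.5 mM, which still saturates growth at the periphery (K_g = 0.1 mM)
while the colony interior is glucose- and oxygen-starved. Under these
conditions the simulations reproduce, in order: exponential establishment,
buckling/verticalization with a constant-width peripheral monolayer and
linear radial expansion; oxygen depletion of the interior (minimum colony
C_o ≪ K_o while monolayer C_o ≈ ambient) with the anaerobic share of
glucose uptake rising above half; vertical slowdown as basal glucose
penetration thins; acetate uptake shifting from growth to maintenance at
the oxygenated top; and from ~11 h an interior death zone whose
expected-dead profile peaks strictly between the agar surface and the
colony top.

## What the synthetic data do and do not show

The fixture generator produces cell arrangements, cross-section profiles
and viability decay series with closed-form ground truth (disk-sum
volumes, configured monolayer skirts, exact exponential decays with
lognormal noise); these validate the observables and fitting code, not
the biology. The scaled simulations share the (1+1)-dimensional
simplification of the model itself: horizontal cells must point radially,
which overestimates the monolayer width; there is no third dimension for
nutrient spreading; heights and radii are tens-of-µm scale, so quantities
quantized by cell size (monolayer width, height steps) carry relative
fluctuations that mm-scale colonies would average away. Colony-scale
trends (linearity, slowdown, zonation, death-zone interiority) are the
meaningful outputs; absolute speeds and widths are semi-quantitative.

## Numerical choices and degenerate inputs

* Profile/height bookkeeping uses 2 µm z-bins in the driver (the ~5 µm
  disks of the experimental protocol would quantize tens-of-µm colonies
  too coarsely); the stack-of-disks volume is Σπr²dz.
* The monolayer is the outermost contiguous run of 2 µm x-columns whose
  material top is below 1.5 cell diameters; an all-monolayer colony
  returns half the footprint per side. The intensity-trace mode uses a
  1.5× plateau threshold.
* The vertical-slowdown flag compares fitted vertical speeds over the two
  halves of the analysis window (per-interval height increments are too
  noisy at desk scale); slowdown means the late speed is at least 5%
  below the early one.
* Orientation ties (|angle| exactly at the cutoff) classify as
  horizontal; angles live in [−π/2, π/2] (nematic wrap).
* A colony reaching the lateral wall or the domain top stops the run with
  an explicit reason — the finite domain is an artifact, not physics.
* Empty populations, empty profiles, non-positive durations, unstable
  mechanics steps and invalid configurations raise informative errors
  rather than propagating NaNs.

## Known limitations

No EPS, motility, adhesion maturation or agar deformation; no nitrate
respiration, pH/buffer chemistry, alanine cross-feeding or lysis-product
recycling; dead cells remain as inert mechanical objects. The mechanical
force constants are not fit to data, so monolayer width (and hence
absolute radial speed) is semi-quantitative. The oxygen quasi-steady
treatment ignores the small dissolved-oxygen store of the agar. The ADI
splitting is first-order in time across the reaction–diffusion coupling;
transients shorter than the ~30 s sub-step are not resolved.
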