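# Methods

`socolony` simulates the expansion of a two-species bacterial colony on a
surface, coupling an individual-based mechanical model of rod-shaped cells to
reaction-diffusion fields for a shared nutrient and for secreted chemicals
(toxins and public goods) that implement the six pairwise social
interactions.  A companion well-mixed batch ODE model reproduces the
qualitative phase behavior without spatial structure.  This note records the
model, the parameter choices, the numerical scheme, and the limits of what
the synthetic experiments demonstrate.

## Units

Lengths are micrometers; the time unit tau is 30 minutes (roughly one
*E. coli* division time under good conditions); nutrient concentration is
scaled to the boundary (reservoir) value, and each secreted chemical is
scaled so its production term is exactly the producer cell density.

## Cell mechanics

A cell is a spherocylinder: a rigid rod of length L (cap-center to
cap-center) with hemispherical caps of diameter d = 1 um, moving in 2-D.
For each cell pair, the closest points between the axis segments are found
with the standard clamped quadratic minimization (capsule-capsule test); for
exactly parallel overlapping axes the midpoint of the overlapping parameter
interval is the deterministic tie-break.  Spheres of the cell diameter
placed at the closest points overlap by h = d - |q_ci - q_cj|; contacts with
h > 0 repel with the Hertzian law F = E sqrt(d) h^(3/2).

Inertia is negligible at this scale, so the equations of motion are
overdamped with a single lumped dimensionless mobility M = E t_c / (beta rho)
(elasticity x time scale / drag x line mass density):

    dq_i/dtau   = M * sum_contacts h^(3/2) / L_i * q_hat_ij
    dphi_i/dtau = M * sum_contacts 12 h^(3/2) / L_i^3 * [(q_ci - q_i) x q_hat_ij]

with q_hat_ij the contact normal toward cell i and (q_ci - q_i) the lever
arm.  The torque is the physical lever x force order — the convention that
rotates rods away from contacts.  The rod length is floored at 0.5 um in the
mobility denominators so newborn, nearly spherical cells do not acquire
divergent velocities.  Rods are unoriented: phi and phi + pi are equivalent,
and tests compare axes rather than angles.

Integration is explicit forward Euler with a fixed timestep (default 1e-4
tau at the default mobility 2e5).  A displacement cap of 0.1 d per force
evaluation — counting cap-end motion from rotation — guards the explicit
scheme.  Two enforcement modes exist: the default per-cell limiter scales an
offending cell's translation and rotation down to the cap, touching only the
extreme tail of the contact-jostle distribution; `cap_mode="substep"`
subdivides the global step with forces recomputed each sub-step.  On a
2,500-cell competition colony the two modes agree on every structure metric
(green fraction 0.475 vs 0.473, roughness 0.54 vs 0.55, identical radii)
while the limiter does one force evaluation per step.

The mobility value is a calibration, not a measured quantity: any value
giving pair relaxation much faster than a division time and steady overlaps
far below a diameter produces the same quasi-static packing.  The default
2e5 relaxes an overlapping pair in ~1e-4 of a division time; the
reduced-scale protocol (below) uses 2e3, which still relaxes pairs in ~2 %
of a division time with steady overlaps of 1-3 % of a diameter, and was
verified to leave the structure metrics unchanged against 2e4.

## Growth and division

Cell length grows at

    dl_i/dt = g * A_i * n/(kappa + n) * (1 - xi * T),   clamped at >= 0,

with A_i the footprint area (rod x d + pi d^2/4), n the local nutrient,
kappa = 0.3 the Monod half-saturation, T the locally sensed concentration of
the *other* species' secreted chemical and xi the signed interaction
strength (positive toxin, negative public good).  The per-area rate constant
g = 0.5 um^-1 tau^-1 makes an unimpeded cell divide in roughly 1.5 tau.  The
clamp means strong toxins stop growth rather than shrink cells.

Each cell carries a personal division threshold drawn at birth from a
normal distribution (mean 4.0 um, s.d. 0.3 um) clipped to [3.1, 4.9] um,
applied by default to the total cap-to-cap length (a 4-um threshold for a
1-um-wide cell; `threshold_on="rod"` is the alternative).  At division the
parent splits into two daughters whose spherocylinders exactly tile the
parent's footprint (daughter rod (L - d)/2, centers offset half a daughter
length along the axis), inheriting species and lineage and drawing fresh
ids and thresholds.  A uniform +/-0.05 rad angular nudge per daughter breaks
perfect collinearity — without it colonies grow as unrealistic single-file
chains; the magnitude is config-exposed, including 0.

## Chemical fields

All fields live on one square lattice (5 um spacing by default, shared with
the metrics grid).  The cell density each field consumes is the summed cell
footprint area per lattice cell over the lattice cell area (about 0-1.6,
dimensionless), apportioned through 9 sample points along each cell's axis.

    nutrient:  dn/dt = D_n lap(n) - alpha_n * rho * n/(kappa + n),
               boundary ring held at 1 (external reservoir)
    secreted:  dc/dt = D_c lap(c) + rho_producer - beta_c * c,
               absorbing ring (c = 0), standing in for loss from an open
               system; negligible for a domain much larger than the colony

Nutrient therefore obeys 0 <= n <= 1 (maximum principle); a secreted
chemical is bounded by max(rho)/beta_c.  Defaults: D_n = 3e4 um^2/tau,
alpha_n = 10/tau, kappa = 0.3; D_c = 100 um^2/tau, beta_c = 1/tau.  The
produced-chemical pair sets the interaction length sqrt(D_c/beta_c) = 10 um
— a few cell lengths — and a concentration scale rho/beta_c of order 1 in
packed regions, which is what makes the default interaction magnitude
|xi| = 2 meaningful: xi*c crosses 1 (growth shut down) where the producing
species is locally dense, but not at the dilute leading edge.  With these
scales the six wirings produce qualitatively distinct colonies: the victim
species is marginalized under amensalism, sector boundaries pin and roughen
under competition, and well-mixed mutualistic regions grow up to ~3x faster.

Stepping is explicit FTCS with the stability bound
dt <= h^2 / (4D + h^2 * rate); chemistry is sub-stepped automatically inside
each mechanics step (fused in a compiled kernel).  A quasi-steady option
iterates the fields to stationarity each mechanics step instead; the default
is dynamic stepping.  Concentrations are clipped at zero only to absorb
rounding.  Verification: a uniform-consumption slab matches an independent
boundary-value integration of D n'' = alpha rho n/(kappa+n) to < 1 %, a
point source matches the screened-Poisson K0(r/lambda) profile to < 5 %, and
doubling the resolution moves the slab steady state by < 2 %.

## Interaction wiring

A species only senses the chemical produced by the other species.  With s
the magnitude: control — no chemicals; commensalism — red produces,
xi_green = -s; amensalism — red produces, xi_green = +s; competition — both
produce, both xi = +s; mutualism — both produce, both xi = -s; parasitism —
red's product benefits green (xi_green = -s) while green's product harms red
(xi_red = +s), matching the two-arrow depiction of the interaction and the
observed dominance of the benefiting species (a one-chemical parasitism
variant keeps only the toxin).  The red-producer convention for the
asymmetric types makes green the beneficiary of commensalism/parasitism and
the victim of amensalism.

## Simulation protocol

Seeding places cells on a regular sub-grid of a 60x60 um^2 square: 16x16,
8x8, 4x4 for the high/medium/low densities of 256/64/16 cells.  Well-mixed
seeding assigns species in an alternating (checkerboard-like) pattern that
hits the requested abundance ratio exactly (ratios 1:7 to 7:1; non-integral
splits round in green's favor); random seeding jitters positions and
randomly permutes the same exact label multiset.  Orientations are uniform
and initial rod lengths uniform in [1, 2] um.

Each mechanics step executes a fixed event order: rasterize densities ->
sub-step chemistry -> elongate -> divide -> resolve contacts and move.  One
master seed spawns independent named substreams (seeding, division lengths,
division-angle noise) so adding draws to one stream never perturbs another;
identical config + seed reproduces snapshot tables bit for bit, and swapping
species labels together with the interaction wiring mirrors the trajectory
exactly.  Runs exit when the population reaches `max_cells` (30,000 in the
full-scale protocol).

### Reduced-scale survey protocol

The full six-interaction survey at 30,000 cells takes hours per run on one
CPU.  `reduced_scale_config` defines the package's desk-scale protocol:
5,000-cell colonies in a 300-um domain, timestep 1e-3 tau, mobility 2e3
(see above), density re-rasterization every 4 steps, and nutrient
consumption alpha_n = 60/tau.  The consumption rate follows from a scaling
argument rather than a new calibration: the structure of a depleted colony
is governed by the depletion number alpha rho R^2 / D_n (~27 at full scale)
and the active-layer-to-radius ratio sqrt(D_n kappa / alpha rho) / R (~0.1),
and alpha_n = 60 preserves both at the smaller final radius (~96 um).  The
secreted-chemical length (10 um) is anchored to the cell scale and stays
unchanged.  Under this protocol one colony takes ~25-45 s; the 6 x 3
ensemble used by the acceptance suite runs in roughly 10 minutes.

## Structure metrics

* **Abundance** — fraction of green cells.
* **Occupancy and edge** — a 5-um lattice cell is occupied if any cell axis
  sample falls in it; edge cells are occupied cells with an empty
  4-neighbor.
* **Roughness and radius** — distances of edge-cell centers from the
  area-weighted colony center; the mean is the radius, the standard
  deviation in 5-um lattice units is the roughness.  An independent radius
  comes from the moment of inertia, R = sqrt(2 I / A), exact for a uniform
  disc.
* **Active cells** — the growing front: cells whose realized per-area
  elongation rate is within e^-2 of the current population maximum.  The
  realized rate includes toxin/public-good modulation, so a toxin-stalled
  cell is not "active" even where nutrient is plentiful; this is what lets
  deleterious interactions extinguish victim lineages.  The chemical-free
  alternative (thresholding the nutrient Monod factor instead) is available
  as `criterion="nutrient"`.  The threshold boundary is closed, and a fully
  quiescent population counts as all-active.
* **Surviving lineages** — distinct seed ancestors among active cells
  (lineages are species-pure because species is heritable).
* **Sectors** — active cells are rendered at 0.5 um/px with nearest-cell
  species ownership, smoothed by one 3x3 majority pass (background competes
  and wins ties), connected-components labeled per species with
  8-connectivity, and component pixel masses converted to cell counts via
  the snapshot's mean pixels per cell; clusters of more than 100 cells
  count.  The conversion makes the threshold resolution-independent; edge
  metrics use 4-connectivity (the literal nearest neighbors) while sector
  labeling uses 8-connectivity so diagonal contact keeps a sector whole.
  Sector analysis is run on final states, mirroring the full-scale protocol.

## Well-mixed batch model

    du/dt = alpha n/(kappa+n) (1 - xi1 v) u
    dv/dt = alpha n/(kappa+n) (1 - xi2 u) v
    dn/dt = -Y alpha n/(kappa+n) (u + v)

The (1 - xi rho) factors are the steady-state stand-ins for secreted
chemicals.  By default they may go negative — net death under a strong toxin
— which is what produces competitive exclusion in a batch culture; the
clamped (growth-only) variant of the spatial model is available.  The
nutrient equation mirrors the spatial consumption law with a configurable
yield Y (default 1), giving two exact neutral-case invariants: u/v constant
and n + u + v constant.

The initial nutrient matters because a batch holds a finite growth budget:
with yield 1 the achievable change in log-ratio is bounded by |xi| n0, and
driving a losing species below the survival threshold (1e-6 of the initial
biomass) under parasitism or competition takes roughly |xi| n0 e-folds of
net death.  The default n0 = 50 (in initial-biomass-scaled units) provides
that budget with margin, so the model exhibits the full qualitative
repertoire: symmetric mutualism converges to exactly 1:1 from any start,
symmetric competition excludes one species with the winner set by the
initial majority, and parasitism leaves only the beneficiary.  Amensalism
in a batch is genuinely initial-condition dependent: the victim survives
when nutrient runs out before the producer becomes dense enough.

Integration uses adaptive LSODA with a terminal event at nutrient
exhaustion (n < 1e-6); densities are floored at zero inside the right-hand
side.  Outcome classification integrates a set of initial conditions on
both sides of the u = v diagonal (ratios 1:7, 1:3, 3:1, 7:1 at total
biomass 0.01) and inspects survivors: one survivor in every run is
dominance, a run-dependent winner is bistable exclusion, and joint survival
is coexistence when the final fraction is initial-condition-insensitive
(spread < 0.02) and the neutral line otherwise.  Classification is stable
over two decades of integrator tolerance.

## What the synthetic experiments do and do not show

The generators and fixtures emulate the study conditions: exact-count
seeding in a 60x60 um^2 square, three seeding densities, five abundance
ratios, and deterministic disc/half-disc/stripe/annulus colonies for metric
unit tests.  Passing tests demonstrate that the implementation reproduces
the model's internal structure — contact mechanics against independent
minimizers, field solvers against analytic and boundary-value oracles,
metric recoveries on known geometries, and the qualitative
interaction-structure hierarchy at reduced scale (ordering of surviving
lineages, roughness elevation of deleterious interactions, variance ordering
of symmetric interactions, abundance bias of asymmetric ones).

They do not show quantitative agreement with laboratory colonies:
mechanical, kinetic and interaction parameters are calibrated stand-ins
(documented above) rather than measured values, and the reduced-scale
ensemble reproduces orderings between interaction types, not absolute
numbers.  Real
colonies additionally involve three-dimensional buckling, adhesion and
friction, nutrient yield stoichiometry, density-regulated production
(quorum sensing), and contact-dependent inhibition — all outside this
model.  Ensemble statistics at three replicates resolve the large ordering
gaps but not fine distinctions; the full-scale 30,000-cell protocol with
more replicates sharpens them at proportionate cost.

## Numerical and degenerate-input choices

* Zero-length rods are valid (point cells); contacts at exactly coincident
  closest points push perpendicular to the first cell's axis.
* The candidate-pair search uses a cell-linked grid with per-pair reach
  pruning; it is exact (a superset of all contacts) for any cutoff at least
  the maximum rod length plus a diameter.
* Snapshot CSVs round-trip floats exactly (shortest-round-trip repr);
  malformed files report the offending line number.
* The sector threshold comparison carries a 1e-9 relative slack so a
  cluster of exactly 100 equal-size cells is excluded without being subject
  to float rounding.
* Division on the same step as threshold crossing uses the post-growth
  length; daughters inherit the parent's last growth rate until their first
  growth update.
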