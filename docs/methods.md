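# Methods

`primosim` implements two complementary mechanics models of the migrating
zebrafish posterior lateral line primordium (PLLp) — the ~140-cell tissue
that crawls along the trunk depositing nascent sensory organs
(protoneuromasts, visible as epithelial rosettes with apical
constrictions) — together with the cluster/rosette detection used to
quantify them. Both models encode the same physical hypothesis: adhesion
plus apical constriction act as a local, self-amplifying aggregation force,
while the tension generated by differential leading/trailing migration acts
as a long-range inhibitor of aggregation. The balance of the two sets the
number and size of rosettes; compressing the tissue (slow leaders) fuses
rosettes, stretching it (slow trailers) splits them.

## Agent-based model (`primosim.abm`)

**State.** The primordium is a column of point agents on a continuous 2D
plane, 5 wide and 30 long (150 agents) at unit spacing, with x the
migration axis. Agents in the leading 60 % of the column are WNTERs (Wnt
domain), the trailing 40 % FGFERs. Breakable spring links connect agents
within a link radius.

**Dynamics.** Each step applies, in order:

1. *Migration*: WNTERs advance along +x by `speed_wnt` (default 0.018 per
   step), FGFERs by `speed_fgf` (0.016); Depositers do not move.
2. *Link breakage*: each link is removed with its turnover probability, and
   deterministically when longer than its break threshold.
3. *Link re-formation*: unlinked pairs within the link radius are linked. A
   pair is linkable if within the larger of the two breeds' radii; a link's
   effective parameters combine the breeds symmetrically (mean stiffness,
   rest length, repulsion; min break threshold; max turnover), so a link
   touching a Depositer inherits the Depositer's low break threshold.
4. *Spring relaxation* (one sweep): a linked pair at length *l* pulls each
   endpoint a distance `s·(l − L)` toward the other (pushing when
   compressed); every pair within the link radius repels with displacement
   `r / l²` per agent. The force-directed update follows the spring-embedder
   family of layouts (linear spring attraction, inverse-square repulsion);
   the exact functional forms are this package's choice. Per-agent
   displacement per sweep is capped at 0.5 grid units for stability, and
   repulsion between (near-)coincident agents is evaluated at a floor
   distance of 1e-3 grid units.
5. *Proliferation*: WNTERs/FGFERs divide with a per-step probability
   (default 0 — the cluster-regime experiments are run without division);
   daughters inherit the breed, appear within 0.2 grid units, and start
   unlinked. Depositers never divide.
6. *Wnt shrinkage and deposition* (optional): the Wnt-domain length
   decreases by `wnt_shrink_rate` (default 0.002/step, floored at 0); the
   permitted primordium length is 1.6× the current Wnt-domain length,
   measured back from the leading edge. FGFERs strictly beyond it are
   re-specified as Depositers (zero speed, no proliferation, low break
   thresholds), so the advancing column detaches from them. Boundary
   conventions are strict (">"), matching the wording the rules come from.
7. *Density classification*: each agent's neighbors within
   `density_radius` (1.0) are counted; counts strictly above
   `density_threshold` (5) flag the agent as high-density (the "cyan" view).

**Calibrated defaults.** The column geometry (5×30, 60 % Wnt), speeds
(0.018/0.016) and spring constant (0.18) are published values. The
remaining parameters are not published; they ship as calibrated defaults
chosen once so that the three migration regimes reproduce the reported
cluster counts (no migration: clusters that coarsen over time; fast
leaders: three stable clusters at t = 1000; slow leaders: two clusters by
t = 2000): link radius 3.2, rest length 0.5, repulsion 0.05, break
threshold 3.6 (0.8 for Depositers), turnover 0.005. One step is one
iteration; all lengths are in initial-grid units.

**Randomness.** A single seeded `numpy` generator drives turnover,
proliferation and daughter placement, consumed in a fixed order per step;
a run is a pure function of (config, seed).

## Cellular Potts model (`primosim.cpm`)

**Energy.** A Glazier–Graner–Hogeweg model on a 2D lattice (periodic in x,
closed in y). Each cell is the set of pixels carrying its id; the energy is

    J = Σ λ (v − V)² + Σ β (a − A)² + Σ_contacts H(τ_i, τ_j)
        + Σ_links λ_ij (l_ij − L_ij)²

with per-type volume and surface targets, contact energies summed over
unlike-owner pixel pairs up to neighbor order 3 (12 offsets: 4 axial, 4
diagonal, 4 distance-2 axial), and spring (focal-point-plasticity) links
between cell centers. Surface *a* is counted as order-1 unlike-owner
boundary pixel pairs. A pixel-copy attempt copies a random pixel's owner
onto a random order-1 neighbor and is accepted with probability 1 when the
energy change is at or below the threshold *h* (default 0), and
`exp(−(ΔJ − h)/T)` otherwise (T = 20). One Monte Carlo step (MCS) is
width×height attempts. Copies between frozen types, and copies that would
empty a cell (volume 1 → 0), are rejected — cells in this model persist,
and a vanished cell would leave its link lengths undefined.

**Centers of mass and migration.** The x-center of a cell on the periodic
axis is the circular mean of its pixel x-coordinates
(`atan2` of summed sines/cosines); link lengths use minimal-image
unwrapping. Migratory force enters as a work term
`λ_vec,x · Δcom_x` added to ΔJ for each cell whose center moves in the
attempt (negative coefficients drive +x). This term biases acceptance but
is *not* part of J: on a periodic axis it has no single-valued potential,
so the reported Hamiltonian contains only the four terms above, and the
incremental ΔJ of a copy equals the full Hamiltonian difference exactly
(the central oracle test). Because the per-copy bias scales as
`λ_vec,x / volume`, coefficients are of order 10²–10³.

**Links.** Spring links contribute while active. External links rupture
when stretched strictly beyond their maximum length; internal links
(between compartments of one composite cell, standing in for cytoskeleton)
never rupture. Reformable link classes (apical–apical) re-form whenever two
eligible unlinked cells regain shared boundary, tracked from the order-1
contact ledger at the end of each MCS.

**Scene.** The side-view scene (`SceneSpec`) stacks, bottom to top: a
muscle band five cell-rows thick (keeping the rigid lower boundary away
from the tissue), a thin ECM layer, the primordium resting on the ECM, and
a skin band; Medium fills the rest. The primordium comprises leading
unpolarized Wnt cells, trailing apicobasally polarized FGF cells — each a
composite of apical/lateral/basal compartments sharing a composite id, with
the apical side facing the skin — and superficial sheath cells between the
core and the skin. Apical constriction is realized by (a) an apical target
volume 0.55× its build size and (b) short, strong, breakable-and-reformable
apical–apical links (target 0.3× and maximum 1.4× the build spacing).
Migratory force is applied only to Wnt cells, sheath cells and the basal
compartments of FGF cells. A bridge link joins the last Wnt cell to the
leading lateral compartment, keeping the two domains a single migrating
unit, and ring links stabilize the skin and ECM bands across the periodic
boundary.

**Adhesion hierarchy.** Contact energies (lower = more adhesive) satisfy,
and `validate_adhesion_hierarchy` checks: each primordium type adheres most
to itself; primordium-internal pairs adhere more strongly than any
primordium–skin/ECM pair; and the two substrate anchors (sheath–skin,
basal–ECM) are stickier than other primordium–substrate contacts but no
stickier than primordium-internal cohesion — attached yet able to detach as
the tissue advances.

**Scales and calibration.** None of the numeric type/contact/link values
are published; every number ships in `SceneSpec` as a calibrated default.
The calibrated, tested configuration is the reduced scale
`SceneSpec.desk()`: a 400×150 lattice with 6 Wnt, 16 FGF and 4 sheath cells
(16 FGF cells so that four rosettes of ≥3 apical members are arithmetically
possible). With it, wild-type runs settle at four rosettes (modal over
seeds). `SceneSpec()` is the full-scale 800×300 geometry (10 Wnt, 20 FGF,
6 sheath, cells 2× in each dimension, migration coefficients 4× because the
per-copy bias scales as force/volume); it builds and runs but is not
separately calibrated. Routine runs use the desk scale.

**Scenarios.** `wildtype` applies no events. `stall_leading` zeroes the
migration coefficients of the motile machinery (Wnt, sheath and basal
compartments) at MCS 1200; `stall_leading_wnt_only` zeroes only the
leading Wnt cells, for sensitivity analysis. `stall_then_recover` restores
the original coefficients at MCS 2400. `boost_lat_contractility` raises
lateral-compartment contractility at MCS 300: lateral–lateral link
strength 8×, link rest length 0.25× (a stronger spring at unchanged rest
length exerts no extra pull — contractility requires shortening it), and
lateral–lateral contact energy 0.2×. This reduces the terminal rosette
count relative to wild type without impairing migration, though the
effect at the desk scale is modest (ensemble means ≈3.1 vs ≈3.4).

A mechanistic caveat: in this implementation the rosette count is set
during a plastic window (~MCS 600–1500) in which migration tension
fragments the apical chain; once the pattern locks, clusters rarely fuse
or split under later force changes — the compartment stacks are too rigid
for already-separated apical foci to re-contact. The stall scenario
therefore acts mainly by removing tension *during* the plastic window
(the default stall time, MCS 1200, is calibrated to this), which arrests
fragmentation and leaves fewer, larger rosettes — the same
tension-vs-aggregation balance, expressed through arrested separation
more than through fusion of a locked pattern. Stalling only the Wnt cells
does not reduce the count here: the still-driven trailing cells keep the
apical chain under tension and fragmentation completes regardless, which
is why the default stalls all three motile coefficients.

## Rosette metrics (`primosim.metrics`)

The models' readout is a cluster count, computed the same way everywhere:
connected components over an explicit adjacency, with a minimum size of 3.
For the agent model: components of density-flagged agents adjacent when
within `density_radius`. For the lattice model: components of apical
compartments adjacent when sharing order-1 boundary or joined by an active
apical–apical link. The paper counts rosettes visually; this
adjacency-plus-minimum-size rule is one defensible operationalization, and
both thresholds are exposed in config and reported with the counts.
Primordium extent uses extremal agent x (excluding Depositers) or extremal
primordium-pixel x with the minimal-span unwrap across the periodic
boundary (cutting the largest empty gap). Edge velocities are centered
finite differences over a configurable window. A run "settles" when the
rosette count is unchanged for ≥200 steps/MCS.

## What the generators emulate — and what they do not

The scene builders are the package's synthetic-data source: the agent
column and the layered lattice reproduce the published initial conditions
(column geometry, domain fractions, lattice dimensions, layer order,
compartment stacks). They do not emulate chemokine or FGF ligand fields,
signaling-state changes (breeds/types are fixed labels except the
Depositer rule), cell division in the lattice model, 3D geometry, or
image-derived noise. Passing tests therefore show that the *mechanical*
feedback (local aggregation vs. migration tension) reproduces the reported
cluster dynamics under these idealized conditions; they say nothing about
signaling-driven patterning in real primordia.

## Numerical choices

- ABM relaxation is a single capped sweep per step (displacement cap 0.5);
  the pair-equilibrium distance solves s(l−L) = r/l² and the sweep is a
  stable fixed-point iteration for the default constants.
- CPM per-cell caches (volume, surface, trig sums for centers) are updated
  incrementally per accepted copy; float drift in the trig sums over 10³–10⁴
  MCS is ~1e-13 and is not refreshed. `refresh_caches()` recomputes exactly
  when needed (e.g., after editing a lattice by hand).
- Copy attempts crossing the closed y-boundary are rejected; contact and
  surface sums skip out-of-lattice neighbors.
- Link reformation and breakage are evaluated once per MCS, not per
  attempt (CompuCell3D behaves likewise); energies during an MCS use the
  link set fixed at its start.
- Same-owner copy attempts are no-ops with ΔJ = 0.

## Problem sizes for routine runs

Shipped test and reproduction runs use the desk-scale lattice (400×150),
2,100–3,600 MCS per lattice run, 1,200–5,000 steps per agent run, and
5–25 seeds per ensemble (more where a count distribution straddles two
values and the mode needs a stable estimate); these sizes are where the
reported counts were calibrated and where the behavior is reproducible
seed-to-seed.

## Known limitations

- Cluster counts at the boundary of the minimum-size rule can flicker when
  a 3-member rosette transiently loses a member; the settling criterion
  (≥200 unchanged) absorbs most but not all of this.
- The full-scale scene is a geometric extrapolation of the desk
  calibration, not an independently calibrated model.
- The agent model's spring sweep is first-order and not an energy
  minimizer; it approximates the layout behavior of spring embedders, not
  any specific implementation's trajectories.
- Stall-induced fusion passes through 3 on its way to 2, but the dwell time
  at 3 varies by seed; assertions are made on modal terminal counts, not on
  the intermediate trajectory.
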