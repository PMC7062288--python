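# Methods

`gliomabm` implements a hybrid discrete–continuum model of PDGF-driven
glioma: individual tumor cells are off-lattice agents in a 2D brain slice,
their collective density is book-kept on a coarse square mesh, and the
growth factor that drives them lives on a fine hexagonal lattice.  This
note records the model, its assumptions, the numerical choices, and what
the synthetic data used in testing does and does not establish.

## The model

### Tissue domain

The domain is a raster of gray matter, white matter, and empty space
(ventricles / outside the brain), in image coordinates (origin top-left,
x right, y down, positions in μm).  Two lattices overlay it:

* **Density mesh** — 100 × 100 μm squares.  Each cell belongs to the node
  containing it; a node's carrying capacity is κ in gray matter and 2κ/3
  in white matter (white matter is fibrous and holds fewer cell bodies).
  κ = 100 by default.  κ is a scale choice, not a measured quantity: every
  capacity-relative metric (the 10% / 50% / 1% thresholds below) is
  invariant to it.  The default is a plausibility argument for a ~300-μm
  slice: ~20 cells of 25 μm diameter per 100-μm square in a monolayer ×
  ~5 effective layers.
* **Hexagonal PDGF lattice** — pointy-top, node radius 12.5 μm (one cell
  radius), hence 25 μm center-to-center.  The spacing and orientation are
  package choices; the physical anchor is the node radius matching the
  cell radius.  Nodes whose center pixel is empty are removed; diffusion
  treats missing neighbors as no-flux walls.

The synthetic-tissue generator emulates the one anatomical feature the
model actually uses — a white-matter band (a synthetic corpus callosum)
crossing a gray-matter field, with optional ventricular holes.  It does
not attempt anatomical realism (cortical folds, asymmetric tracts,
boundary geometry of a real coronal slice).  The standard domain used for
calibration and acceptance is 10 × 8 mm with a 1-mm horizontal band
through the center, 25 μm/px.  A loader for real rasters (PGM/PNG with
0 = empty, 128 = gray, 255 = white) accepts atlas-derived slices at their
native resolution (e.g. 833 × 573 px at 17.4 μm/px ≈ 14.5 × 10 mm).

### Cells

Three kinds of cell:

* **Infected** — retrovirally transformed progenitors that secrete PDGF
  and receive a constant autocrine boost C_PA;
* **Recruited** — normal progenitors responding to paracrine PDGF;
* **Recruitable** — an inactive background field (density ρ_R % of local
  capacity, seeded per density node as Poisson) that permanently converts
  to recruited once local paracrine PDGF exceeds 5×10⁻⁴ ng/mL (strict
  inequality).  Inactive cells do not move, divide, or consume.

Each cell inherits a *potential phenotype*: intermitotic time τ (h), so
p_pot = 1/τ, and maximal speed m_pot = v (μm/h).  Initial (and
activation-time) draws are Normal(τ̄, σ_τ) truncated to [5 h, ∞) and
Normal(v̄, σ_v) truncated to [0, 100] μm/h; σ_τ = σ_v = 0 gives the
homogeneous model.  Daughters copy the parent phenotype exactly — there is
no mutation or drift, so all phenotypic change under treatment is
selection.  Recruited cells draw from the same distribution as infected
cells (the experimental data do not constrain a separate one).

The *observed phenotype* scales the potential by a Hill-type dose
response evaluated at the cell's nearest hex node, separately for
proliferation (K_p, β_p) and migration (K_m, β_m):

    infected:   γ(C) = (C_PA + C_PP) / (C_PA + C_PP + K)
    recruited:  γ(C) = C_PP / (C_PP + βK),   β ∈ (0.1, 1)

β < 1 lowers the recruited half-max — a decreased activation barrier —
while keeping γ(0) = 0.  Cells with γ ≤ 0.001 skip their activity that
step (a compute-saving cutoff consistent with the activation threshold).

**Cycle and division.**  Cycle progress advances by γ_p/τ per hour; at 1
the cell divides and resets.  The rate formulation is the integral version
of an intermitotic countdown timer and remains well-defined when γ varies
in time.  If the cell's density node holds *strictly more* cells than its
capacity, the cell is quiescent: the clock freezes (and resumes where it
left off), and no division occurs.  Daughters are placed one cell radius
(12.5 μm) away at a uniform random angle, re-drawn up to 10 times if the
angle lands in empty space, else placed atop the parent.

**Migration.**  Stop-and-go: when a cell's persistence clock expires it
picks stop/move by a fair coin (the probability is configurable; the
asymmetry between observed stop and move durations comes from the means,
not the coin), samples a fresh persistence time (exponential by default,
means 42.6 min moving / 70.1 min stopped, per the tracking data; an
empirical duration table can be plugged in), and picks a heading — uniform
in gray matter, Normal(0, σ_θ) about the current heading in white matter,
where moving runs also last 1.5×.  The 1.5× multiplier applies to moving
runs only, and the tissue class is evaluated at the cell's position at
reset time.  Because consecutive same-state periods merge at the coin
flip, the *apparent* run/stop durations in a track are geometric sums of
the sampled ones (≈2× the configured means at the fair coin); the
recovery tests therefore validate the segmentation against alternating
ground-truth segments, which is what segmentation of real data measures.

Movement is a straight segment of m·dt per step (≤ 25 μm at defaults, so
no sub-stepping).  Segments into empty space retry up to 10 random angles,
escalating the distance by one cell diameter per round up to 3 diameters;
a cell with no valid target stays (never observed in practice).  A move
into a node at/above capacity is allowed only if the target currently
holds fewer cells than the origin — density may slightly exceed capacity
but congestion chokes further influx.  These capacity decisions are taken
one cell at a time in randomized order with the counters updated
transactionally.  Quiescent cells still migrate by default (quiescence
freezes the cycle, not the cytoskeleton; the flowchart ordering places
migration after the quiescence check) — a flag disables this.

### PDGF field

Per step, after the cell loop (infected cells add r_s·dt to their node;
every active cell removes min(r_c·r_s·dt, available), never driving a node
negative), the whole field decays and then diffuses:

* decay is applied in closed form C ← C·exp(−r_d·dt) — the difference
  from forward Euler is O(dt²) and far below fit tolerances, and the form
  is unconditionally stable;
* diffusion uses the standard second-order hex stencil
  ∇²C_i ≈ (2/(3h²))·Σ_j (C_j − C_i), explicitly integrated with substeps
  dt_sub ≤ 0.9·(3h²)/(12·D_p); with symmetric adjacency this conserves
  mass to round-off, and no-flux boundaries keep mass in the tissue.

Table-note on units: the decay-rate range is printed in the source
parameter table as "ng/mL·day", but a first-order decay constant must be
day⁻¹; r_d is treated as day⁻¹ throughout.  Secretion is likewise handled
entirely as field mass: the autocrine pool C_PA is a constant response
parameter (p_a), not a tracked reservoir.

### Engine step

Per dt (default 0.25 h): (1) rebuild density counts; (2) activation sweep;
(3) cell loop — quiescence/cycle, divisions, migration, secretion and
consumption; (4) decay; (5) diffusion; (6) anti-proliferative kill if
active.  The per-cell operations are executed as vectorized phases rather
than a literal per-cell loop; the only order-sensitive decision (moving
into crowded nodes) is resolved transactionally in randomized cell order,
and division placement uses start-of-phase state.  Halving dt changes the
growth metric by <2% on the scaled convergence test.  All randomness flows
from one seed through named substreams (init / division / migration), so a
run is bit-reproducible.

### Treatments

* **AP** (anti-proliferative): at every step while active, every active
  non-quiescent cell with inherited τ < 60 h is removed.  Quiescent cells
  are spared regardless of τ — but become vulnerable once local density
  drops and they re-enter the cycle.
* **AM** (anti-migratory): effective speeds ×0.1 while active; reversible,
  kills nothing.
* Default window: on at day 14, off at day 42 (the main treatment
  experiments); the shorter 14→28 d window used for the waterfall
  comparisons is a schedule setting.

### Metrics

* **Diameter**: centroid of suprathreshold density nodes (≥10% of local
  capacity for the imaging-matched size); 360 angular bins; per-bin
  maximum suprathreshold radius; diameter = 2 × mean over bins.  Each node
  covers the angular extent of its 100-μm square (effective radius
  r + spacing/2), otherwise a discrete grid leaves most 1° bins empty and
  the mean collapses.  An equivalent-area-circle variant sits behind a
  flag; the two conventions differ by less than the 10% calibration
  tolerance.
* **Core/rim**: d_c = diameter at the 50% threshold; rim diameter at 1%;
  d_r = rim diameter − d_c (difference of diameters, per the stacked-bar
  definition of rim size).
* **I/R**: infected / recruited counts over active cells; undefined
  (signaled) with no recruited cells.
* **Phenotype statistics**: measured (p, m) via the dose response at each
  cell's local PDGF, non-quiescent cells only; potential statistics over
  all cells; radial profiles at 100 μm.
* **Ki-67 index**: a non-quiescent cell is positive when its remaining
  cycle time (1 − progress)·τ/γ_p ≤ 20 h; the index is the positive
  percentage within the single 100-μm node holding the most positive
  cells ("area of highest activity"); the window is configurable since the
  histological counterpart is a stained-region percentage.
* **Outcome classes** from the end-of-treatment diameter: <0.5 mm
  complete response, 0.5–2 small, 2–3 medium, >3 large.

### Track statistics

Virtual tracking mirrors the ex-vivo protocol: cells sampled from the rim
(1–50% of capacity, where real cells are distinguishable), positions every
3 min for 25 h, daughters tracked after division (mother's track ends,
both daughters are flagged).  Per-cell speed is distance over time moving;
frames displacing < 1 μm (20 μm/h at the 3-min cadence — the hand-tracking
resolution is unstated, this is the package default) are stops.
Proliferation rate is divisions / (starting cells × hours), in %/h.

### Calibration

The objective is the weighted mean relative error across reference
metrics, each simulated value averaged over replicate seeds (3 during
search; final candidates re-scored at 10).  Size-only mode targets the
serial-imaging diameters 1.7 / 2.4 / 3.2 mm at days 5 / 10 / 17; all-data
mode adds cell-scale metrics — the bundled table carries the values
printed in the main text (rim speed moments, I/R = 0.25 from 80% recruited
labeling) with equal weights, since the full 16-metric table and its
weights live in a supplement that is not bundled.

The search is a hybrid GA / random-sampling scheme: population 20,
tournament k = 2, uniform crossover at rate 0.9, per-parameter Gaussian
mutation with σ = 10% of the range, and 30% random immigrants per
generation; an archive keeps the best 300 unique sets and a trace records
convergence.  These GA internals are package choices (the original
hybrid's exact schedule is not reproduced in the source); what is asserted
is objective value, not trajectory.  Replicates default to 3 in search as
a cost/variance compromise.  A go-or-grow constrained mode splits the
population into a non-migrating "grow" class and a slow-cycling "go"
class (τ = 200 h), used only as an alternative fitting hypothesis.

The pinned constants shipped in `gliomabm.calibration` were produced on
the standard 10 × 8 mm synthetic domain: `PINNED_COHORT` is the top 20 of
a budget-150 GA size search (single-replicate objective), and
`PINNED_SIZE_FIT` is the result of a follow-up local selection among the
leaders on 3-seed replicate-averaged diameters with a penalty on
seed-to-seed spread.  The spread penalty matters because single-run
outcomes are heavy-tailed for parameter sets with large σ_τ: the
truncated-normal draw puts a few percent of cells near the 5-h
intermitotic floor, and whether such a clone arises early can swing the
day-17 diameter by over 20% between seeds.  The pinned set therefore
favors a moderate σ_τ member (characterized over 12 seeds: day-5/10/17
means 1.57 / 2.47 / 3.24 mm, SDs ≈ 0.16 mm); this is a reproducibility
preference among equally well-fitting sets, not a change to the search
ranges.  A deliberate property of this problem — visible in the archive
spread — is that many distinct parameter sets fit the size dynamics
equally well; single-cell data are what discriminates them.

## Problem sizes used in the shipped tests

The test suite runs everything at desk scale as a deliberate design
choice: unit and property tests use 2 × 2 mm domains and hundreds of
cells; the pinned-fit regression runs one full 17-day simulation on the
standard 10 × 8 mm domain (~10⁵ cells); the cohort checks
(anti-migratory monotonicity across 20 fitted sets,
heterogeneous-vs-homogeneous response divergence) use shortened treatment
windows on a 6 × 5 mm domain.  The full-budget search (≈500 evaluations,
hours of CPU) is reproducible through the same API
(`PDGFGliomaModel.fit`) or `gliomabm calibrate` but is not part of the
test run.

## What the synthetic data do and do not show

The generator reproduces the *structural* conditions of the experiment —
initial bolus and 100+100 inoculum, recruitable background, gray/white
anisotropy, the printed persistence means — so passing tests establish
internal consistency: operators do what their definitions say, conserved
quantities are conserved, estimators recover ground truth planted in
synthetic tracks, and fitted parameter sets reproduce the target size
curve.  They do not establish anatomical realism (a band is not a corpus
callosum), identifiability of any single parameter (explicitly the
opposite), or transferability of the fitted values to real tissue, where
angiogenesis, hypoxia, necrosis, and phenotypic drift of recruited cells —
all outside this model's scope — matter.

## Known limitations

* 2D slice; no angiogenesis / hypoxia / necrosis; no death outside the AP
  treatment; no receptor kinetics or PDGF-gradient taxis (migration is
  undirected within the turning rules).
* Recruited cells never transform into secretors, and phenotypes do not
  drift; observations that require drift will not be reproduced.
* The per-node consumption/secretion treats a hex node as a well-mixed
  compartment; sub-node gradients are unresolved.
* Apparent track persistence times differ from the sampling means by the
  state-merging factor discussed above.
* The example-tumor reproduction table ships as placeholders until the
  supplementary parameter values are transcribed.
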