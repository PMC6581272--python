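# Methods

## Model

Two RNA fragments X and Y assemble reversibly into a catalyst C
(X + Y ⇌ C, rates k_f, k_b); the catalyst replicates free fragments
(X + C → 2X + C at k_x, Y + C → 2Y + C at k_y) but not itself, because
only templates shorter than the polymerase are assumed replicable.
Monomers are treated as buffered and complementary-strand synthesis is
ignored.  All defaults are k_f = k_b = k_x = k_y = 1; only the ratio
D/k of transfer to replication matters in the reduced analysis, so k = 1
there without loss of generality.

### Batch (deterministic) level

Concentrations obey mass action minus a dilution term
μ = k_x·x·c + k_y·y·c chosen so the total mass x + y + 2c is constant
(an alternative convention holding x + y + c constant is available via
`conserve="total"`; it does not change the qualitative behavior).  The
ratio dynamics d/dt(x_tot/y_tot) = k c²/y_tot²·(x_tot − y_tot) make the
balanced state a repeller: `integrate_batch` (LSODA, rtol 1e−10,
atol 1e−12) demonstrates the monotone amplification of a 1e−6 imbalance
and the collapse of c, with mass conserved to better than 1e−8 —
asserted after every integration.

The N-fragment generalization uses a single-step N-body assembly
k_f·Πxᵢ → C with dilution μ = Σkᵢxᵢc holding Σxᵢ + N·c = 1.  It reduces
exactly to the two-fragment equations at N = 2 and preserves the
positive-feedback structure; the package claims only the instability
property (positive symmetry-breaking eigenvalue at the balanced steady
state, checked numerically at N = 3), not a specific multi-step
assembly pathway, for which several chemically distinct schemes would
behave alike.

### Protocell (stochastic) level

N_cell compartments hold integer copy numbers (n_x, n_y, n_c).  One
exact Gillespie process runs over the union of all cells' seven
channels: assembly k_f·n_x·n_y/Ω, disassembly k_b·n_c, replication
k_x·n_x·n_c/Ω and k_y·n_y·n_c/Ω, and per-molecule transfer D·n_x, D·n_y,
D·n_c.  The bimolecular volume Ω is the cell's current fragment count
V = n_x + n_y + 2n_c, so counts/V behave like the normalized batch
concentrations (total ≈ 1) and simulated concentrations are directly
comparable with the reduced model's fixed point; a fixed-Ω convention is
available (`omega_fixed`), and is what the SSA-vs-ODE agreement test
uses, since a constant-volume ensemble is what the mass-action ODE
describes.

Division triggers the moment V reaches V_div (fragments inside
catalysts count, two per catalyst; no overshoot beyond the single
molecule delivered by the triggering event).  Every molecule goes to
daughter 1 with probability 1/2, catalysts as intact units.  One cell
chosen uniformly among the N+1 cells present immediately after the
division — the N−1 bystanders and both daughters — is removed.
Daughter eligibility matters: if daughters were exempt, a population
reduced to a single catalyst-bearing lineage could never lose it (only
that cell divides, and it would never be removable), divisions would
continue indefinitely, and the no-transfer instability at large V_div
would be unobservable.  With eligibility the last catalyst is lost in
O(N_cell) divisions once the population has collapsed to single-catalyst
lineages, which is what terminates D = 0 runs.  The exempt variant
remains available (`daughters_eligible=False`).

Transfer removes one molecule from its source and delivers it to a cell
chosen uniformly among the other N_cell − 1 cells (self-return is
impossible at the event level; the reduced model's ½-return factor
emerges from the cell-type frequencies).  With probability p_loss
(default 0) the molecule is destroyed in transit instead.

Runs terminate on: reaching the division budget ("stable" in the
experiment drivers); global loss of one fragment type (absorbing — a
catalyst contains one fragment of each type, so no replication of the
lost type can ever resume); a frozen state with zero total propensity
(all cells pure and catalyst-free); a stall (default 5×10⁶ events
without a single division, catching the divide-but-cannot-grow deadlock
of single-catalyst populations); or an overall event budget.
Identical (parameters, initial state, seed) reproduce the event
sequence bit for bit.  The event loop is a numba-compiled kernel whose
per-cell propensity updates are tested against the plain-Python
reference `cell_propensities`; the running total propensity is
refreshed from scratch every ~10⁶ events to cap floating-point drift,
and boundary picks caused by rounding are discarded rather than allowed
to drive a count negative.

The standard initial condition is V_div/4 copies of each free fragment
and no catalysts in every cell.

### Reduced two-subsystem model

The X-dominant and Y-dominant halves of the population are treated as
two well-mixed subsystems of equal volume with total-X concentrations
x₁, x₂ (each subsystem's total concentration normalized to 1).  Fast
assembly equilibrium with k_f = k_b gives c = 1 − √(1 − x_tot·y_tot),
approximated by c ≈ x_tot·y_tot/2 (relative error < 5% for
x_tot·y_tot < 0.18; both forms in `c_of_totals`).  Substituting into
the growth-plus-dilution dynamics yields the drift
F(x) = −x²(1−x)²(1−2x)/4 and the coupled system
ẋᵢ = F(xᵢ) + (D/2)(x_j − xᵢ).

At the asymmetric fixed point the identity x(1−x) = √(2D) holds, from
which x₁ = ½(1+√(1−4√(2D))) and the eigenvalues λ₁ = F′(x₁) =
5D − √(2D)/2 (eigenvector (1,1)) and λ₂ = λ₁ − D (eigenvector (1,−1))
follow exactly within the c-approximation.  `find_bifurcations` does
not use these closed forms: it tracks the fixed point by root
bracketing on the antisymmetric section, takes eigenvalues from a
central finite-difference Jacobian (h = 1e−6), and bisects D to a 1e−8
bracket — λ₁'s sign change gives D* and the branch's disappearance
gives D⁺.  The closed forms are asserted against this numeric route in
the tests (agreement to 1e−8).

Fixed-point classification uses |λ| < 1e−9 for "marginal".  Note that
the full plane carries, besides the symmetric point, the corner states
and the asymmetric pair, four additional off-section saddle crossings
of the nullclines for small D (found by `interior_fixed_points_numeric`,
a multi-start 2-D root search); the familiar three-to-one fixed-point
transition at D⁺ concerns the swap-symmetric sections and is counted by
`count_section_crossings`.

### Frequency-dependent selection

Perturbing the volume split to (½+ϵ, ½−ϵ) and keeping the molecule
bookkeeping consistent — a molecule leaving subsystem i returns to it
with probability equal to i's own cell-number share, and incoming
amounts are divided by the receiving volume — gives

    ẋ₁ = F(x₁) + D(½−ϵ)(x₂−x₁),   ẋ₂ = F(x₂) + D(½+ϵ)(x₁−x₂).

The ϵ-perturbation then acts along (1,1), so the steady-state shifts
satisfy δ₁ = δ₂ = −Dϵ(2x*−1)/λ₁ > 0 for D < D*: both subsystems gain X,
which makes the X-majority subsystem more asymmetric (slower growth,
μ₁ < μ*) and the X-minority subsystem more balanced (faster growth,
μ₂ > μ*).  `volume_perturbation` reports δ from the first-order linear
solve at the unperturbed fixed point (the two components are then equal
by construction; the full nonlinear steady state differs between them
at O(ϵ²)) and the growth rates μᵢ = (1 − 2cᵢ)cᵢ from the nonlinear
solve, with γ = (μ₂ − μ*)/ϵ.  An asymmetric-in/out variant of the
transfer terms that perturbs along (1,−1) instead would predict equal
and opposite concentration shifts and a *positive* feedback on the
volume split, contradicting both the restoring behavior of the
simulations and the requirement D < D*; the consistent form above is
therefore the one implemented.

## Experiments and problem sizes

All experiment drivers derive child seeds from
(master seed, grid indices, run index) via `numpy.random.SeedSequence`,
making sweeps order-independent and reproducible.

* **Stability trials / phase diagram** — a run is stable when it
  reaches the division budget from the standard initial condition.
  The default grid is V_div ∈ {10, 100, 300, 1000} × N_cell ∈ {10, 100}
  with 10⁴ divisions and 3 runs per point; at these sizes the
  no-transfer system is stable only in the narrow stochastic-corrector
  band (V_div ≈ 100 with N_cell = 100), while D = 0.01 stabilizes the
  entire N_cell = 100 column.  A `--profile full` option raises the
  budget to 4×10⁵ divisions for long-horizon classification; boundary
  points may shift between budgets.
* **Coexistence time series** — V_div = 1000, N_cell = 100; runs of
  2–4×10⁴ divisions at D ∈ {0, 0.01, 0.02}.  Coexistence is scored on
  the final quarter of the division records: "both types retained"
  means the minority dividing-cell type keeps ≥ 25% of typed records
  (a 3:1 band), "symmetry lost" means it falls below that.
* **Minor-fragment sweep** — V_div = 2000, N_cell = 50, 2×10⁴
  divisions, second half sampled.  Mean X_tot/V of Y-dominant dividing
  cells at D = 0.01 falls within a few percent of the analytic
  x₂ = 0.1705.  The statistic is conditioned on runs that reach the
  division budget: at these population sizes a minority of seeds
  loses one cell type during the initial differentiation (small-N
  drift), after which the per-division statistic is no longer defined.
  At D = 1e−4 the simulated minor total exceeds the analytic curve by
  4–6%: cells must hold at least one catalyst to divide, a floor the
  continuous fixed point does not see.
* **SSA/ODE agreement** — one non-dividing cell, (4000, 4000, 1000)
  molecules, fixed Ω = 10⁴, 20 seeds; ensemble means at t = 1 agree
  with the dilution-free ODE to well under 1%.
* **Discreteness effect** — at N_cell = 50, V_div = 1000 a transfer
  rate of D = 1e−5 loses a fragment type within ~2×10³ divisions in
  every seed while D = 0.01 survives 4×10⁴ — replication fails at
  small D in the discrete system despite deterministic stability for
  all 0 < D < D*.  At N_cell = 100 the same loss exists but takes
  longer than the budgets used here (populations survived 2×10⁵
  divisions in exploratory runs), so the property is asserted at the
  smaller population size.

## What the simulations do and do not show

The protocell model is the data generator here: there is no external
data.  Its idealizations — buffered monomers, no complementary strands,
volume exactly proportional to fragment count, binomial partitioning,
uniform transfer — mean that quantitative agreement with the reduced
model demonstrates internal consistency of the two descriptions, not
chemical realism.  Division budgets are one order of magnitude below
the long-horizon classification used for the definitive phase diagram
(4×10⁵ divisions), so stability labels near the boundary are
budget-dependent; the qualitative orderings tested (transfer enlarges
the stable region; coexistence inside 0 < D < D*; fixation outside)
are insensitive to this in the regimes exercised.

## Known limitations

* The protocell simulator is restricted to two fragment species; the
  N-fragment generalization exists only at the deterministic batch
  level.
* `N_cell = 1` with transfer treats the (destination-less) transfer
  event as a return to the source; with division it keeps one daughter.
  Both are degenerate edge cases outside the model's intended regime.
* The reduced model assumes exactly two subsystems and k_x = k_y; for
  k_x ≠ k_y the simulator still runs (the cell-type ratio compensates
  small rate differences) but no closed-form fixed point is provided.
* Divisions triggered by a transferred catalyst can record a volume of
  V_div + 1 (the delivery adds two fragments at once).
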