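# Model and methods

## The cross-bridge cycle

`xbridge` simulates ensembles of myosin II motor heads interacting with an
actin filament through a cyclic, strain-dependent kinetic scheme — the
"bottom-up" approach in which every parameter refers to a property of the
isolated proteins and ensemble behaviour (force-velocity relations,
isometric force development, stepwise sliding) is *predicted*, not fitted.

Seven biochemical states form a single closed cycle:

    MT -> MDP -> AMDP_PP -> AMDP_PiR -> AMD_L -> AMD_H -> AM -> (MT)

`MT` (myosin.ATP) and `MDP` (myosin.ADP.Pi) are detached.  The attached
states are the pre-power-stroke state `AMDP_PP`, the Pi-release state
`AMDP_PiR`, the low-force (`AMD_L`) and high-force (`AMD_H`) strongly
bound states, and rigor `AM`.  Each attached state i has an elastic free
energy G_E = ks (x − x_i)² / 2 centred on its own strain minimum:

| state               | minimum          | default (nm) |
|---------------------|------------------|--------------|
| AMDP_PP             | x₁               | 5.5          |
| AMDP_PiR, AMD_L     | x₁₁              | 5.0          |
| AMD_H               | x₂               | 1.0          |
| AM                  | 0 (origin)       | 0            |

x is the axial distance between a head's anchor and the centre of the
actin site it binds; x = 0 where the rigor free energy is minimal, and
shortening carries attached heads toward decreasing x.  The progression of
minima x₁ → x₁₁ → x₂ → 0 is the working stroke (5.5 nm in total at the
defaults).  In nonlinear-elasticity mode the restoring force is
piecewise linear — stiffness `ks` (2.8 pN/nm) for extension beyond the
minimum, `ks_compliant` (0.28 pN/nm) below it — emulating the buckling
compliance measured for single myosin heads under compression; setting
`ks_compliant = ks` reproduces linear mode bit-for-bit.

Chemical (basal) free-energy levels are fixed so one full cycle dissipates
ΔG_ATP = 25 kBT with kBT = 4 pN·nm (so a 4 nm step against 30 pN —
120 pN·nm — is 30 kBT, more than one ATP turnover can supply; the
`mechanical_work` helper flags exactly this diagnostic).

## Strain-dependent rates and detailed balance

Every reversible transition is parameterized by a rate constant k₀ at the
strain where its elastic free-energy difference vanishes and a *split*
φ ∈ [0, 1]:

    k_f(x) = k₀ exp(φ ΔG_E(x)/kBT),
    k_r(x) = k_f(x) exp(−ΔG(x)/kBT),

with ΔG(x) the full (basal + elastic) free-energy drop.  Detailed balance
therefore holds identically at every strain, for any split.  Attachment
uses φ = 1, making the forward rate a Gaussian of width √(kBT/ks) ≈ 1.2 nm
around x₁ and the early-detachment rate strain-independent; the strokes
use the symmetric Kramers choice φ = ½ so that mid-landscape rates stay
finite; ADP release uses φ = 0.8, giving the strain gate its asymmetry
(release accelerates at negative strain, slows under positive load).
A numerical cap (10⁶ s⁻¹) keeps Gillespie waiting times finite at extreme
strain; the cap rescales a reversible pair *jointly*, so detailed balance
survives even where it engages.  ATP-induced detachment (at mM MgATP) and
hydrolysis are one-way at this resolution; no reverse rate is synthesized
for them.

Default rate constants (s⁻¹): hydrolysis 100; attachment 400 (at x₁);
PP→PiR 5000; Pi release 3000; main stroke 10⁴; ADP release 800;
detachment 10⁴.  These are values typical of fast skeletal actomyosin
near room temperature and produce F₀ ≈ 1.1 pN per head (≈ 6–7 pN per
*attached* head at ≈ 17 % attachment), Vmax ≈ 2.4 µm/s per half-sarcomere
and peak power at ≈ 0.3 Vmax.  Two numerical choices deserve note.
First, the Pi-release step commits only 3 kBT (with 10.5 kBT on the main
stroke): a more deeply committed low-force state creates long-lived
attachments at large positive strain whose stochastic arrival makes
isometric equilibration take seconds and force-rise fits unstable.
Second, x₁ = 5.5 nm sits on the rising branch of Pmax(x₁), which peaks
near 7 nm under this landscape — the sweep experiment (below) probes the
branch where power grows with x₁ while isometric force development slows.

## Ensemble geometry

The half-sarcomere is approximated by its in vitro motility analogue: a
20 µm actin filament presents one myosin-binding target zone per 36 nm
helical repeat (556 zones; 1 or 3 binding sites per zone, neighbouring
sites 5.5 nm apart — one actin monomer along a strand), swept by
surface-anchored heads at 5000 µm⁻² over a 30 nm band, i.e. 3000 heads
per 20 µm (150/µm); the equivalent sarcomere bookkeeping (10 half thick
filaments × 294 heads / 20 thin filaments = 147 heads per thin filament)
is reproduced by `sarcomere_heads_per_thin_filament`.  Head offsets to the
nearest zone centre are uniform: signed offsets on [−18, +18) nm in 360
bins of 0.1 nm (an unsigned [0, 18) variant with 180 bins is provided, as
is a deterministic `uniform_grid` placement for the large-ensemble limit).

## Steady-state solver

At constant sliding velocity v the state probabilities p(state, x) obey
the transport balance −v dp/dx = K(x) p over one 36 nm period with
periodic closure, where K(x) is the kinetic generator expanded over
binding-site channels (each attached state × each site in the zone).
The solver propagates cell-by-cell with matrix exponentials of the
midpoint generator — exact for rates piecewise-constant on cells and
unconditionally probability-conserving and positive — and obtains the
periodic solution as the fixed point of the one-period monodromy matrix.
v = 0 is solved as the algebraic stationary distribution at each x, not
as a small-v limit.  Attached probability reaching the periodic boundary
is negligible at the defaults (detachment is capped-fast at extreme
strain), which is what makes the periodic closure adequate.

Ensemble force is n_heads × the period-average of Σ p·ks(x − x_i) over
attached channels (per-head normalization; with 3-site zones the sites
compete for each head and occupancies are mutually exclusive).  The
force-velocity curve locates Vmax by root finding, maximum power by
bounded maximization of F·v, and fits the Hill hyperbola
(F + a)(v + b) = (F₀ + a) b by least squares.  Grid: Δx = 0.1 nm default
(matching the head-placement bins; halving it moves F₀ and Pmax by well
under 0.5 %).

## Monte Carlo engine

Finite ensembles are simulated event-by-event with the Gillespie
algorithm.  Heads are independent; they couple only through the shared
filament position z.  The filament is rigid and inertia-free: after every
event that can change the force balance, z is re-equilibrated so the
summed cross-bridge force equals the external load (closed form for
linear elasticity, bracketed root find for nonlinear; residual
< 10⁻⁶ pN).  Between events the configuration is constant, so waiting
times are exactly exponential in the total propensity.  Modes:
`zero_load`, `constant_load` (load clamp; velocity estimated from a
least-squares slope over the trailing portion of z(t)), and `isometric`
(z fixed; force recorded).  Under load with no attached heads the
position is held and the episode is counted (diffusive escape is not
modelled).  Runs are bit-reproducible for a fixed seed (one PCG64 stream
per run).

Because isometric ensembles contain rarely-attaching, high-strain heads,
cold starts relax over seconds.  Steady-state comparisons therefore
warm-start the engine from the solver's stationary distribution
(`sample_stationary`) and let it evolve freely; the engine is still free
to drift away if its kinetics disagreed with the solver.

## Experiments

* **Force-velocity (`run_fv_experiment`)** — steady-state curves for
  1-site vs 3-site target zones × linear vs nonlinear elasticity.
  Three-site zones raise isometric force (more heads find a favourably
  placed site); nonlinear elasticity raises peak power (negatively
  strained drag heads push back more weakly).
* **Step records (`run_step_experiment`)** — 18 heads against zero load
  for 0.1 s.  Every event-to-event displacement of ≥ 0.5 nm is a step
  (the trace is piecewise constant, so thresholded event displacements
  are the natural step definition); steps are grouped greedily into
  0.4 ms windows.  Individual stroke sub-steps shared among few attached
  heads produce clusters of typically 2–4 steps of ~1–7 nm.
* **x₁ sweep (`run_x1_sweep`)** — five x₁ values spanning ±1 nm around
  the default, with x₁₁ = x₁ − 0.5 nm moved in parallel.  Maximum power
  (per head, steady-state) rises strictly with x₁ on this branch
  (Spearman r = 1; the exact two-sided permutation p for five points in
  perfect order is 2/120 ≈ 0.0167).  The isometric force-rise rate comes
  from 4 Monte Carlo replicates per x₁ (2000 heads, 0.3 s, all heads
  initially detached — the standard tetanus-rise protocol), each fitted
  with F(t) = F∞(1 − e^{−kt}); attachment optima shifted to larger x₁
  slow the transition into high-force states, so the pooled (x₁, k)
  correlation is negative, with replicate scatter of the same order as
  the trend.  An all-attached (AMDP_PP) initial condition is also
  implemented; at uniform strains it produces an overshoot-decay
  transient rather than a rise, which is why the sweep uses the detached
  start.

## Statistical machinery

Spearman correlations use mid-ranks for ties and, for n ≤ 10, an exact
two-sided p by full enumeration of rank permutations (vectorized in
batches); larger samples use the t approximation.  Exponential rise fits
report the rate with its standard error; an optional window restricted to
the upper half of the rise is provided for sensitivity analysis.

## What the synthetic conditions do and do not show

All inputs are generated programmatically (lattice, placements, seeds);
there is no external data.  The geometry emulates a 1D axial model of a
half-sarcomere: no filament compliance, no 3D lattice or azimuthal
positions, no thick-filament mechanosensing, no regulatory proteins, and
heads are independent single heads (a "molecule" is one head).  Passing
tests therefore demonstrate internal consistency of the mechanokinetic
formalism and its two independent solution routes, and qualitative
agreement with the printed ensemble arithmetic and trend results — not
quantitative agreement with any particular muscle preparation.

## Problem sizes

Default experiment sizes were chosen to make replicate noise meaningful
rather than dominant: 3000 heads for solver/Monte-Carlo equivalence
(4 isometric + 3×3 clamp replicates), 2000 heads × 4 replicates × 5 x₁
values for the force-rise sweep, 20 seeds × 18 heads for the step survey.
The steady-state solver itself is effectively instantaneous at these
sizes.

## Known limitations

* Attached probability reaching the trailing strain boundary is handed to
  the detached pool (its survival distance beyond the boundary is
  negligible because detachment is capped-fast there); for parameter sets
  with slow detachment at extreme strain this closure would become an
  approximation.
* A load-clamped *finite* ensemble slides slightly slower than the
  infinite-ensemble solver prediction at the same load — a genuine
  fluctuation correction of order 1/N_attached (about 0.5 % at 3000 total
  heads), not a numerical error.  Near Vmax the vanishing slope |dF/dv|
  amplifies this correction above replicate noise in velocity space, which
  is why the equivalence check compares at 0.1–0.5 Vmax.
* The force-rise fit is an effective single-exponential summary of a
  multi-exponential relaxation; its value depends on the fit window.
* Eccentric (lengthening) velocities, inter-site slippage and two-head
  cooperativity are out of scope by design.
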