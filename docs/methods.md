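# Methods

## Model structure

The simulator couples three layers on a cubic lattice of 10-µm voxels
(one voxel ≈ one cell diameter ≈ 1 pL):

1. **Continuum chemokine fields.**  Each voxel carries a free (*F*) and
   an ECM-bound (*B*) CXCL12 concentration in nM.  Free chemokine
   diffuses and degrades; bound chemokine is immobile and protected
   from extracellular degradation.  ECM binding is linear
   (non-saturable): matrix sites are assumed far from occupancy, so the
   site density is lumped into the partition coefficient
   K_p = k_on/k_off = B/F at equilibrium.
2. **Discrete cells.**  Secreting cells (fibroblast-like) inject S
   molecules/s into their voxel.  CXCR7+ scavenger cells — scattered in
   the tissue or seeded on the vessel-lining shell — each carry a
   four-pool receptor-trafficking system (surface receptor R_s, surface
   complex C_s, internal receptor R_i, internal complex C_i, in
   molecule counts):

       dR_s/dt = −k_on L R_s + k_off C_s − k_int0 R_s + k_rec R_i
       dC_s/dt =  k_on L R_s − k_off C_s − k_int C_s
       dR_i/dt =  k_int0 R_s − k_rec R_i + k_degL C_i
       dC_i/dt =  k_int C_s − k_degL C_i

   L is the voxel's free + bound concentration: scavengers bind free
   and ECM-bound ligand with the same parameters (this is a stated
   model assumption; it sits in tension with the protective role of
   ECM binding against extracellular degradation, and we follow the
   uptake-sees-total convention).  Ligand degraded from C_i accumulates
   in a tally and its receptor returns to R_i, so total receptor
   R_s + C_s + R_i + C_i is conserved exactly with zero synthesis; the
   ligand-free steady state (R_s = R_total,
   R_i = (k_int0/k_rec)·R_total) is the initial condition.  CXCR4
   uptake is deliberately excluded: CXCR7 binds CXCL12 roughly two
   orders of magnitude more tightly and is taken to dominate
   degradation.
3. **The vessel and its rhythms.**  A k×k-voxel column (default 2×2 =
   400 µm²) spans the full grid; its voxels are internal walls for
   diffusion and exchange chemokine with face-adjacent lining
   compartments via dn/dt = pA(C_blood − C_endo).  C_endo is the lining
   compartment's *free* concentration (matrix-bound ligand cannot cross
   the wall); A sums 100-µm² vessel-facing faces, so the four diagonal
   corner voxels of the lining shell scavenge but do not exchange.
   Blood is an infinite reservoir — tissue fluxes never change
   C_blood.  Secretion rate and blood concentration share the
   cosinusoidal forcing X(t) with default 2-fold daily swing; because
   they oscillate in phase, the blood-tissue gradient is modulated but
   its sign cannot flip, which the day-long runs confirm.

The lining shell includes cross-sectional diagonal neighbors (12 voxels
per layer for the 2×2 vessel, 240 total on the 200-µm grid), which is
what makes 200 endothelial cells an 83% coverage.  Face-only adjacency
(8/layer) would put coverage above 100%.

## Parameters

All rates are package defaults informed by the chemokine-transport
literature, config-overridable, and logged as non-published defaults on
load.  Per-isoform values encode the established orderings: ECM
partition γ > β > α; secretion rate and blood level α > β > γ.

| parameter | default | units | note |
|---|---|---|---|
| D | 150 | µm²/s | free CXCL12 (~8 kDa) in tissue |
| k_deg | 1×10⁻⁴ | 1/s | extracellular proteolysis, free pool only |
| k_on_ecm | 0.05 | 1/s | lumped matrix on-rate; equilibration ~1 min |
| K_p (α, β, γ) | 1, 5, 25 | – | bound:free partition |
| S (α, β, γ) | 1, 0.5, 0.25 | molecules/cell/s | baseline secretion |
| blood mean (α, β, γ) | 0.25, 0.10, 0.02 | nM | mid-cycle blood level |
| k_on / k_off | 0.1 / 0.01 | 1/(nM·s), 1/s | receptor K_D = 0.1 nM |
| k_int / k_int0 | 0.1 / 0.001 | 1/s | complex vs constitutive internalization |
| k_rec / k_degL | 0.01 / 0.05 | 1/s | recycling; lysosomal ligand degradation |
| R_total | 2×10⁵ | receptors/cell | surface pool at rest |
| p | 0.1 | µm/s | vascular permeability |
| dt | 0.1 (full) / 0.5 (desk-scale) | s | transport timestep |

## Numerics

- **Diffusion** uses the averaged-Saulyev alternating-direction explicit
  scheme, one upward and one downward sweep per axis per step, averaged.
  Sweeps are written in conservative flux form — the flux through a face
  is a single expression shared by both adjacent cells, and closed faces
  (domain boundary, vessel wall) carry zero flux — so total mass
  telescopes exactly (measured drift ~10⁻¹² relative over 10⁴ steps).
  The scheme is unconditionally stable; positivity and accuracy degrade
  above diffusion number r = D·dt/dx² = 1 (a warning is logged; default
  conditions sit at r = 0.15–0.75).  Against the closed-form no-flux
  eigenfunction series for a point impulse the solver is within 0.9% L2
  at t = 10 s.  A numba-compiled kernel and a pure-numpy reference
  implementation produce bit-identical results (tested).
- **Degradation and ECM exchange** use exact exponential updates, which
  keep both pools non-negative at any dt.
- **Trafficking** is advanced per transport step by a Strang split: a
  half-step of the slow linear transitions (RK4; rates ≤ 0.1/s), an
  exact exponential update of the stiff ligand↔surface-complex exchange
  with R_s frozen (receptor pools are ~100× larger than per-step ligand
  turnover, so the frozen-R_s error is far below other model
  uncertainty), and a second slow half-step.  This is
  positivity-preserving at any dt, and makes the voxel bookkeeping
  exact: ligand removed from the voxel equals the cell's complex gain
  plus degraded tally, and removal can never exceed the voxel content.
  For clamped-ligand (reservoir) conditions the full linear system is
  integrated with stiffness-scaled RK4 substeps; against an independent
  Radau reference over a simulated hour the error is <10⁻⁸ relative.
- **Operator-splitting order** per step: secretion → diffusion →
  transvascular exchange → degradation → ECM exchange → uptake.  The
  order is a fixed convention; at dt ≤ 0.5 s results are first-order
  insensitive to it.
- **Ties and degenerate inputs**: empty placements and zero rates are
  exact no-ops; a vessel requires k+2 voxels of lateral room; cluster
  cubes must be voxel-aligned; an over-subscribed voxel pool raises a
  capacity error rather than silently double-seeding.

## Experiment drivers and steady-state detection

*Two-cluster runs* (source vs sink, no vessel, no rhythm) measure the
cell-derived gradient between the clusters' facing 6×6-voxel faces,
normalized by the 100-µm center-to-center separation (the printed
inter-cluster distance; the faces themselves are 50 µm apart — this is
a documented sampling convention, not a physical gradient at a point).
Steady state is declared when the gradient's max–min excursion within a
trailing 5-min window falls below a threshold.  The configured default
threshold is 0.1 nM/µm as conventionally printed; it is far coarser
than the ~10⁻⁴–10⁻³ nM/µm gradients these study conditions produce, so
the desk-scale configuration uses 2×10⁻⁶ nM/µm (~5% of a typical
converged gradient) — fine enough that detection reflects convergence
rather than the first full window.

*Vascularized runs* proceed in two stages: stage 1 equilibrates under
constant forcing held at the start-of-day values, declared settled when
both the blood-tissue gradient and the total grid chemokine change by
<1% over 5 min (the gradient criterion alone fires immediately because
the constant blood term dominates it); stage 2 applies the circadian
forcing for 24 h (2 h in the quick desk-scale configuration).  Reported
metrics: endothelial-tissue gradient = (mean shell at 90 µm − mean
lining shell at 10 µm)/80 µm (40 µm far-shell on the desk-scale grid);
blood-tissue gradient = (mean tissue shell at the configured radius −
C_blood)/radius; "maximum gradient over 24 h" is the signed value of
largest magnitude.  Sweeps average over 5 independent placements by
default, with replicate seeds spawned counter-style from the master
seed so each cell of the sweep is order-independent.

## Desk-scale study conditions

The test-suite and the acceptance script run a 100-µm cube (1/8 the
tissue volume) at dt = 0.5 s with volume-scaled cell counts
(25 secreting + 25 tissue scavengers ≈ the 200/200 baseline density)
and endothelial coverage held at 83% of the lining (100 of 120 voxels);
two-cluster runs stay on the 200-µm grid (100-µm cluster separation
does not fit a smaller cube) with dt = 0.5 s and a 2-h cap.  These
sizes keep a full suite run to minutes while preserving the quantities
under test — conservation, oracle agreement, gradient signs and
monotonic trends.  What passing desk-scale tests does *not* establish:
absolute gradient magnitudes at in-vivo scale, isoform differences
beyond the encoded parameter orderings, or any behavior depending on
parameters the supplementary literature values would pin down.

## Known limitations

- ECM binding is non-saturable; at high chemokine loads a site-density
  model would cap B.
- No interstitial flow, cell motility, division, death, or CXCR4
  dynamics; single straight vessel, cubic voxels only.
- The within-step frozen-R_s approximation slightly lags surface-complex
  formation at dt = 0.5 s; at the default dt = 0.1 s the effect is
  negligible.
- With the α-isoform defaults at desk scale, blood delivery dominates
  tissue secretion, so blood-tissue gradients point into the blood
  across all tested compositions (composition still sets the
  magnitude); the replicate-averaged scavenger-insensitivity of the
  two-cluster gradient is marginal (~13–20% change for 25→200
  scavengers) rather than comfortably flat.
- The printed circadian phase term t − (t_start − t_max) is implemented
  verbatim (maximum at clock time t_start − t_max); a "natural"
  convention with the maximum at t_max is a config switch.  The two
  coincide for the default t_start = 0, t_max = 12 with a 24-h period.
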