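# Methods

## Model structure

The simulator couples two layers over a shared global step dt:

1. **Cell dynamics** — center-based mechanics of spherical cells in free 3D
   space (no walls, no substrate). Output: positions, hence each cell's
   local packing fraction ρ.
2. **Intra-cellular dynamics** — a per-cell linear Hippo-YAP/TAZ network
   whose density input ρ shifts YAP/TAZ from the nucleus (X2) to the
   phosphorylated cytoplasmic pool (X3). Output: nuclear YAP/TAZ, which
   gates growth and division.

Each global step applies, in order: (i) growth/arrest discrimination and
growth; (ii) division of every cell at the doubling size, in ascending id
order, daughters not re-checked until the next step; (iii) one mechanics
step; (iv) density refresh, then exact reaction propagation at frozen ρ.
A run starts from two birth-size daughters straddling the origin. With a
fixed (config, seed) pair every output byte is reproducible.

## Parameters, units, defaults

Internal units: µm, s, ng, µM. Defaults live in `presets/normal.yaml` and
`presets/cancer.yaml`; everything below is configurable.

| parameter | default | meaning |
|---|---|---|
| a1, a2 | 5e-2, 5e-4 /s | nuclear import/export of YAP/TAZ (ratio 100: nuclear-biased at low density) |
| a3 | 1e-4 /s | dephosphorylation of P-YAP/TAZ |
| b1, X0 | 1 /(µM·s), 0.15 µM | density-driven phosphorylation; effective rate b1·ρ·X0 |
| X_th | 0.012 µM | nuclear YAP/TAZ arrest threshold |
| X⁰ (normal) | (0.05, 0.2, 0) µM | initial (X1, X2, X3); cancer preset is exactly twofold |
| T_CC, T_M | 20 h, 1 h | cell cycle and mitosis-phase durations |
| dt, L | 3.75 s, 200000 | global step and step count (≈ 208 h ≈ 10.4 cycles) |
| σ0′, m0 | 5 µm, 2 ng | birth radius and (constant) cell mass |
| α_LJ, λ | 0.5, 0.38054 | soft-core shape; ζ = (2 − α_LJ(1−λ)²)^(1/6) = 5/4.53 so σ0 = 4.53 µm |
| ε | 1.2662e-5 ng·µm²/s² | adhesion strength, calibrated (below) |
| μ | 1/30 ng/s | Stokes drag; m0/μ = 60 s, strongly damped vs T_M |
| r_cut | 2.5 × ζσ_ij | pair cutoff, energy-shifted to continuity |
| δ_ρ | 0.25 | packing-kernel decay width (in contact-normalised distance) |

Mass is constant over the cycle (a single m0 is specified); growth changes
geometry only.

### Calibrated adhesion strength

The well depth ε is fixed by a mechanical criterion rather than chosen
freely: it is the smallest value for which two cells released at 0.9× their
equilibrium separation settle permanently within 1% of equilibrium in at
most one mitosis phase (1 h) under the default friction — i.e. the
relaxation scale of a freshly divided pair is tied to the time the daughters
have to separate. Bisection (`hipposim calibrate-epsilon`) gives
1.266e-5 ng·µm²/s²; the settle time decreases monotonically with ε in the
overdamped regime, so the boundary is unique.

## Numerical choices

- **Reaction propagation** is exact per step: the rate matrix A(ρ) has
  columns summing to zero (mass conservation) and non-negative off-diagonal
  entries (Metzler), so `exp(A dt)` is a stochastic-like matrix preserving
  the total and non-negativity. It is computed by eigendecomposition with a
  scaling-and-squaring fallback when the eigenvector condition number
  exceeds 1e8; tiny negative round-off is clipped at zero. Propagators are
  cached on a ρ-grid (spacing 1e-3 in ρ), which bounds the per-step cost at
  one small gather plus a batched 3×3 product; setting
  `cache_propagators: false` propagates each cell at its exact ρ.
- **Frozen-density step**: ρ is refreshed once per global step after
  mechanics and held constant through the reaction update, making the
  per-step propagation exactly linear.
- **Verlet with semi-implicit friction**: the drag force enters at the
  half-step velocity, `v½ = (v + hF)/(1 + hμ)`, `v′ = v½(1 − hμ) + hF′`,
  which is exactly time-reversible at μ = 0 (energy drift ≤ 1e-4 over 1e4
  substeps in the bound-pair test) and second-order accurate in the damped
  limit. A substep that would displace any cell by more than half the
  smallest cell diameter aborts with a diagnostic; the simulator then
  retries the step with doubled substep count (up to 1024).
- **Division threshold slack**: a cell divides when σ ≥ 2^(1/3)σ0·(1 − 1e-9).
  The slack absorbs float accumulation over the ~19200 equal increments of a
  cycle (observed deficit ~1e-11 relative, three orders below the slack;
  one increment is ~1e-5 relative, four orders above it), so an
  uninterrupted cell divides on exactly step T_CC/dt.
- **Tie-break**: X2 exactly equal to X_th classifies as arrest (growth
  requires strictly larger); measure-zero, fixed for determinism.
- **Division directions** follow the stated sampling — azimuth uniform on
  [0, 2π), polar angle uniform on [0, π) — which is not area-uniform on the
  sphere (poles are oversampled); `sphere_uniform: true` switches to
  cos φ-uniform sampling for sensitivity checks.
- **Neighbour search**: exact O(N²) vectorised summation up to N = 200
  (retained as the oracle), cell-linked lists with bin size ≥ the largest
  pair cutoff beyond.
- **Degenerate geometry**: coincident centers get zero pair force (direction
  undefined; the soft core keeps the energy finite) with a logged warning,
  and a finite packing-kernel contribution exp(1/δ_ρ)/12.

## Packing fraction

The density signal is ρ_i = (1/12) Σ_{j≠i} exp(−(s_ij − 1)/δ_ρ) with
s_ij = |r_i − r_j| / (radius_i + radius_j), truncated at the mechanical
cutoff (s = 2.5). The 1/12 normalisation makes twelve neighbours exactly at
contact — the close-packing coordination number — give ρ = 1, so ρ ≈ 1
means "tightly packed". This kernel is a declared construction: it is
size-normalised, smooth, strictly decreasing in every neighbour distance,
and exercised over the 0–1.5 range by the steady-state analysis, but other
normalisations are conceivable; δ_ρ and the cutoff are config keys.

## Analytic reductions used as oracles

At fixed ρ the network's steady state is closed-form:
X1* = total/(1 + a1/a2 + b1ρX0/a3), X2* = (a1/a2)X1*, X3* = (b1ρX0/a3)X1*.
Inverting X2* = X_th gives the critical density ρ* above which a held
density arrests the cell: ρ* ≈ 1.3216 for the normal total (0.25 µM) and
≈ 2.7104 for the cancer total (0.5 µM) — the twofold YAP/TAZ excess roughly
doubles the crowding needed for arrest. With the density coupling removed
(b1 = 0), X2 can never fall below threshold and the population obeys
N(t) = 2^(1 + ⌊t/T_CC⌋) exactly; both closed forms are asserted against the
full simulator in the test suite, and propagation is checked against an
independent adaptive Runge-Kutta integration to 1e-9.

## Problem sizes and what the tests show

The package's own test and reproduction runs use a reduced horizon of five
cell cycles (96 000 steps, populations up to 64 cells, minutes per run) as
the standard qualitative setting: at matched times the normal tissue's
arrested-cell fraction is at least the cancer tissue's (majority vote over
five seeds), the normal cell count never exceeds the cancer one, and the
cancer/normal mean nuclear YAP/TAZ ratio stays at ≈ 2 throughout. Full-scale
runs (L = 200 000, ~10³ cells) reproduce the regime in which the normal
tissue's minimum X2 crosses the arrest threshold near 100 h while the
twofold-YAP/TAZ tissue holds out to ~200 h; they take hours on one CPU and
are launched explicitly via `hipposim run`, never by the test suite.

## Known limitations

- At small populations the packing kernel reports interior ρ well above the
  0–1.5 range typical of large tissues (freshly divided daughters start
  deeply overlapped at 0.26× the pair equilibrium distance, and a newborn
  pair alone contributes ρ ≈ 1.6 to each other), so arrest at the reduced
  horizon is intermittent and division-synchronised rather than a clean
  core/rim pattern; the qualitative normal-vs-cancer ordering is unaffected.
- No cell death, no S/G2 phases (the cycle is M + G1), no thermal noise, no
  substrate or boundary, spheres only, constant mass.
- The synthetic tissue starts from exactly two synchronised cells; real
  tissues are asynchronous, so early-time population curves are stepped
  rather than smooth.
- The division-direction sampling is deliberately not area-uniform (see
  above) to match the stated model; enable `sphere_uniform` to probe the
  difference.
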