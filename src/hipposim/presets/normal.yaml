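# Normal-tissue preset: baseline YAP/TAZ levels, contact inhibition expected.
# Units: um, s, ng, uM; cycle durations in hours.
preset: normal
initial_concentrations: [0.05, 0.2, 0.0]
reaction:
  a1: 0.05          # YAP/TAZ cytoplasm -> nucleus (1/s)
  a2: 0.0005        # YAP/TAZ nucleus -> cytoplasm (1/s)
  a3: 0.0001        # P-YAP/TAZ -> cytoplasmic YAP/TAZ (1/s)
  b1: 1.0           # phosphorylation, effective rate b1*rho*X0 (1/(uM*s))
  X0: 0.15          # density input signal at packing fraction 1 (uM)
  X_th: 0.012       # nuclear YAP/TAZ arrest threshold (uM)
mechanics:
  sigma0_prime: 5.0         # birth cell radius (um)
  m0: 2.0                   # cell mass (ng)
  alpha_LJ: 0.5             # soft-core parameter
  lambda_sc: 0.38054029643567144   # coupling; gives zeta = 5/4.53
  epsilon: 1.266175794865112e-05   # calibrated: two-cell settle <= T_M (see docs)
  mu_fric: 0.03333333333333333     # friction (ng/s); m0/mu = 60 s
  r_cut_factor: 2.5         # pair cutoff / pair equilibrium distance
  dt: 3.75                  # global step (s)
  n_sub: 1                  # mechanical substeps per step
cycle:
  T_CC_h: 20.0
  T_M_h: 1.0
simulation:
  L: 200000                 # 200000 * 3.75 s ~ 208 h ~ 10.4 cycles
  seed: 0
  snapshot_every: 160       # 10 simulated minutes
  delta_rho: 0.25           # packing-fraction kernel width
  rho_quantum: 0.001
  cache_propagators: true
  sphere_uniform: false
  max_cells: null
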