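# Cancer-tissue preset: twofold YAP/TAZ relative to normal tissue; evades
# contact inhibition.  Only the initial concentrations differ from normal.
preset: cancer
initial_concentrations: [0.1, 0.4, 0.0]
reaction:
  a1: 0.05
  a2: 0.0005
  a3: 0.0001
  b1: 1.0
  X0: 0.15
  X_th: 0.012
mechanics:
  sigma0_prime: 5.0
  m0: 2.0
  alpha_LJ: 0.5
  lambda_sc: 0.38054029643567144
  epsilon: 1.266175794865112e-05
  mu_fric: 0.03333333333333333
  r_cut_factor: 2.5
  dt: 3.75
  n_sub: 1
cycle:
  T_CC_h: 20.0
  T_M_h: 1.0
simulation:
  L: 200000
  seed: 0
  snapshot_every: 160
  delta_rho: 0.25
  rho_quantum: 0.001
  cache_propagators: true
  sphere_uniform: false
  max_cells: null
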