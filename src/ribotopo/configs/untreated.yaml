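# Untreated (control) condition field.
#
# The global state vector reproduces the printed control composition:
# 81.7% elongation-cycle states and 15.4% idle; the remaining 2.9% is
# carried by dissociated-subunit labels so the vector sums to 1 (the
# subunit percentages are quoted against a different denominator in the
# source data; see docs/methods.md).  Elongation mass is split with
# decoding predominant and POST low-abundance.
#
# Motif mixture: polysome lattices dominate before treatment; the two
# LSU-mediated hibernating dimers (disome2/3) are rare; stalled-collided
# dimers sit at 1.2% of all particles in both conditions.
condition: untreated
n_particles: 5000
n_tomograms: 1
box: [18000.0, 18000.0, 2500.0]
d_min: 200.0
sigma_t: 15.0
sigma_theta: 5.0
chain_length: [4, 9]
patch_shape: [3, 3]
seed: 0
motif_weights:
  cyto_helical: 0.25
  membrane_planar: 0.18
  disome1: 0.06
  disome2: 0.02
  disome3: 0.01
  collided: 0.012
state_composition:
  global:
    decoding: 0.450
    classical_PRE: 0.180
    rotated_PRE: 0.120
    POST: 0.067
    idle: 0.154
    subunit_SSU: 0.0145
    subunit_LSU: 0.0145
  motif_overrides:
    # translating polysome lattices: almost entirely elongation-cycle
    cyto_helical: {decoding: 0.52, classical_PRE: 0.21, rotated_PRE: 0.14, POST: 0.08, idle: 0.05}
    membrane_planar: {decoding: 0.52, classical_PRE: 0.21, rotated_PRE: 0.14, POST: 0.08, idle: 0.05}
    disome1: {decoding: 0.52, classical_PRE: 0.21, rotated_PRE: 0.14, POST: 0.08, idle: 0.05}
    # hibernating dimers are exclusively idle
    disome2: {idle: 1.0}
    disome3: {idle: 1.0}
    # stalled-collided ribosomes sit in the hybrid (rotated PRE) state
    collided: {rotated_PRE: 1.0}
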