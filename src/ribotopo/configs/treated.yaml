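# Puromycin-treated condition field (also the default mixed-motif field).
#
# Global state vector: elongation collapses to 31.7% (same internal split
# as untreated) and idle rises to 64.8% — an approximately four-fold
# increase; the residual 3.5% is carried by dissociated-subunit labels
# (see docs/methods.md for the denominator note).
#
# Motif mixture: the five topology classes cover 56% of all particles
# (helical 20%, planar 15%, disome1 9%, disome2 8%, disome3 4%), the two
# LSU-mediated hibernating dimers together 12%; stalled-collided dimers
# stay at 1.2%.
condition: treated
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
  cyto_helical: 0.20
  membrane_planar: 0.15
  disome1: 0.09
  disome2: 0.08
  disome3: 0.04
  collided: 0.012
state_composition:
  global:
    decoding: 0.17460
    classical_PRE: 0.06984
    rotated_PRE: 0.04656
    POST: 0.02600
    idle: 0.648
    subunit_SSU: 0.0175
    subunit_LSU: 0.0175
  motif_overrides:
    # surviving polysome lattices carry a large idle fraction after treatment
    cyto_helical: {decoding: 0.35, classical_PRE: 0.14, rotated_PRE: 0.06, POST: 0.05, idle: 0.40}
    membrane_planar: {decoding: 0.35, classical_PRE: 0.14, rotated_PRE: 0.06, POST: 0.05, idle: 0.40}
    disome1: {decoding: 0.35, classical_PRE: 0.14, rotated_PRE: 0.06, POST: 0.05, idle: 0.40}
    disome2: {idle: 1.0}
    disome3: {idle: 1.0}
    collided: {rotated_PRE: 1.0}
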