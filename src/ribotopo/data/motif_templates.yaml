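# Reference inter-ribosome transforms for the packaged topology motifs.
#
# Each transform places a neighboring ribosome in the source particle's own
# frame: `translation` in Angstrom, `rotation` as axis (normalized at load)
# plus angle in degrees.  These numeric transforms are synthetic stand-ins
# designed to reproduce the qualitative geometry of the motif classes
# (extendable helical/planar polysome lattices; three dimer interfaces, one
# of them exactly C2; a tight stalled-collided contact).  They are design
# choices of this package, not measured values.
#
# Design constraints (verified by the test suite):
#   - pairwise symmetrized transform distances >= 6.5 metric units at the
#     default scales (sigma_t=25 A, sigma_theta=10 deg): no two motifs can
#     merge under DBSCAN at eps=3;
#   - disome2 satisfies T = T^-1 exactly (C2 homodimer); disome1/disome3
#     do not (asymmetric interfaces);
#   - composing a dimer transform with itself produces a steric clash
#     (terminal), while the helix/plane generators extend without clashes;
#   - every dimer partner lies within 60 deg of the +x axis of the source
#     particle, the direction used as the mRNA-exit-side proxy.
version: 1
metric:
  sigma_t: 25.0        # Angstrom
  sigma_theta: 10.0    # degrees
templates:
  cyto_helical:        # helical (cytosolic) polysome: screw generator
    translation: [245.0, 50.0, 55.0]
    rotation: {axis: [0.0, 0.0, 1.0], angle_deg: 70.0}
    tol_t: 50.0
    tol_theta: 20.0
    symmetry: none
    extendable: helical
    priority: 1
  membrane_planar:     # membrane-bound polysome patch: two in-plane generators
    translation: [260.0, 0.0, 0.0]
    rotation: {axis: [0.0, 0.0, 1.0], angle_deg: 0.0}
    second_generator:
      translation: [0.0, 270.0, 0.0]
      rotation: {axis: [0.0, 0.0, 1.0], angle_deg: 0.0}
    tol_t: 50.0
    tol_theta: 20.0
    symmetry: none
    extendable: planar
    priority: 2
  disome1:             # SSU-body-mediated dimer (asymmetric)
    translation: [255.0, -60.0, 0.0]
    rotation: {axis: [0.229, 0.973, 0.0], angle_deg: 150.0}
    tol_t: 50.0
    tol_theta: 20.0
    symmetry: none
    extendable: terminal
    priority: 3
  disome2:             # LSU dimer via reciprocal ES31b kissing loops, exact C2
    translation: [255.0, 60.0, 0.0]
    rotation: {axis: [0.0, 0.0, 1.0], angle_deg: 180.0}
    tol_t: 50.0
    tol_theta: 20.0
    symmetry: C2
    extendable: terminal
    priority: 5
  disome3:             # asymmetric LSU dimer via ES20a-ES30a, sterically capped
    translation: [180.0, -140.0, 60.0]
    rotation: {axis: [-0.613941, -0.789353, 0.0], angle_deg: 160.0}
    tol_t: 50.0
    tol_theta: 20.0
    symmetry: none
    extendable: terminal
    priority: 4
  collided:            # stalled-collided dimer: tight entry-to-exit contact
    translation: [225.0, 30.0, -20.0]
    rotation: {axis: [0.0, 1.0, 0.0], angle_deg: 90.0}
    tol_t: 50.0
    tol_theta: 20.0
    symmetry: none
    extendable: terminal
    priority: 6
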