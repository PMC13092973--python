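# ribotopo

Neighbor-topology analysis of in-situ ribosome ensembles.

In cellular cryo-electron tomography, subtomogram averaging yields a
position and orientation for every ribosome in the cell — a *particle
field*.  The spatial relationships between neighboring ribosomes encode
biology that single-particle maps cannot: helical cytosolic polysomes,
planar membrane-bound polysome patches, stalled-collided disomes on one
mRNA, and translationally idle ribosome dimers held together by rRNA
expansion-segment contacts.  `ribotopo` is a toolkit for recovering and
quantifying that organisation, aimed at structural biologists who have
per-particle pose tables (STAR dialect) and want the downstream
statistics, and at methods developers who need a fully synthetic,
ground-truthed test bed for neighbor-topology pipelines.

The package has four layers:

1. **Field simulator** — generates particle fields with planted
   superstructure motifs (helices, planar patches, three dimer types, rare
   collided dimers, free monomers), condition-dependent translation-state
   labels, Gaussian pose noise, and hard-core excluded volume.  Every
   planted particle carries its ground-truth motif, so recovery is exactly
   measurable.
2. **Neighbor topology** — for each neighbor pair (i, j) within a cutoff,
   the relative rigid transform in particle *i*'s frame:

       t_rel = R_i^T (x_j − x_i),      q_rel = q_i^{-1} q_j

   Transforms are clustered with DBSCAN under a scaled, symmetrized metric

       d(T1, T2) = min over T2, T2^{-1} of
                   sqrt( |t1 − t2|² / σ_t² + ang(q1, q2)² / σ_θ² )

   where `ang` is the geodesic rotation angle `2·arccos(|⟨q1, q2⟩|)`.
   Cluster medoids are matched against a template library; each cluster is
   tested for pseudo-C2 symmetry (T ≈ T⁻¹, the signature of a reciprocal
   homodimer interface) and for extendability (does composing T with
   itself build a clash-free helix or lattice, or fold back sterically?).
   Stalled-collided dimers are re-detected at pair level under a strict
   threshold.
3. **State composition** — translation-state proportions stratified by
   topology class and condition, treated/untreated fold-changes,
   Kolmogorov–Smirnov comparison of nearest-neighbor distance
   distributions, and per-state mRNA entry/exit neighbor occupancy.
4. **RNA kissing loops** — base-pair-maximization folding (Nussinov DP,
   Watson–Crick + GU, minimum loop 3) of expansion-segment sequences,
   extraction of the terminal stem-loop, and antiparallel loop–loop
   complementarity scoring.  A terminal loop that scores highly against
   *itself* can form the reciprocal kissing contact of a C2 ribosome
   homodimer.

## Worked example

The packaged condition configs (`untreated`, `treated`) encode the study
conditions: the treated field plants the five topology classes over 56%
of 5000 particles (helical 20%, planar 15%, disome1 9%, disome2 8%,
disome3 4%), collided dimers at 1.2%, and an idle-state share of 64.8%
versus 15.4% untreated.  The numbered scripts run the whole analysis:

```sh
python analysis/01_simulate_fields.py --seed 1
python analysis/02_topology_classes.py
python analysis/03_state_composition.py
python analysis/04_es_kissing_scan.py
```

`02_topology_classes.py` prints, for the treated field:

```
[treated] 12 transform clusters, 56.2% of particles in the five classes, 1.16% stalled-collided
    cluster  0: cyto_helical       852 pairs  C2=False helical
    cluster  5: membrane_planar    799 pairs  C2=False planar
    cluster  8: disome1            228 pairs  C2=False terminal
    cluster  9: disome2            200 pairs  C2=True  terminal
    cluster 10: disome3            100 pairs  C2=False terminal
    cluster 11: collided            30 pairs  C2=False terminal
```

i.e. the clustering recovers the planted 56% coverage, identifies
disome2 — and only disome2 — as pseudo-C2, marks the polysome generators
as extendable (helical/planar) and all dimers as sterically terminal, and
finds the rare collided dimers at their planted 1.2% abundance.
`03_state_composition.py` then reports

```
[untreated] elongation-cycle 81.2%  idle 15.9%
[treated] elongation-cycle 31.7%  idle 65.0%
idle fold-change treated/untreated: 4.08
```

— the planted collapse of active elongation (81.7% → 31.7%) and the
roughly four-fold idle increase, recovered within sampling error.
`04_es_kissing_scan.py` scans a clearly-synthetic expansion-segment panel
and flags exactly the records whose terminal loop is self-complementary
(kissing-capable, C2-homodimer geometry).

The same stages are available as a CLI (`ribotopo simulate / topology /
compose / rna-scan / run`) and as library functions
(`simulate_field`, `analyze_topology`, `composition_by_topology`,
`fold_hairpin`, `kissing_score`, ...).

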