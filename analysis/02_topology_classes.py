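#!/usr/bin/env python
"""Cluster neighbor transforms and classify topology classes.

Reads the fields written by 01_simulate_fields.py, computes relative
rigid transforms between all neighbor pairs (<= 400 A center-to-center),
clusters them with DBSCAN in the symmetrized transform metric, matches
cluster medoids against the motif template library, and reports: the
five topology classes with their per-condition abundances, C2-symmetry
and extendability verdicts, and the stalled-collided dimer fraction
detected under the strict threshold.

Usage: python analysis/02_topology_classes.py
"""

import json
from pathlib import Path

from ribotopo import load_template_library, read_star
from ribotopo.topology import analyze_topology

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    templates = load_template_library()
    summary = {}
    for name in ("untreated", "treated"):
        field = read_star(RESULTS / f"particles_{name}.star")
        res = analyze_topology(field, templates)
        cls = res.classification
        print(f"[{name}] {len(cls.clusters)} transform clusters, "
              f"{100 * cls.classified_fraction:.1f}% of particles in the five classes, "
              f"{100 * res.collided_fraction:.2f}% stalled-collided")
        for c in sorted(cls.clusters, key=lambda c: -c.n_pairs):
            print(f"    cluster {c.cluster_id:2d}: {c.assigned_class:16s} "
                  f"{c.n_pairs:5d} pairs  C2={str(c.is_c2):5s} {c.extendability}")
        tsv = field.df[["particle_id", "condition", "state_label"]].copy()
        tsv["topology_class"] = cls.particle_class.to_numpy()
        tsv.to_csv(RESULTS / f"assignments_{name}.tsv", sep="\t", index=False)
        summary[name] = {
            "classified_percent": round(100 * cls.classified_fraction, 1),
            "collided_percent": round(100 * res.collided_fraction, 2),
            "class_abundance_percent": {
                row["topology_class"]: round(100 * row["fraction"], 1)
                for _, row in cls.abundance.iterrows()
            },
        }
    (RESULTS / "topology_summary.json").write_text(json.dumps(summary, indent=1) + "\n")
    print(f"wrote {RESULTS / 'topology_summary.json'}")


if __name__ == "__main__":
    main()
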