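#!/usr/bin/env python
"""Translation-state composition by topology and condition.

Reads the fields and assignments from the previous scripts and computes:
the state-composition table stratified by topology class, the
treated/untreated fold-changes per state (the idle ratio is the headline
number), the nearest-neighbor distance comparison between conditions
(Kolmogorov-Smirnov), and per-state mRNA entry/exit neighbor occupancy.

Usage: python analysis/03_state_composition.py
"""

import json
from pathlib import Path

import pandas as pd

from ribotopo import read_star
from ribotopo.composition import (
    composition_by_topology,
    condition_delta,
    neighbor_occupancy,
    nn_distance_compare,
)
from ribotopo.field import ELONGATING_STATES, ParticleField

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    fields = {n: read_star(RESULTS / f"particles_{n}.star") for n in ("untreated", "treated")}
    assigns = {
        n: pd.read_csv(RESULTS / f"assignments_{n}.tsv", sep="\t")["topology_class"]
        for n in fields
    }
    merged = ParticleField(
        pd.concat([f.df for f in fields.values()], ignore_index=True), validate=False
    )
    merged_assign = pd.concat(list(assigns.values()), ignore_index=True)
    table = composition_by_topology(merged, merged_assign)
    table.to_csv(RESULTS / "composition_by_topology.tsv", sep="\t")

    for cond in ("untreated", "treated"):
        row = table.loc[(cond, "all")]
        elong = 100 * sum(row[s] for s in ELONGATING_STATES)
        print(f"[{cond}] elongation-cycle {elong:.1f}%  idle {100 * row['idle']:.1f}%")

    delta = condition_delta(table)
    delta.to_csv(RESULTS / "condition_delta.tsv", sep="\t")
    print(f"idle fold-change treated/untreated: {delta.loc['idle', 'ratio']:.2f}")

    nn = nn_distance_compare(fields["untreated"], fields["treated"])
    print(f"NN distance KS: D={nn.statistic:.3f}, p={nn.pvalue:.3g} "
          f"(medians {nn.distances_a.mean():.0f} / {nn.distances_b.mean():.0f} A)")
    (RESULTS / "nn_comparison.json").write_text(json.dumps(nn.to_dict(), indent=1) + "\n")

    occ_frames = []
    for cond, f in fields.items():
        occ = neighbor_occupancy(f)
        occ.insert(0, "condition", cond)
        occ_frames.append(occ)
        both_elong = occ.loc[occ.index.isin(ELONGATING_STATES), "both"].mean()
        idle_single_or_none = (
            occ.loc["idle", ["entry_only", "exit_only", "neither"]].sum()
            if "idle" in occ.index else float("nan")
        )
        print(f"[{cond}] elongating states both-sides {100 * both_elong:.0f}%; "
              f"idle single-or-no neighbor {100 * idle_single_or_none:.0f}%")
    pd.concat(occ_frames).to_csv(RESULTS / "neighbor_occupancy.tsv", sep="\t")


if __name__ == "__main__":
    main()
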