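"""Translation-state composition, condition deltas, NN distances, occupancy.

Reproduces the statistical layer of the topology analysis: state
proportions overall and within topology classes, treated/untreated
fold-changes, the nearest-neighbor distance comparison between
conditions, and per-state mRNA entry/exit-side neighbor occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import ks_2samp

from .field import STATES, ParticleField

ALL_ROW = "all"


def composition_by_topology(
    field: ParticleField, assignments: pd.Series | None = None
) -> pd.DataFrame:
    """Exact state-frequency table stratified by topology class.

    Rows are keyed by ``(condition, topology_class)`` with an ``all`` row
    per condition; columns are the state proportions plus ``n``.  The
    ``all`` row equals the class rows mixed with weights ``n`` (conserved
    totals), which the tests assert.
    """
    df = field.df
    unknown = set(df["state_label"]) - set(STATES)
    if unknown:
        raise ValueError(f"unknown state labels: {sorted(unknown)}")
    if assignments is None:
        assignments = pd.Series("unclassified", index=df.index)
    work = pd.DataFrame(
        {
            "condition": df["condition"].to_numpy(),
            "topology_class": assignments.to_numpy(),
            "state": df["state_label"].to_numpy(),
        }
    )
    rows = []
    for condition, cond_df in work.groupby("condition", sort=True):
        groups = [(ALL_ROW, cond_df)]
        groups += [(cls, sub) for cls, sub in cond_df.groupby("topology_class", sort=True)]
        for cls, sub in groups:
            counts = sub["state"].value_counts()
            n = len(sub)
            row = {"condition": condition, "topology_class": cls, "n": n}
            for s in STATES:
                row[s] = counts.get(s, 0) / n if n else 0.0
            rows.append(row)
    table = pd.DataFrame(rows).set_index(["condition", "topology_class"])
    return table


def condition_delta(table: pd.DataFrame) -> pd.DataFrame:
    """Treated/untreated ratio and absolute difference per state.

    Works on the ``all`` rows of a composition table containing both
    conditions.  A zero untreated proportion makes the ratio undefined
    (reported as NaN with ``undefined=True``), never infinite.
    """
    try:
        untreated = table.loc[("untreated", ALL_ROW)]
        treated = table.loc[("treated", ALL_ROW)]
    except KeyError as e:
        raise ValueError(f"composition table lacks a condition: {e}") from None
    rows = []
    for s in STATES:
        u, t = float(untreated[s]), float(treated[s])
        undefined = u == 0.0
        rows.append(
            {
                "state": s,
                "untreated": u,
                "treated": t,
                "ratio": np.nan if undefined else t / u,
                "difference": t - u,
                "undefined": undefined,
            }
        )
    return pd.DataFrame(rows).set_index("state")


def nn_distances(field: ParticleField) -> np.ndarray:
    """Per-particle nearest-neighbor center distance (within tomograms)."""
    if len(field) < 2:
        raise ValueError("need at least 2 particles for nearest-neighbor distances")
    pos = field.positions
    tomo = field.df["tomogram_id"].to_numpy()
    out = np.empty(len(field))
    for t_id in np.unique(tomo):
        idx = np.where(tomo == t_id)[0]
        if len(idx) < 2:
            raise ValueError(f"tomogram {t_id} has fewer than 2 particles")
        tree = cKDTree(pos[idx])
        d, _ = tree.query(pos[idx], k=2)
        out[idx] = d[:, 1]
    return out


@dataclass
class NNComparison:
    """Two-sample comparison of nearest-neighbor distance distributions."""

    distances_a: np.ndarray
    distances_b: np.ndarray
    statistic: float  # two-sample Kolmogorov-Smirnov D
    pvalue: float
    bin_edges: np.ndarray
    hist_a: np.ndarray  # density histograms on common bins
    hist_b: np.ndarray

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "n_a": int(len(self.distances_a)),
            "n_b": int(len(self.distances_b)),
            "median_a": float(np.median(self.distances_a)),
            "median_b": float(np.median(self.distances_b)),
            "bin_edges": self.bin_edges.tolist(),
            "hist_a": self.hist_a.tolist(),
            "hist_b": self.hist_b.tolist(),
        }


def nn_distance_compare(field_a: ParticleField, field_b: ParticleField, bins: int = 40) -> NNComparison:
    """Kolmogorov-Smirnov comparison of NN-distance distributions."""
    da = nn_distances(field_a)
    db = nn_distances(field_b)
    res = ks_2samp(da, db, method="asymp")
    lo = min(da.min(), db.min())
    hi = max(da.max(), db.max())
    edges = np.linspace(lo, hi, bins + 1)
    ha, _ = np.histogram(da, bins=edges, density=True)
    hb, _ = np.histogram(db, bins=edges, density=True)
    return NNComparison(
        distances_a=da,
        distances_b=db,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        bin_edges=edges,
        hist_a=ha,
        hist_b=hb,
    )


def neighbor_occupancy(
    field: ParticleField,
    entry_dir=(1.0, 0.0, 0.0),
    exit_dir=(-1.0, 0.0, 0.0),
    cone_deg: float = 60.0,
    max_dist: float = 400.0,
) -> pd.DataFrame:
    """Per-state mRNA entry/exit-side neighbor occupancy.

    A side is occupied when some neighbor lies within ``max_dist`` and
    within ``cone_deg`` of that side's direction *in the particle's own
    frame*.  Directions must be unit vectors; defaults are +/-x, matching
    the frame in which the packaged motif templates place partners.
    Returns per-state fractions of particles with entry-only, exit-only,
    both, or neither side occupied (rows sum to 1).
    """
    entry = np.asarray(entry_dir, dtype=float)
    exit_ = np.asarray(exit_dir, dtype=float)
    for v in (entry, exit_):
        if abs(np.linalg.norm(v) - 1.0) > 1e-6:
            raise ValueError("entry/exit directions must be unit vectors")
    cos_cone = np.cos(np.deg2rad(cone_deg))
    pos = field.positions
    rots = field.rotations
    tomo = field.df["tomogram_id"].to_numpy()
    n = len(field)
    has_entry = np.zeros(n, dtype=bool)
    has_exit = np.zeros(n, dtype=bool)
    for t_id in np.unique(tomo):
        idx = np.where(tomo == t_id)[0]
        tree = cKDTree(pos[idx])
        neighbor_lists = tree.query_ball_point(pos[idx], r=max_dist)
        for local_i, neigh in enumerate(neighbor_lists):
            i = idx[local_i]
            others = [idx[j] for j in neigh if j != local_i]
            if not others:
                continue
            d = pos[others] - pos[i]
            local = rots[i].inv().apply(d)
            local /= np.linalg.norm(local, axis=1, keepdims=True)
            if (local @ entry >= cos_cone).any():
                has_entry[i] = True
            if (local @ exit_ >= cos_cone).any():
                has_exit[i] = True
    states = field.df["state_label"].to_numpy()
    rows = []
    for s in STATES:
        sel = states == s
        n_s = int(sel.sum())
        if n_s == 0:
            continue
        both = float((has_entry & has_exit & sel).sum() / n_s)
        entry_only = float((has_entry & ~has_exit & sel).sum() / n_s)
        exit_only = float((~has_entry & has_exit & sel).sum() / n_s)
        neither = float((~has_entry & ~has_exit & sel).sum() / n_s)
        rows.append(
            {
                "state": s,
                "n": n_s,
                "entry_only": entry_only,
                "exit_only": exit_only,
                "both": both,
                "neither": neither,
            }
        )
    return pd.DataFrame(rows).set_index("state")
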