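"""Neighbor-topology analysis: transform clustering and classification.

The pipeline is: find neighboring particle pairs within a center-to-center
cutoff (both orderings of each physical pair are kept); express each
neighbor as a rigid transform in the source particle's frame; cluster the
transforms with DBSCAN under a symmetrized scaled metric (so the two
orderings — and the two halves of a C2 dimer — co-cluster); summarize each
cluster by its medoid (averaging rotations near C2 orbits is ill-defined,
a medoid is not); match medoids against the packaged motif templates; and
propagate classes to particles, resolving multi-class particles by
template priority (specific dimer interfaces outrank extendable lattices,
so a capped dimer is never absorbed into a helix).  Stalled-collided
dimers are re-detected at pair level under a strict threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN
from sklearn.neighbors import sort_graph_by_row_values

from .field import ParticleField
from .geometry import (
    compose_transform,
    geodesic_angle_deg,
    invert_transforms,
    pair_transforms,
    symmetrized_cross_distances,
    transform_distance,
)
from .templates import FIVE_CLASSES, MotifTemplate

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"

# defaults, exposed through every public signature
DEFAULT_CUTOFF = 400.0  # Angstrom, neighbor center-to-center
DEFAULT_SIGMA_T = 25.0  # Angstrom, metric translation scale
DEFAULT_SIGMA_THETA = 10.0  # degrees, metric rotation scale
DEFAULT_EPS = 3.0  # DBSCAN radius in metric units
DEFAULT_MIN_SAMPLES = 10
DEFAULT_STRICT_FRACTION = 0.75  # strict collided threshold, fraction of eps
MEDOID_CAP = 1500  # medoid computed on at most this many members


class PairSet(NamedTuple):
    """Ordered neighbor pairs and their relative transforms."""

    src: np.ndarray  # (m,) source particle row index
    dst: np.ndarray  # (m,) target particle row index
    t: np.ndarray  # (m, 3) Angstrom
    q: np.ndarray  # (m, 4) scalar-first unit quaternions

    @property
    def center_distance(self) -> np.ndarray:
        return np.linalg.norm(self.t, axis=1)


def find_neighbors(field: ParticleField, cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """All ordered pairs with center distance <= cutoff, per tomogram.

    Returns an (m, 2) int array; both (i, j) and (j, i) are present.
    Uses a k-d tree; tests validate against the all-pairs scan.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    pos = field.positions
    tomo = field.df["tomogram_id"].to_numpy()
    out = []
    for t_id in np.unique(tomo):
        idx = np.where(tomo == t_id)[0]
        tree = cKDTree(pos[idx])
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if len(pairs):
            ij = idx[pairs]
            out.append(ij)
            out.append(ij[:, ::-1])
    if not out:
        return np.empty((0, 2), dtype=int)
    pairs = np.concatenate(out, axis=0)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[order]


def neighbor_transforms(field: ParticleField, pairs: np.ndarray) -> PairSet:
    """Relative transforms for an (m, 2) array of ordered pairs."""
    if len(pairs) == 0:
        return PairSet(
            np.empty(0, dtype=int),
            np.empty(0, dtype=int),
            np.empty((0, 3)),
            np.empty((0, 4)),
        )
    t, q = pair_transforms(field.positions, field.rotations, pairs[:, 0], pairs[:, 1])
    return PairSet(pairs[:, 0].copy(), pairs[:, 1].copy(), t, q)


@dataclass
class TopologyCluster:
    """A discovered transform class."""

    cluster_id: int
    medoid_t: np.ndarray
    medoid_q: np.ndarray
    members: np.ndarray  # sample indices into the PairSet
    n_pairs: int  # unique physical (unordered) pairs
    assigned_class: str = UNCLASSIFIED
    is_c2: bool = False
    extendability: str = "terminal"
    match_distance: float = float("nan")
    abundance: dict = dc_field(default_factory=dict)  # condition -> fraction of particles


def _radius_graph(
    pairs: PairSet, eps: float, sigma_t: float, sigma_theta: float, block: int = 1024
) -> sparse.csr_matrix:
    """Sparse symmetrized-distance graph with entries <= eps (incl. self)."""
    m = len(pairs.src)
    t_inv, q_inv = invert_transforms(pairs.t, pairs.q)
    rows, cols, vals = [], [], []
    for start in range(0, m, block):
        stop = min(start + block, m)
        d = symmetrized_cross_distances(
            pairs.t[start:stop],
            pairs.q[start:stop],
            pairs.t,
            pairs.q,
            t_inv,
            q_inv,
            sigma_t,
            sigma_theta,
        )
        r, c = np.nonzero(d <= eps)
        rows.append(r + start)
        cols.append(c)
        # sklearn drops implicit zeros from sparse graphs; floor the values
        vals.append(np.maximum(d[r, c], 1e-9))
    rows = np.concatenate(rows) if rows else np.empty(0, dtype=int)
    cols = np.concatenate(cols) if cols else np.empty(0, dtype=int)
    vals = np.concatenate(vals) if vals else np.empty(0)
    graph = sparse.csr_matrix((vals, (rows, cols)), shape=(m, m))
    return sort_graph_by_row_values(graph, warn_when_not_sorted=False)


def _medoid(
    pairs: PairSet, members: np.ndarray, sigma_t: float, sigma_theta: float
) -> tuple[np.ndarray, np.ndarray]:
    """Member with minimal summed symmetrized distance to the others."""
    idx = members
    if len(idx) > MEDOID_CAP:
        sub_rng = np.random.default_rng(len(idx))  # deterministic given cluster
        idx = np.sort(sub_rng.choice(idx, size=MEDOID_CAP, replace=False))
    t = pairs.t[idx]
    q = pairs.q[idx]
    t_inv, q_inv = invert_transforms(t, q)
    d = symmetrized_cross_distances(t, q, t, q, t_inv, q_inv, sigma_t, sigma_theta)
    best = idx[np.argmin(d.sum(axis=1))]
    return pairs.t[best].copy(), pairs.q[best].copy()


def cluster_transforms(
    pairs: PairSet,
    eps: float = DEFAULT_EPS,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    sigma_t: float = DEFAULT_SIGMA_T,
    sigma_theta: float = DEFAULT_SIGMA_THETA,
) -> tuple[np.ndarray, list[TopologyCluster]]:
    """Density-based clustering in the symmetrized transform metric.

    Returns per-sample labels (-1 = noise) and the cluster list; noise
    pairs stay unassigned.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    m = len(pairs.src)
    if m == 0:
        return np.empty(0, dtype=int), []
    graph = _radius_graph(pairs, eps, sigma_t, sigma_theta)
    labels = DBSCAN(eps=eps, min_samples=min_samples, metric="precomputed").fit_predict(
        graph
    )
    clusters = []
    for cid in np.unique(labels):
        if cid < 0:
            continue
        members = np.where(labels == cid)[0]
        med_t, med_q = _medoid(pairs, members, sigma_t, sigma_theta)
        keys = {
            (min(a, b), max(a, b)) for a, b in zip(pairs.src[members], pairs.dst[members])
        }
        clusters.append(
            TopologyCluster(
                cluster_id=int(cid),
                medoid_t=med_t,
                medoid_q=med_q,
                members=members,
                n_pairs=len(keys),
            )
        )
    return labels, clusters


def detect_c2(
    medoid_t: np.ndarray,
    medoid_q: np.ndarray,
    tol: float = 3.0,
    sigma_t: float = DEFAULT_SIGMA_T,
    sigma_theta: float = DEFAULT_SIGMA_THETA,
) -> bool:
    """True iff the transform coincides with its own inverse within tol.

    Equivalently (tested): composing the transform with itself returns the
    identity — the two dimer halves are related by a ~180 deg rotation.
    """
    ti, qi = invert_transforms(medoid_t, medoid_q)
    d = transform_distance(
        medoid_t, medoid_q, ti, qi, sigma_t, sigma_theta, symmetrize=False
    )
    return d < tol


def extendability(
    t: np.ndarray,
    q: np.ndarray,
    k_steps: int = 6,
    clash_radius: float = 100.0,
    planar_generator: tuple | None = None,
) -> str:
    """Extendability verdict of a transform: helical, planar, or terminal.

    The transform is composed with itself ``k_steps`` times; if any two of
    the generated centers come within ``2 * clash_radius`` the putative
    oligomer clashes sterically and the motif is terminal (a C2 transform
    returns onto the origin particle at the second step).  Otherwise the
    centers lie on a constant-rise screw (any repeated rigid step does) and
    the motif extends helically.  ``planar`` is reserved for motifs carrying
    an in-plane second generator; both generators and their combination are
    checked for clashes.
    """
    if k_steps < 2:
        raise ValueError("k_steps must be >= 2")
    if planar_generator is not None:
        g2_t = np.asarray(planar_generator[0], dtype=float)
        centers = []
        k_side = max(2, k_steps // 2)
        for a in range(k_side):
            for b in range(k_side):
                centers.append(a * np.asarray(t, dtype=float) + b * g2_t)
        centers = np.array(centers)
        d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        return "terminal" if d.min() < 2 * clash_radius else "planar"

    centers = [np.zeros(3)]
    cur_t, cur_q = np.asarray(t, dtype=float), np.asarray(q, dtype=float)
    step_t, step_q = cur_t.copy(), cur_q.copy()
    centers.append(cur_t.copy())
    for _ in range(k_steps - 1):
        cur_t, cur_q = compose_transform(cur_t, cur_q, step_t, step_q)
        centers.append(cur_t.copy())
    centers = np.array(centers)
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return "terminal" if d.min() < 2 * clash_radius else "helical"


def _match_cluster(
    cluster: TopologyCluster,
    templates: dict[str, MotifTemplate],
    sigma_t: float,
    sigma_theta: float,
) -> tuple[str, float, int, bool]:
    """Nearest template whose (tol_t, tol_theta) the medoid satisfies.

    Returns (name, metric, generator index, inverted) where *inverted*
    records whether the medoid matched the generator's group inverse
    (each physical pair is emitted in both orientations, so a cluster's
    medoid may sit on either).
    """
    best = (UNCLASSIFIED, float("inf"), 0, False)
    for name, tpl in templates.items():
        for g_idx, (gen_t, gen_q) in enumerate(tpl.all_generators()):
            for inverted, (cand_t, cand_q) in (
                (False, (gen_t, gen_q)),
                (True, invert_transforms(gen_t, gen_q)),
            ):
                dt = float(np.linalg.norm(cluster.medoid_t - cand_t))
                dth = float(geodesic_angle_deg(cluster.medoid_q, cand_q))
                if dt <= tpl.tol_t and dth <= tpl.tol_theta:
                    metric = float(np.hypot(dt / sigma_t, dth / sigma_theta))
                    if metric < best[1]:
                        best = (name, metric, g_idx, inverted)
    return best


@dataclass
class Classification:
    """Per-particle class assignment plus cluster and abundance summaries."""

    particle_class: pd.Series  # indexed like field.df, values class names
    clusters: list[TopologyCluster]
    labels: np.ndarray  # per-sample DBSCAN labels
    abundance: pd.DataFrame  # rows (condition, class) -> fraction, n

    @property
    def classified_fraction(self) -> float:
        """Fraction of all particles assigned to the five topology classes."""
        return float(self.particle_class.isin(FIVE_CLASSES).mean())


def classify_particles(
    field: ParticleField,
    pairs: PairSet,
    labels: np.ndarray,
    clusters: list[TopologyCluster],
    templates: dict[str, MotifTemplate],
    sigma_t: float = DEFAULT_SIGMA_T,
    sigma_theta: float = DEFAULT_SIGMA_THETA,
    k_steps: int = 6,
    clash_radius: float = 100.0,
) -> Classification:
    """Match clusters to templates and propagate classes to particles.

    Each cluster gets the nearest template within its tolerances (or stays
    unclassified, and stays visible in the output); each particle inherits
    the highest-priority class among its pairs' clusters.  Abundances are
    per-condition fractions of all particles; each physical pair is
    counted once.
    """
    priorities = {name: tpl.priority for name, tpl in templates.items()}
    for cluster in clusters:
        name, metric, g_idx, inverted = _match_cluster(cluster, templates, sigma_t, sigma_theta)
        cluster.assigned_class = name
        cluster.match_distance = metric
        cluster.is_c2 = detect_c2(
            cluster.medoid_t, cluster.medoid_q, sigma_t=sigma_t, sigma_theta=sigma_theta
        )
        ext_t, ext_q = cluster.medoid_t, cluster.medoid_q
        planar_gen = None
        if name != UNCLASSIFIED and templates[name].extendable == "planar":
            # canonicalize the medoid orientation toward its matched
            # generator, then pair it with the template's *other* lattice
            # generator (a cluster may correspond to either one)
            if inverted:
                ext_t, ext_q = invert_transforms(ext_t, ext_q)
            gens = templates[name].all_generators()
            planar_gen = gens[1 - g_idx] if len(gens) == 2 else gens[0]
        cluster.extendability = extendability(
            ext_t,
            ext_q,
            k_steps=k_steps,
            clash_radius=clash_radius,
            planar_generator=planar_gen,
        )

    n = len(field)
    assigned = np.full(n, UNCLASSIFIED, dtype=object)
    rank = np.full(n, -1, dtype=int)
    class_of_label = {c.cluster_id: c.assigned_class for c in clusters}
    for sample_idx, lab in enumerate(labels):
        cls = class_of_label.get(lab, UNCLASSIFIED)
        if cls == UNCLASSIFIED:
            continue
        p = pairs.src[sample_idx]
        if priorities[cls] > rank[p]:
            if rank[p] >= 0 and assigned[p] != cls:
                logger.debug(
                    "particle %d reassigned %s -> %s by priority",
                    p,
                    assigned[p],
                    cls,
                )
            assigned[p] = cls
            rank[p] = priorities[cls]

    particle_class = pd.Series(assigned, index=field.df.index, name="topology_class")

    rows = []
    cond = field.conditions.to_numpy()
    class_names = list(templates) + [UNCLASSIFIED]
    for condition in pd.unique(cond):
        sel = cond == condition
        total = int(sel.sum())
        for cls in class_names:
            k = int(((assigned == cls) & sel).sum())
            rows.append(
                {
                    "condition": condition,
                    "topology_class": cls,
                    "fraction": k / total if total else 0.0,
                    "n": k,
                }
            )
    abundance = pd.DataFrame(rows)
    for cluster in clusters:
        for condition in pd.unique(cond):
            sel = cond == condition
            member_particles = np.unique(
                np.concatenate([pairs.src[cluster.members], pairs.dst[cluster.members]])
            )
            in_cond = sel[member_particles].sum()
            cluster.abundance[str(condition)] = float(in_cond / sel.sum())

    return Classification(
        particle_class=particle_class,
        clusters=clusters,
        labels=labels,
        abundance=abundance,
    )


def detect_collided(
    pairs: PairSet,
    template: MotifTemplate,
    strict_eps: float = DEFAULT_STRICT_FRACTION * DEFAULT_EPS,
    eps: float = DEFAULT_EPS,
    sigma_t: float = DEFAULT_SIGMA_T,
    sigma_theta: float = DEFAULT_SIGMA_THETA,
    n_particles: int | None = None,
) -> tuple[set, float]:
    """Stalled-collided pair detection under a tightened tolerance.

    A pair is collided when its transform lies within ``strict_eps`` (in
    the symmetrized metric, which must be tighter than the clustering
    radius) of the collided template — the mRNA entry of one ribosome
    apposed to the exit of the other.  Returns the unordered pair set and
    the fraction of particles involved (if ``n_particles`` is given).
    """
    if strict_eps >= eps:
        raise ValueError("strict_eps must be tighter than the clustering eps")
    if len(pairs.src) == 0:
        return set(), 0.0
    t_inv, q_inv = invert_transforms(pairs.t, pairs.q)
    tpl_t = template.t0[None, :]
    tpl_q = template.q0[None, :]
    d = symmetrized_cross_distances(
        pairs.t, pairs.q, tpl_t, tpl_q, *invert_transforms(tpl_t, tpl_q), sigma_t, sigma_theta
    )[:, 0]
    # symmetrize over the pair's own inversion as well (double emission)
    d_inv = symmetrized_cross_distances(
        t_inv, q_inv, tpl_t, tpl_q, *invert_transforms(tpl_t, tpl_q), sigma_t, sigma_theta
    )[:, 0]
    d = np.minimum(d, d_inv)
    hits = np.where(d <= strict_eps)[0]
    pair_keys = {
        (min(pairs.src[i], pairs.dst[i]), max(pairs.src[i], pairs.dst[i])) for i in hits
    }
    fraction = 0.0
    if n_particles:
        involved = {p for key in pair_keys for p in key}
        fraction = len(involved) / n_particles
    return pair_keys, fraction


@dataclass
class TopologyResult:
    """End-to-end topology analysis of one field."""

    pairs: PairSet
    classification: Classification
    collided_pairs: set
    collided_fraction: float


def analyze_topology(
    field: ParticleField,
    templates: dict[str, MotifTemplate],
    cutoff: float = DEFAULT_CUTOFF,
    eps: float = DEFAULT_EPS,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    sigma_t: float = DEFAULT_SIGMA_T,
    sigma_theta: float = DEFAULT_SIGMA_THETA,
    strict_fraction: float = DEFAULT_STRICT_FRACTION,
) -> TopologyResult:
    """Neighbor search, clustering, classification and collided detection."""
    pair_idx = find_neighbors(field, cutoff)
    pairs = neighbor_transforms(field, pair_idx)
    labels, clusters = cluster_transforms(pairs, eps, min_samples, sigma_t, sigma_theta)
    classification = classify_particles(
        field, pairs, labels, clusters, templates, sigma_t, sigma_theta
    )
    collided_pairs, collided_fraction = detect_collided(
        pairs,
        templates["collided"],
        strict_eps=strict_fraction * eps,
        eps=eps,
        sigma_t=sigma_t,
        sigma_theta=sigma_theta,
        n_particles=len(field),
    )
    return TopologyResult(
        pairs=pairs,
        classification=classification,
        collided_pairs=collided_pairs,
        collided_fraction=collided_fraction,
    )
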