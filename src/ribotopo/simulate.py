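"""Synthetic ribosome particle-field generator.

Plants polysome/disome motifs by composing each motif's reference
transform (from the packaged template library) into rigid groups — helical
chains, planar patches, dimer pairs — dropping each group into the volume
at a random pose, perturbing every member with Gaussian pose noise, and
enforcing excluded volume by rejection sampling against a uniform spatial
hash.  Translation-state labels are drawn from motif- and
condition-dependent composition vectors.  All randomness flows through a
single seeded generator, so a config (including its seed) determines the
output table bitwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .field import DIMER_MOTIFS, STATES, FieldConfig, ParticleField
from .geometry import quat_to_rotation, rotation_to_euler
from .templates import MotifTemplate, load_template_library


class PlacementError(RuntimeError):
    """Raised when a group cannot be placed within the retry budget."""


class _SpatialGrid:
    """Uniform hash grid for excluded-volume queries (cell = d_min)."""

    def __init__(self, d_min: float):
        self.d_min = d_min
        self.cell = d_min
        self.cells: dict[tuple[int, int, int], list[np.ndarray]] = {}

    def _key(self, p):
        return (int(p[0] // self.cell), int(p[1] // self.cell), int(p[2] // self.cell))

    def too_close(self, p) -> bool:
        kx, ky, kz = self._key(p)
        r2 = self.d_min**2
        for ix in (kx - 1, kx, kx + 1):
            for iy in (ky - 1, ky, ky + 1):
                for iz in (kz - 1, kz, kz + 1):
                    for q in self.cells.get((ix, iy, iz), ()):
                        d = p - q
                        if d @ d < r2:
                            return True
        return False

    def insert(self, p) -> None:
        self.cells.setdefault(self._key(p), []).append(np.asarray(p, dtype=float))


def _random_rotation(rng: np.random.Generator) -> Rotation:
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q))


def _noise_rotations(rng: np.random.Generator, n: int, sigma_theta: float) -> Rotation:
    """Per-particle orientation noise: angle ~ N(0, sigma_theta) about a
    uniformly random axis (sigma_theta is the std of the *total* angle)."""
    if sigma_theta == 0:
        return Rotation.identity(n)
    axes = rng.normal(size=(n, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    angles = np.deg2rad(rng.normal(0.0, sigma_theta, size=n))
    return Rotation.from_rotvec(axes * angles[:, None])


def _group_geometry(motif: str, size: int, template: MotifTemplate, patch_cols: int):
    """Ideal member poses of one group, in the group frame."""
    if motif == "monomer":
        assert size == 1
        return np.zeros((1, 3)), Rotation.identity(1)
    t0 = template.t0
    r0 = quat_to_rotation(template.q0)
    if motif == "cyto_helical":
        pos = [np.zeros(3)]
        rots = [Rotation.identity()]
        for _ in range(size - 1):
            pos.append(pos[-1] + rots[-1].apply(t0))
            rots.append(rots[-1] * r0)
        return np.array(pos), Rotation.concatenate(rots)
    if motif == "membrane_planar":
        g2 = template.generators[0][0]
        pos = np.array(
            [(k // patch_cols) * g2 + (k % patch_cols) * t0 for k in range(size)]
        )
        return pos, Rotation.identity(size)
    if motif in DIMER_MOTIFS:
        assert size == 2
        return np.array([np.zeros(3), t0]), Rotation.concatenate(
            [Rotation.identity(), r0]
        )
    raise ValueError(f"unknown motif {motif!r}")


def _partition_counts(total: int, unit: int, min_size: int = 2) -> list[int]:
    """Split `total` particles into groups of `unit`, absorbing remainders."""
    if total == 0:
        return []
    sizes = [unit] * (total // unit)
    rem = total % unit
    if rem >= min_size:
        sizes.append(rem)
    elif rem and sizes:
        sizes[-1] += rem
    elif rem:
        sizes.append(rem + min_size - rem)  # degenerate tiny request: round up
    return sizes


def _motif_counts(cfg: FieldConfig, n: int) -> dict[str, int]:
    counts = {}
    for motif, w in cfg.motif_weights.items():
        c = int(round(w * n))
        if motif in DIMER_MOTIFS:
            c = 2 * int(round(w * n / 2.0))
        counts[motif] = c
    return counts


def simulate_field(config: FieldConfig, templates: dict | None = None) -> ParticleField:
    """Generate a particle field according to ``config``.

    Deterministic given the config (seed included).  Raises
    :class:`PlacementError` if the volume cannot host the requested count
    at ``d_min`` within ``max_retries`` attempts per group.
    """
    if templates is None:
        templates = load_template_library()
    rng = np.random.default_rng(config.seed)
    box = np.asarray(config.box, dtype=float)

    per_tomo = [config.n_particles // config.n_tomograms] * config.n_tomograms
    per_tomo[0] += config.n_particles - sum(per_tomo)

    records: list[dict] = []
    pid = 0
    for tomo_id, n_tomo in enumerate(per_tomo):
        counts = _motif_counts(config, n_tomo)
        n_structured = sum(counts.values())
        if n_structured > n_tomo:
            raise ValueError("motif weights imply more particles than n_particles")
        n_mono = n_tomo - n_structured

        # group plan: chains, patches, dimer pairs, then monomers
        plan: list[tuple[str, int]] = []
        if counts.get("cyto_helical"):
            remaining = counts["cyto_helical"]
            lo, hi = config.chain_length
            while remaining > 0:
                size = int(rng.integers(lo, hi + 1))
                if remaining - size in (1,):  # never strand a single particle
                    size += 1
                size = min(size, remaining)
                size = max(size, 2) if remaining >= 2 else remaining
                plan.append(("cyto_helical", size))
                remaining -= size
        if counts.get("membrane_planar"):
            unit = config.patch_shape[0] * config.patch_shape[1]
            for size in _partition_counts(counts["membrane_planar"], unit):
                plan.append(("membrane_planar", size))
        for motif in DIMER_MOTIFS:
            for _ in range(counts.get(motif, 0) // 2):
                plan.append((motif, 2))
        plan.extend(("monomer", 1) for _ in range(n_mono))

        grid = _SpatialGrid(config.d_min)
        patch_cols = config.patch_shape[1]
        for motif, size in plan:
            template = templates.get(motif) if motif != "monomer" else None
            local_pos, local_rot = _group_geometry(motif, size, template, patch_cols)
            placed = False
            for _ in range(config.max_retries):
                g_rot = _random_rotation(rng)
                pos = g_rot.apply(local_pos)
                rots = g_rot * local_rot
                # pose noise
                if config.sigma_t > 0:
                    pos = pos + rng.normal(0.0, config.sigma_t, size=(size, 3))
                rots = rots * _noise_rotations(rng, size, config.sigma_theta)
                lo = pos.min(axis=0)
                hi = pos.max(axis=0)
                span_ok = np.all(box - (hi - lo) > 0)
                if not span_ok:
                    continue
                anchor = rng.uniform(-lo, box - hi)
                pos = pos + anchor
                if size > 1:
                    diff = pos[:, None, :] - pos[None, :, :]
                    d2 = np.sum(diff**2, axis=-1)
                    np.fill_diagonal(d2, np.inf)
                    if d2.min() < config.d_min**2:
                        continue
                if any(grid.too_close(p) for p in pos):
                    continue
                for p in pos:
                    grid.insert(p)
                eulers = rotation_to_euler(rots if size > 1 else Rotation.concatenate([rots]))
                eulers = np.atleast_2d(eulers)
                first_pid = pid
                for k in range(size):
                    partner = -1
                    if motif in DIMER_MOTIFS:
                        partner = first_pid + (1 - k)
                    records.append(
                        {
                            "particle_id": pid,
                            "tomogram_id": tomo_id,
                            "x": pos[k, 0],
                            "y": pos[k, 1],
                            "z": pos[k, 2],
                            "rot": eulers[k, 0],
                            "tilt": eulers[k, 1],
                            "psi": eulers[k, 2],
                            "condition": config.condition,
                            "truth_motif": motif,
                            "truth_partner_id": partner,
                        }
                    )
                    pid += 1
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"could not place a {motif} group of {size} particles at "
                    f"d_min={config.d_min} A within {config.max_retries} attempts; "
                    f"volume too small or too crowded"
                )

    df = pd.DataFrame.from_records(records)

    # translation-state labels, motif- and condition-conditional
    vectors = config.state_vectors() if config.state_global else None
    df["state_label"] = "idle"
    if vectors is not None:
        for motif in df["truth_motif"].unique():
            v = vectors.get(motif)
            if v is None:  # motif planted but no vector: fall back to global
                v = np.array([config.state_global.get(s, 0.0) for s in STATES])
            idx = np.where(df["truth_motif"].to_numpy() == motif)[0]
            draws = rng.choice(len(STATES), size=len(idx), p=v)
            df.loc[idx, "state_label"] = [STATES[d] for d in draws]

    return ParticleField(df)
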