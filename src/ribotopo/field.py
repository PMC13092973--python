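"""Particle-field container and simulation configuration.

A field is a table of ribosome poses: position (Angstrom), orientation
(ZYZ Euler angles, degrees), tomogram id, experimental condition,
translation-state label, and — for simulated fields — the ground-truth
motif and dimer partner.  The table is a plain :class:`pandas.DataFrame`
wrapped by :class:`ParticleField` for validated, typed access.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.transform import Rotation

from .geometry import UNIT_TOL, euler_to_rotation, rotation_to_euler, rotation_to_quat

CONDITIONS = ("untreated", "treated")

STATES = (
    "decoding",
    "classical_PRE",
    "rotated_PRE",
    "POST",
    "idle",
    "subunit_SSU",
    "subunit_LSU",
)

#: the four 80S states of the elongation cycle
ELONGATING_STATES = ("decoding", "classical_PRE", "rotated_PRE", "POST")

TRUTH_MOTIFS = (
    "cyto_helical",
    "membrane_planar",
    "disome1",
    "disome2",
    "disome3",
    "collided",
    "monomer",
)

#: motifs realised as mutual two-particle groups
DIMER_MOTIFS = ("disome1", "disome2", "disome3", "collided")

COLUMNS = (
    "particle_id",
    "tomogram_id",
    "x",
    "y",
    "z",
    "rot",
    "tilt",
    "psi",
    "condition",
    "state_label",
    "truth_motif",
    "truth_partner_id",
)


@dataclass(frozen=True)
class ParticlePose:
    """One ribosome: position/orientation plus condition and labels."""

    particle_id: int
    tomogram_id: int
    position: np.ndarray  # (3,) Angstrom
    quaternion: np.ndarray  # (4,) scalar-first, unit within 1e-6
    condition: str = "untreated"
    state_label: str = "idle"
    truth_motif: str = "monomer"
    truth_partner_id: int | None = None

    def __post_init__(self):
        q = np.asarray(self.quaternion, dtype=float)
        if abs(np.linalg.norm(q) - 1.0) > 1e-5:
            raise ValueError("quaternion must be unit within 1e-5")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.state_label not in STATES:
            raise ValueError(f"unknown state label {self.state_label!r}")
        if self.truth_motif not in TRUTH_MOTIFS:
            raise ValueError(f"unknown motif {self.truth_motif!r}")

    @property
    def euler(self) -> np.ndarray:
        from .geometry import quat_to_euler

        return quat_to_euler(self.quaternion)


class ParticleField:
    """DataFrame-backed collection of particle poses.

    The orientation columns are ZYZ Euler angles in degrees; vectorized
    accessors return scipy Rotations / quaternion arrays.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"field table missing columns: {missing}")
        self.df = df.reset_index(drop=True)
        if validate:
            self.validate()

    def __len__(self) -> int:
        return len(self.df)

    # -- accessors ---------------------------------------------------------
    @property
    def positions(self) -> np.ndarray:
        return self.df[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def rotations(self) -> Rotation:
        return euler_to_rotation(self.df[["rot", "tilt", "psi"]].to_numpy(dtype=float))

    @property
    def quaternions(self) -> np.ndarray:
        return rotation_to_quat(self.rotations)

    @property
    def conditions(self) -> pd.Series:
        return self.df["condition"]

    def pose(self, idx: int) -> ParticlePose:
        row = self.df.iloc[idx]
        partner = row["truth_partner_id"]
        return ParticlePose(
            particle_id=int(row["particle_id"]),
            tomogram_id=int(row["tomogram_id"]),
            position=np.array([row["x"], row["y"], row["z"]], dtype=float),
            quaternion=rotation_to_quat(
                euler_to_rotation([row["rot"], row["tilt"], row["psi"]])
            ),
            condition=str(row["condition"]),
            state_label=str(row["state_label"]),
            truth_motif=str(row["truth_motif"]),
            truth_partner_id=None if partner < 0 else int(partner),
        )

    def validate(self) -> None:
        df = self.df
        if df["particle_id"].duplicated().any():
            raise ValueError("duplicate particle ids")
        bad_state = set(df["state_label"]) - set(STATES)
        if bad_state:
            raise ValueError(f"unknown state labels: {sorted(bad_state)}")
        bad_motif = set(df["truth_motif"]) - set(TRUTH_MOTIFS)
        if bad_motif:
            raise ValueError(f"unknown motifs: {sorted(bad_motif)}")
        bad_cond = set(df["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValueError(f"unknown conditions: {sorted(bad_cond)}")
        # dimer partner relation must be present and mutual
        dimers = df[df["truth_motif"].isin(DIMER_MOTIFS)]
        if len(dimers):
            if (dimers["truth_partner_id"] < 0).any():
                raise ValueError("dimer-motif particle without truth partner")
            by_id = df.set_index("particle_id")["truth_partner_id"]
            partners = dimers.set_index("particle_id")["truth_partner_id"]
            back = by_id.loc[partners.to_numpy()].to_numpy()
            if not np.array_equal(back, partners.index.to_numpy()):
                raise ValueError("dimer partner relation is not mutual")

    def subset(self, mask) -> "ParticleField":
        return ParticleField(self.df[mask].reset_index(drop=True), validate=False)

    def transformed(self, rotation: Rotation, translation) -> "ParticleField":
        """Apply one global rigid motion to every pose (equivariance checks)."""
        df = self.df.copy()
        pos = rotation.apply(self.positions) + np.asarray(translation, dtype=float)
        rots = rotation * self.rotations
        df[["x", "y", "z"]] = pos
        df[["rot", "tilt", "psi"]] = rotation_to_euler(rots)
        return ParticleField(df, validate=False)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class FieldConfig:
    """Parameters of one simulated condition (a set of tomogram volumes).

    ``motif_weights`` are number fractions of particles planted in each
    structured motif; the remainder are free monomers.  ``state_composition``
    holds a global per-state vector (the condition's printed composition)
    plus per-motif overrides; the monomer vector is the residual that makes
    the mixture reproduce the global vector exactly.
    """

    n_particles: int = 5000
    n_tomograms: int = 1
    box: tuple[float, float, float] = (18000.0, 18000.0, 2500.0)  # Angstrom
    condition: str = "untreated"
    motif_weights: dict = dc_field(default_factory=dict)
    state_global: dict = dc_field(default_factory=dict)
    state_overrides: dict = dc_field(default_factory=dict)
    chain_length: tuple[int, int] = (4, 9)  # helical polysome length range
    patch_shape: tuple[int, int] = (3, 3)  # planar patch grid
    sigma_t: float = 15.0  # Angstrom, per-axis positional noise
    sigma_theta: float = 5.0  # degrees, std of the total noise rotation angle
    d_min: float = 200.0  # Angstrom, excluded-volume hard core
    max_retries: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.sigma_t < 0 or self.sigma_theta < 0:
            raise ValueError("noise scales must be >= 0")
        total = sum(self.motif_weights.values())
        if not 0 <= total <= 1 + 1e-9:
            raise ValueError("motif weights must be fractions summing to <= 1")
        for name, w in self.motif_weights.items():
            if name not in TRUTH_MOTIFS or name == "monomer":
                raise ValueError(f"unknown motif weight key {name!r}")
            if not 0 <= w <= 1:
                raise ValueError(f"motif weight {name} outside [0, 1]")
        if self.state_global:
            s = sum(self.state_global.values())
            if not math.isclose(s, 1.0, abs_tol=1e-6):
                raise ValueError(f"global state vector sums to {s}, expected 1")

    @property
    def monomer_weight(self) -> float:
        return 1.0 - sum(self.motif_weights.values())

    def state_vectors(self) -> dict[str, np.ndarray]:
        """Resolve per-motif state vectors (ordered as :data:`STATES`).

        Structured motifs take their override (missing states are 0) or the
        global vector.  Monomers take the residual
        ``(global - sum_m w_m v_m) / w_monomer`` so that the planted mixture
        reproduces the global composition exactly; a negative residual means
        the overrides are inconsistent with the global vector and raises.
        """
        if not self.state_global:
            raise ValueError("config has no state composition")
        g = np.array([self.state_global.get(s, 0.0) for s in STATES], dtype=float)
        vectors: dict[str, np.ndarray] = {}
        acc = np.zeros(len(STATES))
        for motif, w in self.motif_weights.items():
            ov = self.state_overrides.get(motif)
            if ov is None:
                v = g.copy()
            else:
                unknown = set(ov) - set(STATES)
                if unknown:
                    raise ValueError(f"unknown states in override {motif}: {sorted(unknown)}")
                v = np.array([ov.get(s, 0.0) for s in STATES], dtype=float)
            if not math.isclose(v.sum(), 1.0, abs_tol=1e-6):
                raise ValueError(f"state vector for {motif} sums to {v.sum()}")
            v = v / v.sum()
            vectors[motif] = v
            acc += w * v
        w_mono = self.monomer_weight
        if w_mono > 1e-12:
            resid = (g - acc) / w_mono
            if (resid < -1e-9).any():
                bad = [STATES[i] for i in np.where(resid < -1e-9)[0]]
                raise ValueError(
                    f"motif overrides overdraw the global composition for {bad}"
                )
            resid = np.clip(resid, 0.0, None)
            vectors["monomer"] = resid / resid.sum()
        return vectors

    @classmethod
    def from_dict(cls, raw: dict) -> "FieldConfig":
        raw = dict(raw)
        comp = raw.pop("state_composition", {})
        kwargs = {}
        for key in (
            "n_particles",
            "n_tomograms",
            "condition",
            "motif_weights",
            "sigma_t",
            "sigma_theta",
            "d_min",
            "max_retries",
            "seed",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "box" in raw:
            kwargs["box"] = tuple(float(v) for v in raw["box"])
        if "chain_length" in raw:
            kwargs["chain_length"] = tuple(int(v) for v in raw["chain_length"])
        if "patch_shape" in raw:
            kwargs["patch_shape"] = tuple(int(v) for v in raw["patch_shape"])
        if comp:
            kwargs["state_global"] = dict(comp.get("global", {}))
            kwargs["state_overrides"] = {
                k: dict(v) for k, v in comp.get("motif_overrides", {}).items()
            }
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "FieldConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_condition_config(name: str, **overrides) -> FieldConfig:
    """Load a packaged condition config (``"untreated"`` or ``"treated"``).

    Keyword overrides replace top-level config entries (e.g. ``seed=...``,
    ``n_particles=...``).
    """
    text = resources.files("ribotopo").joinpath(f"configs/{name}.yaml").read_text()
    raw = yaml.safe_load(text)
    raw.update(overrides)
    return FieldConfig.from_dict(raw)
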