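"""Motif template library: reference inter-ribosome transforms.

Templates live in a versioned YAML data file shipped with the package
(``data/motif_templates.yaml``); nothing numeric is hard-coded in logic.
A template is matched against cluster medoids under the symmetrized
transform metric, so a C2 template and the double emission of each
physical pair are handled uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .geometry import rotation_to_quat, transform_distance

MOTIF_NAMES = (
    "cyto_helical",
    "membrane_planar",
    "disome1",
    "disome2",
    "disome3",
    "collided",
)

#: the five topology classes of the main clustering (collided is detected
#: separately under a strict threshold)
FIVE_CLASSES = (
    "cyto_helical",
    "membrane_planar",
    "disome1",
    "disome2",
    "disome3",
)


@dataclass(frozen=True)
class MotifTemplate:
    """Reference transform class with symmetry and extendability attributes."""

    name: str
    t0: np.ndarray  # (3,) Angstrom
    q0: np.ndarray  # (4,) scalar-first unit quaternion
    tol_t: float  # Angstrom
    tol_theta: float  # degrees
    symmetry: str  # "none" | "C2"
    extendable: str  # "helical" | "planar" | "terminal"
    priority: int  # larger outranks smaller in particle classification
    generators: tuple = field(default=())  # extra (t, q) generators (planar lattice)

    def all_generators(self):
        """Primary transform plus any secondary lattice generators."""
        return ((self.t0, self.q0),) + tuple(self.generators)


def _parse_transform(node) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(node["translation"], dtype=float)
    axis = np.asarray(node["rotation"]["axis"], dtype=float)
    angle = float(node["rotation"]["angle_deg"])
    norm = np.linalg.norm(axis)
    if norm == 0:
        if angle != 0:
            raise ValueError("zero rotation axis with nonzero angle")
        rot = Rotation.identity()
    else:
        rot = Rotation.from_rotvec(np.deg2rad(angle) * axis / norm)
    return t, rotation_to_quat(rot)


def load_template_library(path=None) -> dict[str, MotifTemplate]:
    """Load the motif template library (packaged file by default).

    Validates tolerances and the C2 algebra of any template declared C2
    (its transform must equal its own inverse within one metric unit).
    """
    if path is None:
        text = resources.files("ribotopo").joinpath("data/motif_templates.yaml").read_text()
        raw = yaml.safe_load(text)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    sigma_t = float(raw["metric"]["sigma_t"])
    sigma_theta = float(raw["metric"]["sigma_theta"])
    library: dict[str, MotifTemplate] = {}
    for name, node in raw["templates"].items():
        t0, q0 = _parse_transform(node)
        generators = ()
        if "second_generator" in node:
            generators = (_parse_transform(node["second_generator"]),)
        tpl = MotifTemplate(
            name=name,
            t0=t0,
            q0=q0,
            tol_t=float(node["tol_t"]),
            tol_theta=float(node["tol_theta"]),
            symmetry=str(node["symmetry"]),
            extendable=str(node["extendable"]),
            priority=int(node["priority"]),
            generators=generators,
        )
        if tpl.tol_t <= 0 or tpl.tol_theta <= 0:
            raise ValueError(f"template {name}: tolerances must be > 0")
        if tpl.symmetry == "C2":
            d = transform_distance(
                tpl.t0, tpl.q0, tpl.t0, tpl.q0, sigma_t, sigma_theta, symmetrize=False
            )
            # C2 algebra: T must coincide with its own inverse
            from .geometry import invert_transforms

            ti, qi = invert_transforms(tpl.t0, tpl.q0)
            d = transform_distance(tpl.t0, tpl.q0, ti, qi, sigma_t, sigma_theta, symmetrize=False)
            if d >= 1.0:
                raise ValueError(f"template {name} declared C2 but d(T, T^-1) = {d:.2f} >= 1")
        library[name] = tpl
    return library


def metric_scales(path=None) -> tuple[float, float]:
    """(sigma_t, sigma_theta) declared alongside the packaged templates."""
    if path is None:
        text = resources.files("ribotopo").joinpath("data/motif_templates.yaml").read_text()
        raw = yaml.safe_load(text)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return float(raw["metric"]["sigma_t"]), float(raw["metric"]["sigma_theta"])
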