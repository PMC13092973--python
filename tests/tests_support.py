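"""Shared helpers for the test suite."""

import numpy as np
import pandas as pd

from ribotopo.field import ParticleField


def field_from_positions(pos, tomo=None, eulers=None):
    """Minimal monomer field from raw positions (and optional Euler angles)."""
    pos = np.asarray(pos, dtype=float)
    n = len(pos)
    if eulers is None:
        eulers = np.zeros((n, 3))
    df = pd.DataFrame(
        {
            "particle_id": np.arange(n),
            "tomogram_id": tomo if tomo is not None else np.zeros(n, dtype=int),
            "x": pos[:, 0],
            "y": pos[:, 1],
            "z": pos[:, 2],
            "rot": eulers[:, 0],
            "tilt": eulers[:, 1],
            "psi": eulers[:, 2],
            "condition": "untreated",
            "state_label": "idle",
            "truth_motif": "monomer",
            "truth_partner_id": -1,
        }
    )
    return ParticleField(df, validate=False)
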