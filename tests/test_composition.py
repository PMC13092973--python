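"""Composition tables, condition deltas, NN distances, occupancy."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from ribotopo import load_condition_config, simulate_field
from ribotopo.composition import (
    composition_by_topology,
    condition_delta,
    neighbor_occupancy,
    nn_distance_compare,
)
from ribotopo.field import ELONGATING_STATES, FieldConfig, ParticleField


def _manual_field(states, conditions=None, classes=None):
    n = len(states)
    df = pd.DataFrame(
        {
            "particle_id": np.arange(n),
            "tomogram_id": 0,
            "x": np.arange(n) * 400.0,
            "y": 0.0,
            "z": 0.0,
            "rot": 0.0,
            "tilt": 0.0,
            "psi": 0.0,
            "condition": conditions if conditions is not None else "untreated",
            "state_label": states,
            "truth_motif": "monomer",
            "truth_partner_id": -1,
        }
    )
    field = ParticleField(df, validate=False)
    assign = pd.Series(classes if classes is not None else "unclassified", index=df.index)
    return field, assign


class TestCompositionTable:
    def test_single_class_all_idle(self):
        field, assign = _manual_field(["idle"] * 5)
        table = composition_by_topology(field, assign)
        assert table.loc[("untreated", "all"), "idle"] == 1.0
        assert table.loc[("untreated", "all"), "n"] == 5

    def test_manual_tally(self):
        states = ["idle", "idle", "decoding", "POST", "decoding",
                  "decoding", "idle", "classical_PRE", "rotated_PRE", "idle"]
        classes = ["disome2", "disome2", "cyto_helical", "cyto_helical", "cyto_helical",
                   "unclassified", "unclassified", "unclassified", "unclassified", "unclassified"]
        field, assign = _manual_field(states, classes=classes)
        table = composition_by_topology(field, assign)
        assert table.loc[("untreated", "all"), "idle"] == pytest.approx(0.4)
        assert table.loc[("untreated", "disome2"), "idle"] == 1.0
        assert table.loc[("untreated", "cyto_helical"), "decoding"] == pytest.approx(2 / 3)
        # rows normalize and the "all" row mixes the class rows by size
        for _, row in table.iterrows():
            assert sum(row[s] for s in row.index if s != "n") == pytest.approx(1.0)
        class_rows = table.drop(index=("untreated", "all"))
        assert class_rows["n"].sum() == table.loc[("untreated", "all"), "n"]
        mixed = (class_rows["idle"] * class_rows["n"]).sum() / class_rows["n"].sum()
        assert mixed == pytest.approx(table.loc[("untreated", "all"), "idle"])

    def test_unknown_state_rejected(self):
        field, assign = _manual_field(["idle"] * 3)
        field.df.loc[0, "state_label"] = "bogus"
        with pytest.raises(ValueError, match="unknown state"):
            composition_by_topology(field, assign)

    def test_planted_disomes_are_idle_rows(self, templates, small_treated_field):
        from ribotopo.topology import analyze_topology

        res = analyze_topology(small_treated_field, templates)
        table = composition_by_topology(small_treated_field, res.classification.particle_class)
        for cls in ("disome2", "disome3"):
            assert table.loc[("treated", cls), "idle"] == pytest.approx(1.0)


class TestConditionDelta:
    @staticmethod
    def _two_condition_table(untreated_idle, treated_idle):
        states = {"idle": untreated_idle, "decoding": 1 - untreated_idle}
        rows = []
        for cond, idle in (("untreated", untreated_idle), ("treated", treated_idle)):
            row = {"condition": cond, "topology_class": "all", "n": 1000}
            for s in ("decoding", "classical_PRE", "rotated_PRE", "POST",
                      "idle", "subunit_SSU", "subunit_LSU"):
                row[s] = 0.0
            row["idle"] = idle
            row["decoding"] = 1 - idle
            rows.append(row)
        return pd.DataFrame(rows).set_index(["condition", "topology_class"])

    def test_identical_conditions_unit_ratio(self):
        table = self._two_condition_table(0.3, 0.3)
        delta = condition_delta(table)
        assert delta.loc["idle", "ratio"] == pytest.approx(1.0)
        assert delta.loc["idle", "difference"] == pytest.approx(0.0)

    def test_fourfold_idle_increase(self):
        delta = condition_delta(self._two_condition_table(0.154, 0.648))
        assert delta.loc["idle", "ratio"] == pytest.approx(4.2078, abs=1e-3)

    def test_zero_denominator_undefined_not_infinite(self):
        delta = condition_delta(self._two_condition_table(0.0, 0.5))
        assert bool(delta.loc["idle", "undefined"])
        assert np.isnan(delta.loc["idle", "ratio"])

    def test_missing_condition_rejected(self):
        table = self._two_condition_table(0.3, 0.3).drop(index="treated", level=0)
        with pytest.raises(ValueError, match="condition"):
            condition_delta(table)


class TestNNDistances:
    def test_self_comparison_null(self, monomer_config):
        field = simulate_field(monomer_config(n=100, seed=5))
        res = nn_distance_compare(field, field)
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(1.0)

    def test_separated_supports_maximal_statistic(self):
        from tests_support import field_from_positions

        # 1-D lattices: every NN distance is 300 A in one field, 600 in the
        # other -- disjoint supports, so the KS statistic is 1
        a = field_from_positions(np.c_[np.arange(50) * 300.0, np.zeros(50), np.zeros(50)])
        b = field_from_positions(np.c_[np.arange(50) * 600.0, np.zeros(50), np.zeros(50)])
        res = nn_distance_compare(a, b)
        assert res.statistic == pytest.approx(1.0)

    def test_null_calibration_same_config(self, monomer_config):
        """Same generative conditions, different seeds: the KS test should
        accept the null in at least 90% of 50 seeded replicates."""
        accept = 0
        base = simulate_field(monomer_config(n=150, seed=1000, box=(9000.0, 9000.0, 2000.0)))
        for seed in range(50):
            other = simulate_field(
                monomer_config(n=150, seed=2000 + seed, box=(9000.0, 9000.0, 2000.0))
            )
            if nn_distance_compare(base, other).pvalue > 0.05:
                accept += 1
        assert accept >= 45

    def test_singleton_field_rejected(self, monomer_config):
        lone = simulate_field(monomer_config(n=1, seed=0))
        pair = simulate_field(monomer_config(n=2, seed=0))
        with pytest.raises(ValueError):
            nn_distance_compare(lone, pair)


class TestOccupancy:
    def test_isolated_monomer_neither_side(self, monomer_config):
        field = simulate_field(monomer_config(n=20, seed=77, box=(30000.0, 30000.0, 5000.0)))
        # huge box: essentially no neighbors within 400 A
        occ = neighbor_occupancy(field)
        assert occ.loc["idle", "neither"] == pytest.approx(1.0)

    def test_zero_noise_helix_interior_both_sides(self):
        cfg = FieldConfig(
            n_particles=6,
            motif_weights={"cyto_helical": 1.0},
            chain_length=(6, 6),
            sigma_t=0.0,
            sigma_theta=0.0,
            state_global={"decoding": 1.0},
            seed=8,
        )
        field = simulate_field(cfg)
        occ = neighbor_occupancy(field)
        # every interior particle sees both sides (ends may pick up an
        # additional far helix neighbor inside the cone)
        assert occ.loc["decoding", "both"] >= 4 / 6
        assert occ.loc["decoding", "neither"] == 0.0

    def test_planted_dimer_single_side(self):
        cfg = FieldConfig(
            n_particles=2,
            motif_weights={"disome1": 1.0},
            sigma_t=0.0,
            sigma_theta=0.0,
            state_global={"idle": 1.0},
            seed=4,
        )
        field = simulate_field(cfg)
        occ = neighbor_occupancy(field)
        assert occ.loc["idle", "entry_only"] + occ.loc["idle", "exit_only"] == pytest.approx(1.0)

    def test_row_fractions_partition(self, small_treated_field):
        occ = neighbor_occupancy(small_treated_field)
        total = occ[["entry_only", "exit_only", "both", "neither"]].sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_rigid_motion_invariance(self, small_treated_field, rng):
        moved = small_treated_field.transformed(
            Rotation.from_quat(rng.normal(size=4)), rng.uniform(-2000, 2000, 3)
        )
        a = neighbor_occupancy(small_treated_field)
        b = neighbor_occupancy(moved)
        pd.testing.assert_frame_equal(a, b)

    def test_non_unit_directions_rejected(self, small_treated_field):
        with pytest.raises(ValueError, match="unit"):
            neighbor_occupancy(small_treated_field, entry_dir=(2.0, 0.0, 0.0))


def test_recovered_composition_matches_configured():
    """Planted state fractions recovered within 3 binomial SE per state."""
    for name in ("untreated", "treated"):
        cfg = load_condition_config(name, n_particles=5000, seed=55)
        field = simulate_field(cfg)
        freqs = field.df["state_label"].value_counts(normalize=True)
        for state, p in cfg.state_global.items():
            se = np.sqrt(p * (1 - p) / 5000)
            assert abs(freqs.get(state, 0.0) - p) <= 3 * se, (name, state)


def test_elongating_states_cover_both_pre_states():
    assert "classical_PRE" in ELONGATING_STATES
    assert "rotated_PRE" in ELONGATING_STATES
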