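import logging

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from bridgeswitch import (
    DistanceSeries,
    ProtonationPolicy,
    Topology,
    Trajectory,
    bridge_state_series,
    distance_series,
    identify_charged_groups,
    min_pair_distance,
)
from bridgeswitch.errors import EmptyAnalysisError, GroupLookupError, ParameterError
from bridgeswitch.saltbridges import GroupType

from conftest import atom


def _groups_from(atoms, **kw):
    return identify_charged_groups(Topology(tuple(atoms)), **kw)


class TestIdentifyChargedGroups:
    def test_asp_lys_found_gly_ignored(self):
        groups = _groups_from(
            [
                atom(1, "OD1", "ASP", seq=1),
                atom(2, "OD2", "ASP", seq=1),
                atom(3, "NZ", "LYS", seq=2),
                atom(4, "CA", "GLY", seq=3),
            ]
        )
        assert [(g.group_type, g.sign) for g in groups] == [
            (GroupType.CARBOXYLATE, -1),
            (GroupType.AMMONIUM, +1),
        ]
        assert groups[0].atom_names == ("OD1", "OD2")

    @pytest.mark.parametrize("ph,expected", [(5.5, 1), (7.4, 0)])
    def test_histidine_charged_only_at_low_ph(self, ph, expected):
        groups = _groups_from(
            [atom(1, "ND1", "HIS", seq=4), atom(2, "NE2", "HIS", seq=4)],
            policy=ProtonationPolicy(pH=ph),
        )
        assert len(groups) == expected

    def test_lys_without_nz_skipped_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            groups = _groups_from([atom(1, "CA", "LYS", seq=2), atom(2, "NZ", "LYS", seq=5)])
        assert [g.residue_seq for g in groups] == [5]
        assert "skipped" in caplog.text

    def test_per_residue_override_beats_ph(self):
        groups = _groups_from(
            [atom(1, "ND1", "HIS", seq=4)],
            policy=ProtonationPolicy(pH=7.4, overrides={"H4": True}),
        )
        assert len(groups) == 1

    def test_termini_opt_in(self):
        atoms = [
            atom(1, "N", "GLY", seq=1),
            atom(2, "CA", "GLY", seq=1),
            atom(3, "O", "GLY", seq=2),
            atom(4, "OXT", "GLY", seq=2),
        ]
        assert _groups_from(atoms) == []
        groups = _groups_from(atoms, include_termini=True)
        assert {g.group_type for g in groups} == {GroupType.N_TERMINUS, GroupType.C_TERMINUS}

    def test_deterministic_order(self):
        atoms = [
            atom(1, "NZ", "LYS", seq=9),
            atom(2, "OE1", "GLU", seq=5),
            atom(3, "OD1", "ASP", seq=7),
        ]
        assert [g.residue_seq for g in _groups_from(atoms)] == [5, 7, 9]


def _grp(indices, sign=1):
    from bridgeswitch.saltbridges import ChargedGroup

    return ChargedGroup(
        chain="A",
        residue_seq=1 if sign > 0 else 2,
        residue_name="LYS" if sign > 0 else "ASP",
        group_type=GroupType.AMMONIUM if sign > 0 else GroupType.CARBOXYLATE,
        sign=sign,
        atom_names=tuple(f"X{i}" for i in indices),
        atom_indices=tuple(indices),
    )


class TestMinPairDistance:
    def test_three_four_five(self):
        frame = np.array([[0.0, 0, 0], [3.0, 4.0, 0]])
        assert min_pair_distance(frame, _grp([0]), _grp([1], -1)) == pytest.approx(5.0)

    def test_min_over_pairs(self):
        frame = np.array([[0.0, 0, 0], [2.0, 0, 0], [5.0, 0, 0]])
        assert min_pair_distance(frame, _grp([0, 1], -1), _grp([2])) == pytest.approx(3.0)

    def test_matches_bruteforce_oracle_and_symmetry(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            frame = rng.uniform(-10, 10, size=(20, 3))
            ga, gb = _grp(list(range(10))), _grp(list(range(10, 20)), -1)
            oracle = min(
                np.linalg.norm(frame[i] - frame[j]) for i in range(10) for j in range(10, 20)
            )
            assert min_pair_distance(frame, ga, gb) == pytest.approx(oracle, abs=1e-12)
            assert min_pair_distance(frame, gb, ga) == pytest.approx(oracle, abs=1e-12)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(3)
        frame = rng.uniform(-5, 5, size=(6, 3))
        ga, gb = _grp([0, 1, 2]), _grp([3, 4, 5], -1)
        d0 = min_pair_distance(frame, ga, gb)
        rot = Rotation.random(random_state=5).as_matrix()
        moved = frame @ rot.T + np.array([10.0, -4.0, 2.0])
        assert min_pair_distance(moved, ga, gb) == pytest.approx(d0, abs=1e-10)

    def test_missing_atoms_error(self):
        with pytest.raises(GroupLookupError):
            min_pair_distance(np.zeros((2, 3)), _grp([0]), _grp([5], -1))


class TestDistanceSeries:
    def _traj(self, n=20, dt=100.0):
        atoms = (atom(1, "NZ", "LYS", seq=9), atom(2, "OD1", "ASP", seq=37))
        coords = np.zeros((n, 2, 3))
        coords[:, 1, 0] = 3.0 + np.arange(n)
        return Trajectory(Topology(atoms), coords, dt_ps=dt)

    def test_one_ns_exclusion_drops_ten_of_twenty(self):
        traj = self._traj()
        groups = identify_charged_groups(traj.topology)
        ds = distance_series(traj, groups[1], groups[0], exclude_ps=1000.0)
        assert len(ds) == 10
        assert ds.times_ps[0] == 1000.0

    def test_no_exclusion_keeps_all(self):
        traj = self._traj()
        g = identify_charged_groups(traj.topology)
        assert len(distance_series(traj, g[0], g[1], exclude_ps=0.0)) == 20

    def test_exclusion_beyond_duration_errors(self):
        traj = self._traj()
        g = identify_charged_groups(traj.topology)
        with pytest.raises(EmptyAnalysisError):
            distance_series(traj, g[0], g[1], exclude_ps=1e6)

    def test_labels_from_residues(self):
        traj = self._traj()
        g = identify_charged_groups(traj.topology)
        ds = distance_series(traj, g[0], g[1], exclude_ps=0.0)
        assert {ds.label_a, ds.label_b} == {"D37", "K9"}


class TestBridgeStateSeries:
    def _series(self, values, dt=10.0):
        return DistanceSeries(np.arange(len(values)) * dt, np.asarray(values, float))

    def test_hysteresis_rule_application(self):
        bss = bridge_state_series(self._series([3.5, 4.5, 5.5, 6.5, 5.5, 3.5]), 4.0, 6.0)
        assert bss.labels.tolist() == ["FORMED"] * 3 + ["BROKEN"] * 2 + ["FORMED"]

    def test_constant_low_all_formed(self):
        assert bridge_state_series(self._series([3.0] * 5)).formed.all()

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ParameterError):
            bridge_state_series(self._series([3.0]), d_on=6.0, d_off=4.0)

    @pytest.mark.parametrize("first,expected", [(4.9, True), (5.1, False)])
    def test_first_frame_midpoint_tiebreak(self, first, expected):
        bss = bridge_state_series(self._series([first, 5.0]), 4.0, 6.0)
        assert bss.formed[0] == expected
        assert bss.formed[1] == expected  # held through the gap

    def test_empty_series_errors(self):
        with pytest.raises(EmptyAnalysisError):
            bridge_state_series(self._series([]))

    @given(
        st.lists(st.floats(min_value=0.0, max_value=12.0, allow_nan=False), min_size=2, max_size=60)
    )
    def test_no_break_without_exceeding_d_off(self, values):
        """Hysteresis: a FORMED->BROKEN flip requires the distance to exceed d_off."""
        bss = bridge_state_series(self._series(values), 4.0, 6.0)
        v = np.asarray(values)
        flips = np.flatnonzero(bss.formed[:-1] & ~bss.formed[1:]) + 1
        assert (v[flips] > 6.0).all()

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=12.0, allow_nan=False).filter(
                lambda x: not 3.9 < x < 6.1
            ),
            min_size=1,
            max_size=60,
        )
    )
    def test_reduces_to_single_threshold_outside_gap(self, values):
        """With no values inside the gap, hysteresis equals one-cutoff calling."""
        bss = bridge_state_series(self._series(values), 4.0, 6.0)
        np.testing.assert_array_equal(bss.formed, np.asarray(values) < 4.0)
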