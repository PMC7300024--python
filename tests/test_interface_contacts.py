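import math

import numpy as np
import pytest

from tmrepack import interface_contacts as ic
from tmrepack.errors import NonUniformSpacingError, TmrepackError
from tmrepack.structure_io import AtomRecord, Frame, Trajectory


def _atoms(positions, elements=None, resseq_start=1, chain="A", per_residue=1):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    elements = elements or ["C"] * n
    return [
        AtomRecord(
            serial=i + 1,
            atom_name=elements[i] if elements[i] != "H" else f"H{i}",
            element=elements[i],
            residue_name="ALA",
            residue_seq=resseq_start + i // per_residue,
            chain_id=chain,
            position=tuple(positions[i]),
        )
        for i in range(n)
    ]


class TestCountContacts:
    def _pair_frame(self, distance):
        topo = _atoms([[0, 0, 0], [distance, 0, 0]], resseq_start=1)
        # put the two atoms in different residues
        topo[1] = AtomRecord(2, "C", "C", "ALA", 2, "A", (distance, 0.0, 0.0))
        frame = Frame(np.array([[0, 0, 0], [distance, 0, 0]], dtype=float))
        return frame, topo

    def test_within_cutoff(self):
        frame, topo = self._pair_frame(3.0)
        assert ic.count_contacts(frame, topo, [0], [1], cutoff=3.5) == 1

    def test_beyond_cutoff(self):
        frame, topo = self._pair_frame(3.6)
        assert ic.count_contacts(frame, topo, [0], [1], cutoff=3.5) == 0

    def test_overlapping_groups_rejected(self):
        frame, topo = self._pair_frame(3.0)
        with pytest.raises(TmrepackError, match="overlap"):
            ic.count_contacts(frame, topo, [0, 1], [1], cutoff=3.5)

    def test_brute_force_oracle(self, rng):
        # oracle: O(N^2) double loop
        pos_a = rng.uniform(0, 20, size=(200, 3))
        pos_b = rng.uniform(0, 20, size=(200, 3))
        pos = np.vstack([pos_a, pos_b])
        topo = _atoms(pos)
        frame = Frame(pos)
        idx_a = np.arange(200)
        idx_b = np.arange(200, 400)
        cutoff = 3.5
        expected = sum(
            1
            for i in range(200)
            for j in range(200)
            if np.linalg.norm(pos_a[i] - pos_b[j]) <= cutoff
        )
        assert ic.count_contacts(frame, topo, idx_a, idx_b, cutoff) == expected

    def test_hydrogens_excluded(self):
        pos = np.array([[0, 0, 0], [1.0, 0, 0], [3.0, 0, 0]], dtype=float)
        topo = _atoms(pos, elements=["C", "H", "C"])
        topo[2] = AtomRecord(3, "C", "C", "ALA", 2, "A", (3.0, 0.0, 0.0))
        frame = Frame(pos)
        assert ic.count_contacts(frame, topo, [0, 1], [2], cutoff=3.5) == 1


class TestContactFrequencies:
    def _two_residue_trajectory(self, pattern, near=3.0, far=8.0):
        """Two single-atom residues; distance follows the on/off pattern."""
        topo = [
            AtomRecord(1, "C", "C", "ALA", 1, "A", (0.0, 0.0, 0.0)),
            AtomRecord(2, "C", "C", "GLY", 2, "B", (0.0, 0.0, 0.0)),
        ]
        frames = [
            Frame(np.array([[0, 0, 0], [near if on else far, 0, 0]], dtype=float))
            for on in pattern
        ]
        return Trajectory(topo, frames)

    def test_duty_cycle_exact(self):
        pattern = [1, 1, 1, 1, 1, 1, 1, 0, 0, 0]
        traj = self._two_residue_trajectory(pattern)
        series = ic.contact_frequencies(traj, [0], [1], residue_cutoff=4.5)
        assert len(series) == 1
        assert series[0].frequency == 0.7

    def test_never_in_contact_absent(self):
        traj = self._two_residue_trajectory([0, 0, 0])
        assert ic.contact_frequencies(traj, [0], [1], residue_cutoff=4.5) == []

    def test_programmed_patterns(self):
        for pattern in ([1, 0, 1, 0], [1, 1, 0, 0, 0], [0, 1, 1, 1]):
            traj = self._two_residue_trajectory(pattern)
            series = ic.contact_frequencies(traj, [0], [1], residue_cutoff=4.5)
            assert series[0].frequency == pytest.approx(np.mean(pattern))
            np.testing.assert_array_equal(series[0].present, np.array(pattern, bool))


class TestSignificantPairs:
    KEY = ((("A", 1, "ALA"), ("B", 2, "GLY")),)

    def _one(self, wt, var, **kw):
        key = self.KEY[0]
        return ic.significant_pairs({key: wt} if wt else {}, {key: var} if var else {}, **kw)

    def test_paper_thresholds_pass(self):
        assert len(self._one(0.8, 0.6)) == 1  # freq >= 0.5, delta 0.2 > 0.1

    def test_small_delta_fails(self):
        assert self._one(0.55, 0.50) == []

    def test_new_contact_passes(self):
        out = self._one(0.0, 0.6)
        assert len(out) == 1 and out[0].delta == pytest.approx(0.6)

    def test_lost_contact_passes(self):
        out = self._one(0.6, 0.0)
        assert len(out) == 1 and out[0].delta == pytest.approx(-0.6)

    def test_symmetry_under_swap(self, rng):
        keys = [
            ((("A", i, "ALA"), ("B", i + 100, "GLY"))) for i in range(20)
        ]
        wt = {k: float(rng.uniform()) for k in keys}
        var = {k: float(rng.uniform()) for k in keys}
        fwd = ic.significant_pairs(wt, var)
        rev = ic.significant_pairs(var, wt)
        assert {p.residue_pair for p in fwd} == {p.residue_pair for p in rev}
        fwd_d = {p.residue_pair: p.delta for p in fwd}
        rev_d = {p.residue_pair: p.delta for p in rev}
        for k, d in fwd_d.items():
            assert rev_d[k] == pytest.approx(-d)

    def test_sorted_by_abs_delta(self, rng):
        keys = [((("A", i, "ALA"), ("B", i, "GLY"))) for i in range(10)]
        wt = {k: 0.9 for k in keys}
        var = {k: float(rng.uniform(0, 0.7)) for k in keys}
        out = ic.significant_pairs(wt, var)
        deltas = [abs(p.delta) for p in out]
        assert deltas == sorted(deltas, reverse=True)


def _hbond_system(d_a=2.9, angle=15.0):
    """Donor N at origin with H placed at the given H-D-A angle; acceptor O on x."""
    h = np.array(
        [math.cos(math.radians(angle)), math.sin(math.radians(angle)), 0.0]
    )
    pos = np.array([[0.0, 0.0, 0.0], h.tolist(), [d_a, 0.0, 0.0]])
    topo = [
        AtomRecord(1, "N", "N", "ALA", 1, "A", tuple(pos[0])),
        AtomRecord(2, "H", "H", "ALA", 1, "A", tuple(pos[1])),
        AtomRecord(3, "O", "O", "GLY", 2, "B", tuple(pos[2])),
    ]
    return Frame(pos), topo


class TestHbondDetect:
    def test_good_geometry_detected(self):
        frame, topo = _hbond_system(2.9, 15.0)
        assert ic.hbond_detect(frame, topo, [0], [2]) == [(0, 1, 2)]

    def test_bad_angle_rejected(self):
        frame, topo = _hbond_system(2.9, 45.0)
        assert ic.hbond_detect(frame, topo, [0], [2]) == []

    def test_too_far_rejected(self):
        frame, topo = _hbond_system(3.8, 5.0)
        assert ic.hbond_detect(frame, topo, [0], [2]) == []

    def test_donor_without_hydrogen_warns(self):
        frame, topo = _hbond_system()
        no_h = [topo[0], topo[2]]
        frame2 = Frame(np.array([topo[0].position, topo[2].position]))
        with pytest.warns(UserWarning, match="no bonded hydrogen"):
            out = ic.hbond_detect(frame2, no_h, [0], [1])
        assert out == []

    def test_random_sweep_against_oracle(self, rng):
        # oracle: direct distance + angle computation per candidate triple
        for _ in range(200):
            d_a = rng.uniform(2.0, 5.0)
            angle = rng.uniform(0.0, 90.0)
            frame, topo = _hbond_system(d_a, angle)
            got = ic.hbond_detect(frame, topo, [0], [2])
            expected = d_a <= 3.5 and angle <= 30.0 + 1e-12
            assert (len(got) == 1) == expected


class TestHbondStats:
    def _square_wave_trajectory(self, pattern, dt=10.0):
        frames = []
        for k, on in enumerate(pattern):
            frame, topo = _hbond_system(2.9 if on else 6.0, 10.0)
            frame.time = k * dt
            frames.append(frame)
        return Trajectory(topo, frames)

    def test_square_wave_lifetime(self):
        # dwells {3, 3} x 10 ps -> tau 30 ps
        traj = self._square_wave_trajectory([1, 1, 1, 0, 0, 0, 1, 1, 1, 0, 0, 0])
        stats_list, summary = ic.hbond_stats(traj, [0], [2])
        assert len(stats_list) == 1
        assert stats_list[0].tau_ps == pytest.approx(30.0)

    def test_free_energy_closed_form(self):
        # -(0.0019872 x 303) ln(30) = -2.0479 kcal/mol
        assert ic.hbond_free_energy(30.0) == pytest.approx(
            -(1.9872e-3 * 303.0) * math.log(30.0)
        )
        assert ic.hbond_free_energy(30.0) == pytest.approx(-2.05, abs=0.005)

    def test_never_bonded_absent(self):
        traj = self._square_wave_trajectory([0, 0, 0, 0])
        stats_list, summary = ic.hbond_stats(traj, [0], [2])
        assert stats_list == []
        assert summary.mean_count == 0.0

    def test_mean_count(self):
        traj = self._square_wave_trajectory([1, 1, 0, 0])
        _, summary = ic.hbond_stats(traj, [0], [2])
        assert summary.mean_count == 0.5

    def test_non_uniform_spacing_rejected(self):
        traj = self._square_wave_trajectory([1, 0, 1, 0])
        traj.frames[2].time = 23.0
        with pytest.raises(NonUniformSpacingError):
            ic.hbond_stats(traj, [0], [2])

    def test_tau_invariant_to_zero_padding(self):
        base = [1, 1, 0, 1, 1, 1, 0]
        padded = [0, 0] + base + [0, 0, 0]
        t1 = self._square_wave_trajectory(base)
        t2 = self._square_wave_trajectory(padded)
        s1, _ = ic.hbond_stats(t1, [0], [2])
        s2, _ = ic.hbond_stats(t2, [0], [2])
        assert s1[0].tau_ps == s2[0].tau_ps

    def test_dg_monotone_in_tau(self):
        taus = [1.0, 5.0, 30.0, 200.0]
        dgs = [ic.hbond_free_energy(t) for t in taus]
        assert all(a > b for a, b in zip(dgs, dgs[1:]))

    def test_dwell_oracle(self, rng):
        # oracle: itertools.groupby run lengths
        from itertools import groupby

        for _ in range(50):
            pattern = rng.integers(0, 2, size=30).astype(bool)
            runs = [len(list(g)) for v, g in groupby(pattern) if v]
            expected = float(np.mean(runs)) if runs else 0.0
            assert ic.mean_dwell_length(pattern) == expected
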