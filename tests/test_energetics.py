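"""Switching function, pair energies, and regional energy sums."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

import helixscope as hx
from helixscope.errors import HelixscopeError
from helixscope.energetics import NonbondedOptions

OPTS = NonbondedOptions()


def random_fixture(rng, n_a=10, n_b=20, spread=14.0, box=None):
    """Two disjoint random atom groups with random LJ/charge parameters."""
    atoms = []
    for i in range(n_a + n_b):
        seg = "AAAA" if i < n_a else "BBBB"
        atoms.append(hx.AtomRecord(
            "X", "RES", i + 1, seg, mass=10.0,
            charge=float(rng.uniform(-0.8, 0.8)),
            lj_epsilon=float(rng.uniform(0.01, 0.6)),
            lj_rmin_half=float(rng.uniform(1.2, 2.4))))
    top = hx.Topology(atoms)
    coords = rng.uniform(0.0, spread, size=(n_a + n_b, 3))
    frame = hx.Frame(coords, box=box)
    traj = hx.Trajectory(top, [frame])
    return traj, hx.select(top, "segid AAAA"), hx.select(top, "segid BBBB")


class TestSwitchingFactor:
    def test_below_switch_on_is_one(self):
        assert hx.switching_factor(9.0, OPTS) == 1.0

    def test_at_cutoff_is_zero(self):
        assert hx.switching_factor(12.0, OPTS) == 0.0

    def test_closed_form_at_11(self):
        c2, s2, r2 = 144.0, 100.0, 121.0
        expected = (c2 - r2) ** 2 * (c2 + 2 * r2 - 3 * s2) / (c2 - s2) ** 3
        assert hx.switching_factor(11.0, OPTS) == pytest.approx(expected,
                                                                rel=1e-14)

    def test_continuity_at_both_boundaries(self):
        for edge in (10.0, 12.0):
            grid = edge + np.linspace(-5e-4, 5e-4, 11)
            sw = hx.switching_factor(grid, OPTS)
            assert np.max(np.abs(np.diff(sw))) < 1e-6

    def test_monotone_within_window(self):
        r = np.linspace(10.0, 12.0, 500)
        sw = hx.switching_factor(r, OPTS)
        assert np.all(np.diff(sw) <= 0)
        assert np.all((sw >= 0) & (sw <= 1))


class TestPairEnergy:
    def _atom(self, charge=0.0, eps=0.2, rmin_half=1.9):
        return hx.AtomRecord("X", "RES", 1, "A", mass=1.0, charge=charge,
                             lj_epsilon=eps, lj_rmin_half=rmin_half)

    def test_lj_minimum_is_minus_epsilon(self):
        a = self._atom(eps=0.25, rmin_half=1.8)
        b = self._atom(eps=0.16, rmin_half=2.0)
        rmin = 1.8 + 2.0
        elec, vdw = hx.pair_energy(a, b, rmin, OPTS)
        assert vdw == -np.sqrt(0.25 * 0.16)
        assert elec == 0.0

    def test_coulomb_arithmetic(self):
        a = self._atom(charge=0.5, eps=0.0)
        b = self._atom(charge=0.5, eps=0.0)
        elec, vdw = hx.pair_energy(a, b, 5.0, OPTS)
        assert elec == pytest.approx(332.0636 * 0.25 / 5.0, rel=1e-12)
        assert vdw == 0.0

    def test_zero_distance_rejected(self):
        a = self._atom()
        with pytest.raises(HelixscopeError):
            hx.pair_energy(a, a, 0.0, OPTS)

    def test_beyond_cutoff_is_zero(self):
        a = self._atom(charge=0.3)
        assert hx.pair_energy(a, a, 12.5, OPTS) == (0.0, 0.0)


class TestInteractionEnergy:
    def test_kdtree_equals_naive_on_random_fixtures(self, rng):
        for k in range(10):
            box = np.array([20.0, 20.0, 20.0]) if k % 2 else None
            traj, sel_a, sel_b = random_fixture(rng, box=box)
            fast = hx.interaction_energy(traj, sel_a, sel_b, OPTS)
            slow = hx.interaction_energy(traj, sel_a, sel_b, OPTS,
                                         method="naive")
            for col in ("elec", "vdw", "total"):
                np.testing.assert_allclose(fast[col], slow[col], rtol=1e-10,
                                           atol=1e-12)

    def test_symmetry_in_selection_order(self, rng):
        traj, sel_a, sel_b = random_fixture(rng)
        ab = hx.interaction_energy(traj, sel_a, sel_b, OPTS)
        ba = hx.interaction_energy(traj, sel_b, sel_a, OPTS)
        np.testing.assert_allclose(ab["total"], ba["total"], rtol=1e-12)

    def test_distant_groups_contribute_zero(self, rng):
        traj, sel_a, sel_b = random_fixture(rng, spread=5.0)
        shifted = traj.frames[0].coordinates.copy()
        shifted[sel_b.array] += 100.0
        far = hx.Trajectory(traj.topology, [hx.Frame(shifted)])
        out = hx.interaction_energy(far, sel_a, sel_b, OPTS)
        assert out["total"].to_numpy() == pytest.approx(0.0, abs=1e-15)

    def test_rigid_motion_invariance(self, rng):
        traj, sel_a, sel_b = random_fixture(rng)
        base = hx.interaction_energy(traj, sel_a, sel_b, OPTS)["total"][0]
        rot = Rotation.random(random_state=np.random.RandomState(3))
        moved = hx.Trajectory(traj.topology, [hx.Frame(
            rot.apply(traj.frames[0].coordinates) + np.array([3.0, -7.0, 1.0]))])
        after = hx.interaction_energy(moved, sel_a, sel_b, OPTS)["total"][0]
        assert after == pytest.approx(base, rel=1e-9)

    def test_overlapping_selections_rejected(self, rng):
        traj, sel_a, _ = random_fixture(rng)
        with pytest.raises(HelixscopeError, match="overlap"):
            hx.interaction_energy(traj, sel_a, sel_a, OPTS)

    def test_doubling_charges_quadruples_elec(self, rng):
        traj, sel_a, sel_b = random_fixture(rng)
        base = hx.interaction_energy(traj, sel_a, sel_b, OPTS)
        doubled_atoms = [
            hx.AtomRecord(a.atom_name, a.residue_name, a.residue_id,
                          a.segment_id, mass=a.mass, charge=2 * a.charge,
                          lj_epsilon=a.lj_epsilon,
                          lj_rmin_half=a.lj_rmin_half)
            for a in traj.topology]
        traj2 = hx.Trajectory(hx.Topology(doubled_atoms), traj.frames)
        out = hx.interaction_energy(traj2, sel_a, sel_b, OPTS)
        np.testing.assert_allclose(out["elec"], 4 * base["elec"], rtol=1e-12)
        np.testing.assert_allclose(out["vdw"], base["vdw"], rtol=1e-12)

    def test_minimum_image_wraps_across_box(self):
        atoms = [hx.AtomRecord("X", "RES", i + 1, "S" + str(i), mass=1.0,
                               charge=0.5, lj_epsilon=0.1, lj_rmin_half=1.5)
                 for i in range(2)]
        top = hx.Topology(atoms)
        box = np.array([30.0, 30.0, 30.0])
        coords = np.array([[1.0, 15.0, 15.0], [29.0, 15.0, 15.0]])
        traj = hx.Trajectory(top, [hx.Frame(coords, box=box)])
        a = hx.select(top, "segid S0")
        b = hx.select(top, "segid S1")
        out = hx.interaction_energy(traj, a, b, OPTS)
        # minimum-image distance is 2 Å, not 28 Å
        expected_elec = 332.0636 * 0.25 / 2.0
        assert out["elec"][0] == pytest.approx(expected_elec, rel=1e-10)
        no_pbc = hx.interaction_energy(
            traj, a, b, NonbondedOptions(use_minimum_image=False))
        assert no_pbc["total"][0] == 0.0


class TestInternalEnergy:
    def _chain_traj(self, rng, n=8):
        atoms = [hx.AtomRecord("CA", "ALA", i + 1, "PROT", mass=12.0,
                               charge=float(rng.uniform(-0.3, 0.3)),
                               lj_epsilon=0.1, lj_rmin_half=1.9)
                 for i in range(n)]
        coords = np.cumsum(rng.uniform(2.5, 3.8, size=(n, 1))
                           * rng.normal(size=(n, 3)) * 0.4 + 3.0, axis=0)
        return hx.Trajectory(hx.Topology(atoms), [hx.Frame(coords)])

    def test_matches_brute_force_with_exclusions(self, rng):
        traj = self._chain_traj(rng)
        sel = hx.select(traj.topology, "segid PROT")
        out = hx.internal_energy(traj, sel, OPTS)
        # independent O(N²) loop with |Δresid| < 3 exclusions
        coords = traj.frames[0].coordinates
        top = traj.topology
        elec = vdw = 0.0
        for i in range(len(top)):
            for j in range(i + 1, len(top)):
                if abs(top[i].residue_id - top[j].residue_id) < 3:
                    continue
                r = float(np.linalg.norm(coords[i] - coords[j]))
                if r > OPTS.cutoff:
                    continue
                e, v = hx.pair_energy(top[i], top[j], r, OPTS)
                elec += e
                vdw += v
        assert out["elec"][0] == pytest.approx(elec, rel=1e-10, abs=1e-12)
        assert out["vdw"][0] == pytest.approx(vdw, rel=1e-10, abs=1e-12)

    def test_kdtree_equals_naive(self, rng):
        traj = self._chain_traj(rng, n=12)
        sel = hx.select(traj.topology, "segid PROT")
        fast = hx.internal_energy(traj, sel, OPTS)
        slow = hx.internal_energy(traj, sel, OPTS, method="naive")
        np.testing.assert_allclose(fast["total"], slow["total"], rtol=1e-10)

    def test_rigid_trajectory_constant_series(self, rng):
        traj = self._chain_traj(rng)
        frames = [traj.frames[0],
                  hx.Frame(traj.frames[0].coordinates + 5.0),
                  hx.Frame(Rotation.from_euler("z", 60, degrees=True).apply(
                      traj.frames[0].coordinates))]
        moved = hx.Trajectory(traj.topology, frames)
        sel = hx.select(moved.topology, "segid PROT")
        out = hx.internal_energy(moved, sel, OPTS)["total"]
        assert np.ptp(out) < 1e-9 * max(1.0, abs(out[0]))

    def test_singleton_rejected(self, rng):
        traj = self._chain_traj(rng)
        sel = hx.select(traj.topology, "resid 1")
        with pytest.raises(HelixscopeError):
            hx.internal_energy(traj, sel, OPTS)

    def test_tmd_lipid_energy_more_negative_than_termini(self, small_traj):
        top = small_traj.topology
        mem = hx.select(top, "segid MEMB and name P")
        tmd = hx.interaction_energy(
            small_traj, hx.select(top, "resid 57 to 82 and name CA"), mem,
            OPTS)["total"].mean()
        n_hel = hx.interaction_energy(
            small_traj, hx.select(top, "resid 10 to 30 and name CA"), mem,
            OPTS)["total"].mean()
        c_hel = hx.interaction_energy(
            small_traj, hx.select(top, "resid 90 to 95 and name CA"), mem,
            OPTS)["total"].mean()
        assert tmd < n_hel and tmd < c_hel
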