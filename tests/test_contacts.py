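import numpy as np
import pytest

import duplexmd as dm
from duplexmd.contacts import ContactConfig, census_frame
from duplexmd.structure_io import AtomRecord, Topology
from conftest import random_rigid_motion, rigid_copy

from _oracles import recount_population


def _patched(placements, n_frames=1, jitter=0.0, seed=0):
    duplex = dm.make_duplex(dm.DuplexSpec())
    merged = dm.make_protein_patch(dm.DomainSpec(residues=placements), duplex)
    if n_frames == 1:
        return merged
    return dm.make_trajectory(merged, dm.MotionSpec(
        n_frames=n_frames, dt=10.0, jitter_sigma=jitter, seed=seed))


class TestHydrophobic:
    @pytest.mark.parametrize("offset,expected_pop", [(6.4, 1.0), (6.6, None)])
    def test_cutoff_boundary_is_strict(self, offset, expected_pop):
        traj = _patched([dm.ResiduePlacement("ILE", 300, ("A", 5), offset)])
        found = {(c.protein_partner[1], c.rna_partner): c.population
                 for c in dm.hydrophobic_contacts(traj)}
        key = (300, ("A", 5, "A"))
        if expected_pop is None:
            assert key not in found
        else:
            assert found[key] == expected_pop

    def test_population_counts_match_per_frame_recount(self):
        """26 in-range frames out of 50 give population 0.52, surviving the filter."""
        traj = _patched([dm.ResiduePlacement("ILE", 300, ("A", 5), 6.0)])
        coords = np.repeat(traj.coords, 50, axis=0).copy()
        res_idx = traj.topology.residue_atoms("K", 300)
        coords[26:, res_idx, :] += np.array([50.0, 0.0, 0.0])  # out of range after frame 26
        traj50 = dm.Trajectory(traj.topology, coords, dt=10.0)
        census = dm.hydrophobic_contacts(traj50)
        rec = next(c for c in census if c.protein_partner[1] == 300
                   and c.rna_partner[:2] == ("A", 5))
        # independent recount from raw distances
        from duplexmd import chemistry
        sc = chemistry.sidechain_atom_indices(traj50.topology, res_idx)
        base = chemistry.base_atom_indices(
            traj50.topology, traj50.topology.residue_atoms("A", 5))
        m_sc = traj50.topology.masses[sc]
        m_b = traj50.topology.masses[base]
        d = [np.linalg.norm((f[sc] * m_sc[:, None]).sum(0) / m_sc.sum()
                            - (f[base] * m_b[:, None]).sum(0) / m_b.sum())
             for f in coords]
        assert rec.population == recount_population(d, 6.5) == 0.52
        assert rec in dm.filter_by_population(census, 0.5)


class TestElectrostatic:
    @pytest.mark.parametrize("offset,present", [(10.9, True), (11.1, False)])
    def test_cutoff_boundary(self, offset, present):
        traj = _patched([dm.ResiduePlacement("ARG", 310, ("A", 5), offset,
                                             anchor_atom="P")])
        hits = [(c.protein_partner[1], c.rna_partner[:2])
                for c in dm.electrostatic_contacts(traj)]
        assert ((310, ("A", 5)) in hits) == present

    def test_fourteen_charged_residues_all_survive_filter(self):
        """14 Arg/Lys parked in range yield 14 charged residues above 50%."""
        placements = []
        for k in range(14):
            resname = "ARG" if k % 2 == 0 else "LYS"
            chain, resid = ("A", k + 2) if k < 7 else ("B", k - 4)
            placements.append(dm.ResiduePlacement(resname, 400 + k, (chain, resid),
                                                  9.5, anchor_atom="P"))
        traj = _patched(placements, n_frames=20, jitter=0.1)
        kept = dm.filter_by_population(dm.electrostatic_contacts(traj), 0.5)
        residues = {c.protein_partner for c in kept}
        assert len(residues) == 14

    def test_5prime_terminal_nucleotides_skipped(self):
        traj = _patched([dm.ResiduePlacement("ARG", 310, ("A", 5), 10.0,
                                             anchor_atom="P")])
        partners = {c.rna_partner[:2] for c in dm.electrostatic_contacts(traj)}
        assert ("A", 1) not in partners and ("B", 1) not in partners


class TestHydrogenBonds:
    @staticmethod
    def _gly_near_u(d):
        """A glycine whose backbone O sits d Å from a uracil N3."""
        atoms = [
            AtomRecord(1, "C5'", "U", 1, "B", "C", 12.011),
            AtomRecord(2, "N1", "U", 1, "B", "N", 14.007),
            AtomRecord(3, "C2", "U", 1, "B", "C", 12.011),
            AtomRecord(4, "N3", "U", 1, "B", "N", 14.007),
            AtomRecord(5, "C4", "U", 1, "B", "C", 12.011),
            AtomRecord(6, "C5", "U", 1, "B", "C", 12.011),
            AtomRecord(7, "N", "GLY", 10, "K", "N", 14.007),
            AtomRecord(8, "CA", "GLY", 10, "K", "C", 12.011),
            AtomRecord(9, "C", "GLY", 10, "K", "C", 12.011),
            AtomRecord(10, "O", "GLY", 10, "K", "O", 15.999),
        ]
        xyz = np.array([
            [-4.0, 0, 0], [-1.5, 1.0, 0], [-1.5, -1.0, 0], [0.0, 0.0, 0.0],
            [-2.5, 0.0, 1.0], [-2.5, 0.0, -1.0],
            [d + 3.0, 1.5, 0], [d + 2.0, 0.5, 0], [d + 1.0, 1.0, 0], [d, 0.0, 0.0],
        ])
        return dm.Trajectory(Topology(atoms), xyz[None], dt=10.0)

    @pytest.mark.parametrize("d,present", [(3.4, True), (3.6, False)])
    def test_distance_only_mode_without_hydrogens(self, d, present):
        traj = self._gly_near_u(d)
        found = bool(dm.hydrogen_bonds(traj))
        assert found == present

    def test_forty_percent_occupancy_fails_default_filter(self):
        """A bond holding in 40% of frames mirrors a marginally stable contact."""
        traj = self._gly_near_u(3.2)
        coords = np.repeat(traj.coords, 50, axis=0).copy()
        o_idx = 9  # backbone O
        coords[20:, o_idx, :] += np.array([10.0, 0.0, 0.0])
        traj50 = dm.Trajectory(traj.topology, coords, dt=10.0)
        census = dm.hydrogen_bonds(traj50)
        assert len(census) == 1
        assert census[0].population == pytest.approx(0.40)
        assert dm.filter_by_population(census, 0.5) == []


class TestFilterAndCompare:
    def test_threshold_is_strictly_greater_than(self):
        mk = lambda pop, rid: dm.ContactSummary(
            "hbond", ("K", rid, "SER"), ("A", 1, "A"),
            np.array([True] * int(pop * 100) + [False] * (100 - int(pop * 100))))
        contacts = [mk(0.50, 1), mk(0.52, 2), mk(1.0, 3)]
        kept = dm.filter_by_population(contacts, 0.5)
        assert [c.protein_partner[1] for c in kept] == [3, 2]
        assert dm.filter_by_population([], 0.5) == []

    def test_identical_censuses_all_common(self):
        traj = _patched([dm.ResiduePlacement("ILE", 300, ("A", 5), 6.0)])
        census = dm.hydrophobic_contacts(traj)
        table = dm.compare_censuses(census, census)
        assert (table["status"] == "common").all()
        np.testing.assert_allclose(table["population_a"], table["population_b"])

    def test_disjoint_censuses_share_nothing(self):
        t1 = _patched([dm.ResiduePlacement("ILE", 300, ("A", 5), 6.0)])
        t2 = _patched([dm.ResiduePlacement("VAL", 301, ("B", 5), 6.0)])
        table = dm.compare_censuses(dm.hydrophobic_contacts(t1),
                                    dm.hydrophobic_contacts(t2))
        assert not (table["status"] == "common").any()

    def test_two_shared_electrostatic_records_found_common(self):
        """Two conserved Arg anchors shared between ensembles show as common."""
        shared = [dm.ResiduePlacement("ARG", 315, ("A", 4), 9.0, anchor_atom="P"),
                  dm.ResiduePlacement("ARG", 317, ("A", 8), 9.0, anchor_atom="P")]
        only1 = [dm.ResiduePlacement("LYS", 320, ("B", 5), 9.0, anchor_atom="P")]
        t1 = _patched(shared + only1)
        t2 = _patched(shared)
        a = dm.filter_by_population(dm.electrostatic_contacts(t1), 0.5)
        b = dm.filter_by_population(dm.electrostatic_contacts(t2), 0.5)
        table = dm.compare_censuses(a, b)
        common = table[table["status"] == "common"]
        assert set(common["protein_resid"]) == {315, 317}
        assert (table.loc[table["protein_resid"] == 320, "status"] == "a_only").all()


class TestCensusProperties:
    def test_occupancy_invariant_under_frame_reordering(self):
        traj = _patched([dm.ResiduePlacement("ILE", 300, ("A", 5), 6.3)],
                        n_frames=30, jitter=0.25, seed=4)
        perm = np.random.default_rng(0).permutation(traj.n_frames)
        shuffled = dm.Trajectory(traj.topology, traj.coords[perm], dt=traj.dt)
        pops = lambda t: sorted((c.pair_key, c.population)
                                for c in dm.hydrophobic_contacts(t))
        assert pops(traj) == pops(shuffled)

    def test_contact_set_monotone_in_cutoff(self):
        traj = _patched([dm.ResiduePlacement("ILE", 300, ("A", 5), 6.3),
                         dm.ResiduePlacement("VAL", 301, ("B", 4), 6.9)],
                        n_frames=30, jitter=0.3, seed=5)
        small = {c.pair_key for c in dm.hydrophobic_contacts(
            traj, ContactConfig(hydrophobic_cutoff=6.5))}
        large = {c.pair_key for c in dm.hydrophobic_contacts(
            traj, ContactConfig(hydrophobic_cutoff=7.0))}
        assert small <= large

    def test_census_invariant_under_global_rigid_motion(self):
        traj = _patched([dm.ResiduePlacement("ILE", 300, ("A", 5), 6.3),
                         dm.ResiduePlacement("ARG", 310, ("B", 4), 10.0,
                                             anchor_atom="P")],
                        n_frames=20, jitter=0.2, seed=6)
        R, t = random_rigid_motion(np.random.default_rng(1))
        moved = rigid_copy(traj, R, t)
        for fn in (dm.hydrophobic_contacts, dm.electrostatic_contacts, dm.hydrogen_bonds):
            a = sorted((c.pair_key, c.population) for c in fn(traj))
            b = sorted((c.pair_key, c.population) for c in fn(moved))
            assert a == b

    def test_census_frame_columns(self):
        traj = _patched([dm.ResiduePlacement("ILE", 300, ("A", 5), 6.0)])
        df = census_frame(dm.hydrophobic_contacts(traj))
        assert list(df.columns) == ["class", "protein_chain", "protein_resid",
                                    "protein_resname", "rna_chain", "rna_resid",
                                    "base", "population", "n_frames"]
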