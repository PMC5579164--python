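"""Contact counting against brute-force enumeration, normalization, SDs, PDB."""

import warnings

import numpy as np
import pandas as pd
import pytest

from annulipid.contacts import (
    ContactTable,
    contact_sd_across_systems,
    count_contacts,
    map_contacts_to_structure,
    normalize_contacts,
)
from annulipid.core import min_image_displacement
from annulipid.synth import MembraneSpec, SquareWell, simulate, write_fixture

from conftest import make_table, make_traj


def _two_bead_system(separation):
    table = make_table([(0, 0, "PROTEIN", "protein", 1),
                        (1, 1, "POPC", "headgroup", 2)])
    coords = np.zeros((1, 2, 3))
    coords[0, 0] = [5.0, 5.0, 5.0]
    coords[0, 1] = [5.0 + separation, 5.0, 5.0]
    return make_traj(coords), table


class TestCounting:
    def test_within_cutoff(self):
        traj, table = _two_bead_system(0.5)
        ct = count_contacts(traj, table, ["POPC"], cutoff=0.6)
        assert ct.table.loc[1, "POPC"] == 1

    def test_outside_cutoff(self):
        traj, table = _two_bead_system(0.5)
        ct = count_contacts(traj, table, ["POPC"], cutoff=0.4)
        assert ct.table.loc[1, "POPC"] == 0

    def test_one_contact_per_molecule_per_frame(self):
        # two beads of the same lipid within cutoff still count once
        table = make_table([(0, 0, "PROTEIN", "protein", 1),
                            (1, 1, "POPC", "headgroup", 2),
                            (2, 1, "POPC", "tail", 2)])
        coords = np.zeros((1, 3, 3))
        coords[0] = [[5, 5, 5], [5.3, 5, 5], [5, 5.3, 5]]
        traj = make_traj(coords)
        ct = count_contacts(traj, table, ["POPC"], bead_scope="all_lipid_beads",
                            cutoff=0.6)
        assert ct.table.loc[1, "POPC"] == 1

    def test_five_frame_toy_matches_brute_force(self):
        rng = np.random.default_rng(50)
        records, coords = [], []
        pid = 0
        for res in range(3):  # 3 protein residues, 2 beads each
            for b in range(2):
                records.append((pid, 0, "PROTEIN", "protein", res + 1))
                pid += 1
        for mol in range(6):  # 6 lipids, 2 beads each
            sp = "POPS" if mol % 2 else "POPC"
            records.append((pid, mol + 1, sp, "headgroup", 10 + mol))
            pid += 1
            records.append((pid, mol + 1, sp, "tail", 10 + mol))
            pid += 1
        table = make_table(records)
        coords = rng.random((5, pid, 3)) * 4.0
        traj = make_traj(coords, box=(4.0, 4.0, 4.0))
        cutoff = 0.9
        ct = count_contacts(traj, table, ["POPC", "POPS"],
                            bead_scope="all_lipid_beads", cutoff=cutoff)
        # exhaustive enumeration with minimum image
        df = table.df
        expected = {}
        for f in range(5):
            seen = set()
            for _, prow in df[df.species == "PROTEIN"].iterrows():
                for _, lrow in df[df.species != "PROTEIN"].iterrows():
                    d = min_image_displacement(coords[f, prow.particle_id],
                                               coords[f, lrow.particle_id],
                                               np.array([4.0, 4.0, 4.0]))
                    if np.linalg.norm(d) < cutoff:
                        key = (prow.residue_id, lrow.molecule_id)
                        if key not in seen:
                            seen.add(key)
                            k = (prow.residue_id, lrow.species)
                            expected[k] = expected.get(k, 0) + 1
        for (res, sp), n in expected.items():
            assert ct.table.loc[res, sp] == n
        assert ct.table.to_numpy().sum() == sum(expected.values())

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(51)
        records = [(0, 0, "PROTEIN", "protein", 1)]
        for m in range(8):
            records.append((m + 1, m + 1, "POPC", "headgroup", m + 2))
        table = make_table(records)
        traj = make_traj(rng.random((3, 9, 3)) * 5, box=(5.0, 5.0, 5.0))
        prev = 0
        for cutoff in [0.3, 0.6, 0.9, 1.5]:
            n = count_contacts(traj, table, ["POPC"], cutoff=cutoff,
                               bead_scope="headgroup_only").table.to_numpy().sum()
            assert n >= prev
            prev = n

    def test_empty_selection_errors(self):
        traj, table = _two_bead_system(0.5)
        with pytest.raises(ValueError):
            count_contacts(traj, table, [], cutoff=0.6)
        with pytest.raises(ValueError):
            count_contacts(traj, table, ["POPE"], cutoff=0.6)


class TestNormalization:
    def _ct(self, values):
        return ContactTable(pd.DataFrame({"POPC": values},
                                         index=pd.Index([1, 2, 3][:len(values)],
                                                        name="residue_id")))

    def test_division_by_global_max(self):
        out = normalize_contacts(self._ct([2, 4, 8]))
        np.testing.assert_allclose(out.table["POPC"], [0.25, 0.5, 1.0])

    def test_single_nonzero(self):
        out = normalize_contacts(self._ct([0, 0, 7]))
        assert out.table["POPC"].tolist() == [0.0, 0.0, 1.0]

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning, match="zero"):
            out = normalize_contacts(self._ct([0, 0, 0]))
        assert (out.table == 0).all().all()

    def test_idempotent(self):
        once = normalize_contacts(self._ct([2, 4, 8]))
        twice = normalize_contacts(once)
        pd.testing.assert_frame_equal(once.table, twice.table)

    def test_shared_scale_across_species(self):
        ct = ContactTable(pd.DataFrame({"POPC": [2, 4], "POPS": [8, 1]},
                                       index=pd.Index([1, 2], name="residue_id")))
        out = normalize_contacts(ct)
        assert out.table.loc[1, "POPS"] == 1.0
        assert out.table.loc[2, "POPC"] == 0.5  # normalized by the POPS peak


class TestCrossSystemSd:
    def _t(self, values):
        return pd.DataFrame({"POPC": values},
                            index=pd.Index([1, 2], name="residue_id"))

    def test_identical_systems_zero(self):
        sd = contact_sd_across_systems([self._t([0.5, 1]), self._t([0.5, 1]),
                                        self._t([0.5, 1])])
        assert (sd == 0).all().all()

    def test_population_convention(self):
        sd = contact_sd_across_systems([self._t([0.0, 0]), self._t([0.5, 0]),
                                        self._t([1.0, 0])])
        assert sd.loc[1, "POPC"] == pytest.approx(np.std([0, 0.5, 1.0]))

    def test_mismatched_residues_error(self):
        other = pd.DataFrame({"POPC": [1.0]},
                             index=pd.Index([9], name="residue_id"))
        with pytest.raises(ValueError, match="differs"):
            contact_sd_across_systems([self._t([0, 1]), other])

    def test_synthetic_triplicate_positive_sds(self):
        tables = []
        for seed in (70, 71, 72):
            spec = MembraneSpec(compositions={"outer": {"POPS": 80},
                                              "inner": {"POPS": 80}},
                                protein_radius=0.8, n_ring_beads=6,
                                wells={"POPS": SquareWell(1.5, 1.0)},
                                n_frames=80, seed=seed)
            traj, table, _ = simulate(spec)
            ct = normalize_contacts(count_contacts(traj, table, ["POPS"],
                                                   cutoff=0.8))
            tables.append(ct)
        sd = contact_sd_across_systems(tables)
        contacted = tables[0].table["POPS"] > 0
        assert (sd.loc[contacted, "POPS"] > 0).all()


class TestStructureMapping:
    def test_bfactor_round_trip(self, tmp_path):
        spec = MembraneSpec(compositions={"outer": {"POPC": 10},
                                          "inner": {"POPC": 10}},
                            protein_radius=0.8, n_ring_beads=4,
                            n_frames=3, seed=80)
        traj, table, truth = simulate(spec)
        paths = write_fixture(traj, table, truth, tmp_path)
        prot_res = sorted(table.df[table.df.species == "PROTEIN"]
                          ["residue_id"].unique())
        values = np.linspace(0, 1, len(prot_res))
        ct = ContactTable(pd.DataFrame({"POPC": values},
                                       index=pd.Index(prot_res,
                                                      name="residue_id")),
                          normalized=True)
        pdb = tmp_path / "contacts.pdb"
        map_contacts_to_structure(ct, paths["gro"], pdb)
        import MDAnalysis as mda
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(pdb))
        got = {int(r.resid): float(r.atoms.tempfactors[0]) for r in u.residues
               if int(r.resid) in set(prot_res)}
        for res, v in zip(prot_res, values):
            assert got[res] == pytest.approx(v, abs=5e-3)  # PDB: 2 decimals

    def test_unresolvable_residue_errors(self, tmp_path, fixture_dir):
        ct = ContactTable(pd.DataFrame({"POPC": [1.0]},
                                       index=pd.Index([99999],
                                                      name="residue_id")))
        with pytest.raises(ValueError, match="not in topology"):
            map_contacts_to_structure(ct, fixture_dir["paths"]["gro"],
                                      tmp_path / "x.pdb")


def test_enriched_species_makes_more_contacts():
    # PS sits in a well at the protein surface; PC does not
    spec = MembraneSpec(compositions={"outer": {"POPC": 80, "POPS": 80},
                                      "inner": {"POPC": 80, "POPS": 80}},
                        protein_radius=0.8, n_ring_beads=8,
                        wells={"POPS": SquareWell(1.5, 1.5)},
                        n_frames=100, seed=81)
    traj, table, _ = simulate(spec)
    ct = count_contacts(traj, table, ["POPC", "POPS"], cutoff=0.8)
    assert ct.table["POPS"].sum() > ct.table["POPC"].sum()
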