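"""Periodic geometry, reference frame, COM distances and file ingestion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from annulipid.core import (
    ReferenceFrame,
    TopologyError,
    UnsupportedBoxError,
    com_z_distance,
    lateral_distance_to_protein,
    lateral_distances,
    load_trajectory,
    min_image_displacement,
    periodic_mean,
    reference_frame,
    wrap_coords,
)

from conftest import make_table, make_traj


class TestMinImage:
    @pytest.mark.parametrize("a, b, expected", [
        ((0.5, 0.5), (18.5, 0.5), (-1.0, 0.0)),   # wraps, not +18
        ((1.0, 1.0), (1.0, 1.0), (0.0, 0.0)),
        ((1.0, 1.0), (2.0, 3.0), (1.0, 2.0)),     # within half-box
    ])
    def test_examples(self, a, b, expected):
        d = min_image_displacement(a, b, (19.0, 19.0))
        np.testing.assert_allclose(d, expected, atol=1e-12)

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=2),
           st.lists(st.floats(-100, 100), min_size=2, max_size=2),
           st.floats(0.5, 50))
    @settings(max_examples=200, deadline=None)
    def test_antisymmetric_and_in_range(self, a, b, L):
        d1 = min_image_displacement(a, b, L)
        d2 = min_image_displacement(b, a, L)
        assert np.all(d1 >= -L / 2) and np.all(d1 < L / 2)
        # antisymmetry up to the half-box boundary convention
        wrapped_sum = min_image_displacement((0.0, 0.0), d1 + d2, L)
        np.testing.assert_allclose(wrapped_sum, 0.0, atol=1e-9)

    def test_rejects_bad_box(self):
        with pytest.raises(ValueError):
            min_image_displacement((0, 0), (1, 1), (0.0, 1.0))


def test_periodic_mean_straddling_boundary():
    # cloud split across the wrap point averages near 0, not near L/2
    x = np.array([0.1, 9.9])
    assert min(periodic_mean(x, 10.0), 10 - periodic_mean(x, 10.0)) < 1e-9


class TestLateralDistance:
    def _ref(self, n_frames, center=(9.5, 9.5)):
        return ReferenceFrame(np.tile(center, (n_frames, 1)), np.zeros(n_frames))

    def test_at_center_is_zero(self):
        traj = make_traj([[[9.5, 9.5, 5.0]]])
        assert lateral_distance_to_protein(traj, self._ref(1), 0, 0) == 0.0

    def test_pythagoras(self):
        traj = make_traj([[[9.5 + 3, 9.5 + 4, 5.0]]])
        assert lateral_distance_to_protein(traj, self._ref(1), 0, 0) == \
            pytest.approx(5.0)

    def test_minimum_image(self):
        traj = make_traj([[[0.5 + 18, 0.5, 5.0]]])
        ref = ReferenceFrame([[0.5, 0.5]], [0.0])
        assert lateral_distance_to_protein(traj, ref, 0, 0) == pytest.approx(1.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        coords = rng.random((3, 10, 3)) * 19
        traj = make_traj(coords)
        ref = ReferenceFrame(rng.random((3, 2)) * 19, np.zeros(3))
        d0 = lateral_distances(traj, ref, np.arange(10))
        shift = np.array([7.3, 12.9, 0.0])
        traj2 = make_traj(wrap_coords(coords + shift, np.array([19.0, 19.0, 10.0])))
        ref2 = ReferenceFrame(wrap_coords(ref.protein_center_xy + shift[:2], 19.0),
                              ref.midplane_z)
        d1 = lateral_distances(traj2, ref2, np.arange(10))
        np.testing.assert_allclose(d0, d1, atol=1e-9)


class TestComZ:
    def _system(self):
        # 4-bead bilayer (z = 4, 4, 6, 6) + 1 probe bead
        table = make_table([
            (0, 0, "POPC", "headgroup", 1),
            (1, 1, "POPC", "headgroup", 2),
            (2, 2, "POPC", "headgroup", 3),
            (3, 3, "POPC", "headgroup", 4),
            (4, 4, "PROTEIN", "protein", 5),
        ])
        return table

    def test_constant_offset(self):
        table = self._system()
        coords = np.zeros((3, 5, 3))
        coords[:, :4, 2] = [4, 4, 6, 6]
        coords[:, 4, 2] = 7.0  # 2 nm above the bilayer centre (5.0)
        traj = make_traj(coords)
        np.testing.assert_allclose(
            com_z_distance(traj, [4], table), [2.0, 2.0, 2.0])

    def test_selection_is_bilayer(self):
        table = self._system()
        coords = np.zeros((2, 5, 3))
        coords[:, :4, 2] = [4, 4, 6, 6]
        traj = make_traj(coords)
        np.testing.assert_allclose(
            com_z_distance(traj, [0, 1, 2, 3], table), [0.0, 0.0])

    def test_three_frame_toy_matches_hand_com(self):
        table = self._system()
        rng = np.random.default_rng(3)
        coords = rng.random((3, 5, 3)) * 8
        traj = make_traj(coords)
        got = com_z_distance(traj, [4], table)
        for f in range(3):
            expected = coords[f, 4, 2] - np.mean(coords[f, :4, 2])
            assert got[f] == pytest.approx(expected)

    def test_empty_selection_errors(self):
        with pytest.raises(ValueError, match="empty"):
            com_z_distance(make_traj(np.zeros((1, 5, 3))), [], self._system())


class TestLoadTrajectory:
    def test_round_trip(self, fixture_dir):
        paths = fixture_dir["paths"]
        traj, table = load_trajectory(paths["gro"], paths["xtc"])
        orig = fixture_dir["traj"]
        assert traj.n_frames == 100
        assert table.n_lipids == 716
        assert traj.dt_frame == pytest.approx(orig.dt_frame, rel=1e-6)
        # XTC quantizes to 0.001 nm
        np.testing.assert_allclose(traj.coords, orig.coords, atol=2e-3)
        np.testing.assert_allclose(traj.box, orig.box, atol=1e-3)
        # species composition survives
        orig_sp = fixture_dir["table"].df["species"].value_counts()
        new_sp = table.df["species"].value_counts()
        assert dict(orig_sp) == dict(new_sp)

    def test_missing_species_mapping_is_reported(self, fixture_dir):
        naming = {"residues": {"POPC": "POPC"},
                  "species": {"POPC": {"kind": "lipid",
                                       "reference_beads": ["PO4"]}}}
        with pytest.raises(TopologyError, match="CHOL"):
            load_trajectory(fixture_dir["paths"]["gro"],
                            fixture_dir["paths"]["xtc"], naming)

    def test_no_lipids_rejected(self, tmp_path):
        gro = tmp_path / "prot.gro"
        gro.write_text(
            "protein only\n"
            "    2\n"
            "    1PROT    BB    1   1.000   1.000   1.000\n"
            "    2PROT    BB    2   2.000   2.000   2.000\n"
            "  19.00000  19.00000  10.00000\n")
        with pytest.raises(TopologyError, match="no lipid"):
            load_trajectory(gro)

    def test_particle_count_mismatch(self, fixture_dir, tmp_path):
        gro = tmp_path / "one.gro"
        gro.write_text(
            "one lipid\n"
            "    1\n"
            "    1POPC   PO4    1   1.000   1.000   1.000\n"
            "  19.00000  19.00000  10.00000\n")
        with pytest.raises(TopologyError):
            load_trajectory(gro, fixture_dir["paths"]["xtc"])

    def test_triclinic_rejected(self, tmp_path):
        gro = tmp_path / "tric.gro"
        gro.write_text(
            "triclinic\n"
            "    1\n"
            "    1POPC   PO4    1   1.000   1.000   1.000\n"
            "  19.00000  19.00000  10.00000   0.00000   0.00000"
            "   5.00000   0.00000   0.00000   0.00000\n")
        with pytest.raises(UnsupportedBoxError):
            load_trajectory(gro)


def test_reference_frame_tracks_protein(small_membrane):
    traj, table, truth = small_membrane
    ref = reference_frame(traj, table)
    # the synthetic protein ring is static at the box centre
    np.testing.assert_allclose(ref.protein_center_xy,
                               np.tile([9.5, 9.5], (traj.n_frames, 1)),
                               atol=1e-9)
    # midplane lies between the two leaflet planes
    assert np.all(ref.midplane_z > 3.0) and np.all(ref.midplane_z < 7.0)
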