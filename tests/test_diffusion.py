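"""MSD/Einstein machinery, annulus assignment, ratios and block errors."""

import numpy as np
import pandas as pd
import pytest

from annulipid.core import ReferenceFrame, fixed_point_reference
from annulipid.diffusion import (
    NM2_PER_NS_TO_CM2_PER_S,
    block_errors,
    d_annular,
    d_of_dt,
    d_ratio_profile,
    msd_lateral,
)
from annulipid.leaflets import LeafletAssignment, assign_leaflets
from annulipid.synth import MembraneSpec, simulate

from conftest import make_table, make_traj


def _assign_all_inner(n_frames, n, species="POPC", dt=1.0):
    return LeafletAssignment(np.zeros((n_frames, n), dtype=np.uint8),
                             np.arange(n), np.array([species] * n), dt)


class TestMsd:
    def test_stationary_particles(self):
        traj = make_traj(np.zeros((5, 3, 3)))
        msd = msd_lateral(traj, [0, 1, 2], [1.0, 2.0])
        assert np.all(msd["msd_nm2"] == 0.0)

    def test_hand_built_two_particle_toy(self):
        # A moves (1,0)/frame, B moves (0,2)/frame
        coords = np.zeros((3, 2, 3))
        for f in range(3):
            coords[f, 0, :2] = [1.0 * f, 0.0]
            coords[f, 1, :2] = [0.0, 2.0 * f]
        traj = make_traj(coords + 5.0)
        msd = msd_lateral(traj, [0, 1], [1.0, 2.0])
        # dt=1: origins {0,1} x 2 particles -> (1+1+4+4)/4 = 2.5
        assert msd.loc[0, "msd_nm2"] == pytest.approx(2.5)
        # dt=2: (4 + 16)/2 = 10
        assert msd.loc[1, "msd_nm2"] == pytest.approx(10.0)

    def test_crossing_periodic_boundary(self):
        coords = np.zeros((2, 1, 3))
        coords[0, 0, :2] = [18.5, 0.5]
        coords[1, 0, :2] = [0.5, 0.5]   # +1 nm through the wall
        msd = msd_lateral(make_traj(coords), [0], [1.0])
        assert msd.loc[0, "msd_nm2"] == pytest.approx(1.0)

    def test_dt_validation(self):
        traj = make_traj(np.zeros((5, 1, 3)))
        with pytest.raises(ValueError, match="multiple"):
            msd_lateral(traj, [0], [1.5])
        with pytest.raises(ValueError, match="exceeds"):
            msd_lateral(traj, [0], [10.0])


class TestDofDt:
    def test_einstein_arithmetic_and_units(self):
        msd = pd.DataFrame({"dt_ns": [6.0], "msd_nm2": [0.24], "n_windows": [1]})
        out = d_of_dt(msd)
        assert out.loc[0, "D_nm2_ns"] == pytest.approx(0.01)
        assert out.loc[0, "D_cm2_s"] == pytest.approx(1e-7)
        assert NM2_PER_NS_TO_CM2_PER_S == 1e-5

    def test_zero_msd(self):
        out = d_of_dt(pd.DataFrame({"dt_ns": [2.0], "msd_nm2": [0.0],
                                    "n_windows": [1]}))
        assert out.loc[0, "D_nm2_ns"] == 0.0

    def test_zero_dt_rejected(self):
        with pytest.raises(ValueError):
            d_of_dt(pd.DataFrame({"dt_ns": [0.0], "msd_nm2": [0.1],
                                  "n_windows": [1]}))

    def test_flat_in_dt_for_uniform_d(self):
        spec = MembraneSpec(compositions={"outer": {"POPC": 250},
                                          "inner": {"POPC": 250}},
                            n_frames=4000, seed=40)
        traj, table, _ = simulate(spec)
        idx = table.reference_beads()["particle_id"].to_numpy()
        out = d_of_dt(msd_lateral(traj, idx, [2.0, 4.0, 6.0, 10.0, 20.0]))
        np.testing.assert_allclose(out["D_nm2_ns"], 0.01, rtol=0.02)


class TestAnnular:
    def _toy(self):
        # one lipid walks radially outward from the centre: starts in
        # annulus 0, ends in annulus 3; windows assigned by START frame
        table = make_table([(0, 0, "POPC", "headgroup", 1)])
        coords = np.zeros((5, 1, 3))
        r_path = [0.5, 1.5, 2.5, 3.5, 3.6]
        for f, r in enumerate(r_path):
            coords[f, 0, :2] = [9.5 + r, 9.5]
        traj = make_traj(coords)
        ref = ReferenceFrame(np.tile([9.5, 9.5], (5, 1)), np.zeros(5))
        assign = _assign_all_inner(5, 1)
        return traj, table, ref, assign

    def test_start_frame_assignment(self):
        traj, table, ref, assign = self._toy()
        prof = d_annular(traj, table, "POPC", "inner", ref, assign,
                         dt_values=[3.0], n_blocks=0, r_max=9.0)
        t = prof.table
        # both 3-frame windows start in annuli 0 and 1 respectively
        assert t.set_index("annulus").loc[0, "n_windows"] == 1
        assert t.set_index("annulus").loc[1, "n_windows"] == 1
        assert t.set_index("annulus").loc[3, "n_windows"] == 0
        assert np.isnan(t.set_index("annulus").loc[3, "D_nm2_ns"])

    def test_window_conservation(self):
        traj, table, ref, assign = self._toy()
        prof = d_annular(traj, table, "POPC", "inner", ref, assign,
                         dt_values=[1.0], n_blocks=0, r_max=9.0)
        assert prof.table["n_windows"].sum() == 4  # every origin counted once

    def test_uniform_d_null_no_spurious_slowdown(self):
        spec = MembraneSpec(compositions={"outer": {"POPC": 300},
                                          "inner": {"POPC": 300}},
                            n_frames=2500, seed=41)
        traj, table, _ = simulate(spec)
        assign = assign_leaflets(traj, table)
        ref = fixed_point_reference(traj, (9.5, 9.5), table)
        prof = d_annular(traj, table, "POPC", "whole_bilayer", ref, assign,
                         dt_values=[2.0], n_blocks=5)
        prof = d_ratio_profile(prof)
        t = prof.table[prof.table["n_windows"] > 0]
        z = np.abs(t["D_nm2_ns"] - t["D_bulk_nm2_ns"]) / t["block_sd_nm2_ns"]
        assert z.max() < 3.0

    def test_ratio_profile_toy(self):
        rows = []
        for a, (D, n) in enumerate([(0.005, 100), (0.007, 100), (np.nan, 0),
                                    (0.010, 100), (0.010, 300),
                                    (0.010, 100), (0.010, 100)]):
            rows.append(("POPC", "inner", a, float(a), a + 1.0, 2.0, D,
                         (D * 1e-5) if np.isfinite(D) else np.nan, n, 0.0))
        from annulipid.diffusion import DiffusionProfile
        prof = DiffusionProfile(pd.DataFrame(rows, columns=[
            "species", "leaflet", "annulus", "r_inner_nm", "r_outer_nm",
            "dt_ns", "D_nm2_ns", "D_cm2_s", "n_windows", "block_sd_nm2_ns"]), 1.0)
        out = d_ratio_profile(prof, bulk_min_r=5.0).table.set_index("annulus")
        assert out.loc[0, "ratio_to_bulk"] == pytest.approx(0.5)
        assert np.isnan(out.loc[2, "ratio_to_bulk"])  # missing stays missing
        assert out.loc[5, "D_bulk_nm2_ns"] == pytest.approx(0.010)

    def test_empty_bulk_errors(self):
        traj, table, ref, assign = self._toy()
        prof = d_annular(traj, table, "POPC", "inner", ref, assign,
                         dt_values=[1.0], n_blocks=0, r_max=9.0)
        with pytest.raises(ValueError, match="bulk"):
            d_ratio_profile(prof, bulk_min_r=5.0)


class TestBlockErrors:
    def test_hand_set_block_values(self):
        # 5 blocks yielding D = 1..5 -> population SD = sqrt(2)
        traj = make_traj(np.zeros((50, 1, 3)))
        values = {0: 1.0, 10: 2.0, 20: 3.0, 30: 4.0, 40: 5.0}

        def analysis(sub):
            return {"D": values[int(sub.times[0])]}

        sd = block_errors(traj, analysis, n_blocks=5)
        assert sd["D"] == pytest.approx(np.sqrt(2.0))

    def test_identical_blocks_zero_sd(self):
        traj = make_traj(np.zeros((20, 1, 3)))
        sd = block_errors(traj, lambda sub: {"q": 3.14}, n_blocks=4)
        assert sd["q"] == 0.0

    def test_block_shorter_than_window_errors(self):
        traj, = [make_traj(np.zeros((10, 1, 3)))]
        table = make_table([(0, 0, "POPC", "headgroup", 1)])
        ref = ReferenceFrame(np.tile([9.5, 9.5], (10, 1)), np.zeros(10))
        assign = _assign_all_inner(10, 1)
        with pytest.raises(ValueError, match="short"):
            d_annular(traj, table, "POPC", "inner", ref, assign,
                      dt_values=[4.0], n_blocks=5)

    def test_block_sd_same_order_as_seed_scatter(self):
        # resampling oracle: block SD ~ seed-to-seed SD (same order)
        def one(seed, n_blocks):
            spec = MembraneSpec(compositions={"outer": {"POPC": 100},
                                              "inner": {"POPC": 100}},
                                n_frames=500, seed=seed)
            traj, table, _ = simulate(spec)
            assign = assign_leaflets(traj, table)
            ref = fixed_point_reference(traj, (9.5, 9.5), table)
            prof = d_annular(traj, table, "POPC", "whole_bilayer", ref, assign,
                             dt_values=[2.0], n_blocks=n_blocks, r_max=9.0)
            t = prof.table
            far = t[t["annulus"] == 7].iloc[0]
            return far["D_nm2_ns"], far["block_sd_nm2_ns"]

        seeds = range(60, 68)
        ds, sds = zip(*(one(s, 5) for s in seeds))
        seed_sd = np.std(ds, ddof=1)
        block_sd = np.mean(sds)
        # block SD estimates the SD of one 1/5-length block, so the full-run
        # seed scatter should be ~ block_sd/sqrt(5); same order of magnitude
        assert 0.1 < seed_sd / (block_sd / np.sqrt(5)) < 10.0
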