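"""Canonical estimator-recovery experiments on synthetic membranes.

Each experiment generates a membrane whose ground truth is known exactly and
measures how well one estimator recovers it: the Einstein relation on uniform
free diffusion, the annular estimator on a two-level D(r) profile, RDF
calibration against an ideal gas and a Boltzmann square well, density-map
mass conservation, and Poisson flip-flop rate recovery.  These are the
package's own calibration runs; the test suite asserts tolerances on their
outputs and the reproduction script reports them.

Problem sizes are chosen so every experiment finishes in well under a few
minutes on one CPU while leaving the statistical error comfortably below the
tolerance being checked.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .core import fixed_point_reference, reference_frame
from .density import density_map_2d, rdf_lateral
from .diffusion import d_annular, d_of_dt, d_ratio_profile, msd_lateral
from .leaflets import assign_leaflets, detect_flipflops, leaflet_counts
from .synth import MembraneSpec, RadialProfile, SquareWell, preset_bilayer, simulate

__all__ = [
    "einstein_experiment",
    "uniform_null_experiment",
    "two_level_experiment",
    "ideal_gas_rdf_experiment",
    "well_enrichment_experiment",
    "density_mass_experiment",
    "flip_rate_experiment",
    "coupled_well_slowdown_experiment",
]

_CENTER = (9.5, 9.5)


def make_uniform_membrane(seed: int, n_per_leaflet: int = 250,
                          n_frames: int = 10_000, d: float = 0.01):
    """Free uniform diffusion, no protein, no well: the Einstein-relation and
    ideal-gas reference system (>= 500 lipids, 1e4 frames by default)."""
    spec = MembraneSpec(
        compositions={"outer": {"POPC": n_per_leaflet},
                      "inner": {"POPC": n_per_leaflet}},
        default_d=d, n_frames=n_frames, seed=seed)
    return simulate(spec)


def einstein_experiment(seed: int, dt_eval: float = 6.0, sim=None) -> dict:
    """Recover uniform D from MSD(dt)/(4 dt); truth D = 0.01 nm^2/ns."""
    traj, table, truth = sim if sim is not None else make_uniform_membrane(seed)
    d_true = truth.spec.default_d
    idx = table.reference_beads()["particle_id"].to_numpy()
    out = d_of_dt(msd_lateral(traj, idx, [dt_eval]))
    d_est = float(out.loc[0, "D_nm2_ns"])
    return {"d_true_nm2_ns": d_true, "d_est_nm2_ns": d_est,
            "rel_err": abs(d_est - d_true) / d_true,
            "n_lipids": table.n_lipids, "n_frames": traj.n_frames,
            "n_windows": int(out.loc[0, "n_windows"])}


def uniform_null_experiment(seed: int, dt_eval: float = 2.0,
                            n_blocks: int = 5, sim=None) -> dict:
    """Annular estimator on uniform D: no annulus may deviate from the bulk
    by more than its block SD allows (no spurious slow-down)."""
    traj, table, _ = sim if sim is not None else make_uniform_membrane(seed)
    assign = assign_leaflets(traj, table)
    ref = fixed_point_reference(traj, _CENTER, table)
    prof = d_annular(traj, table, "POPC", "whole_bilayer", ref, assign,
                     dt_values=[dt_eval], n_blocks=n_blocks)
    prof = d_ratio_profile(prof)
    t = prof.table[(prof.table["n_windows"] > 0) &
                   prof.table["block_sd_nm2_ns"].notna()]
    z = (np.abs(t["D_nm2_ns"] - t["D_bulk_nm2_ns"]) /
         t["block_sd_nm2_ns"]).to_numpy()
    return {"max_z": float(z.max()), "n_annuli": len(t),
            "n_frames": traj.n_frames}


def make_two_level_membrane(seed: int, n_per_leaflet: int = 350,
                            n_frames: int = 6000, d_out: float = 0.01,
                            slow_factor: float = 0.5, slow_radius: float = 2.5,
                            obstacle: float = 0.3):
    """Two-level D(r): slow_factor x d_out within slow_radius of the protein
    centre; a small reflective disc marks the protein."""
    spec = MembraneSpec(
        compositions={"outer": {"POPC": n_per_leaflet},
                      "inner": {"POPC": n_per_leaflet}},
        protein_radius=obstacle, n_ring_beads=6,
        d_profiles={"POPC": RadialProfile((slow_radius,),
                                          (slow_factor * d_out, d_out))},
        default_d=d_out, n_frames=n_frames, seed=seed)
    return simulate(spec)


def two_level_experiment(seed: int, dt_eval: float = 2.0, sim=None) -> dict:
    """Recover the slow annulus: annulus-0/bulk ratio should be slow_factor."""
    traj, table, truth = sim if sim is not None else make_two_level_membrane(seed)
    prof_true = truth.spec.d_profiles["POPC"]
    truth_ratio = prof_true.values[0] / prof_true.values[-1]
    assign = assign_leaflets(traj, table)
    ref = reference_frame(traj, table)
    prof = d_annular(traj, table, "POPC", "whole_bilayer", ref, assign,
                     dt_values=[dt_eval], n_blocks=5)
    prof = d_ratio_profile(prof)
    row0 = prof.at(0, dt_eval)
    far = prof.table[(prof.table["r_inner_nm"] >= 5.0) &
                     (prof.table["n_windows"] > 0)]
    d_far = float(np.average(far["D_nm2_ns"], weights=far["n_windows"]))
    return {"ratio_annulus0": float(row0["ratio_to_bulk"]),
            "ratio_true": truth_ratio,
            "d_annulus0_nm2_ns": float(row0["D_nm2_ns"]),
            "d_bulk_nm2_ns": d_far,
            "n_windows_annulus0": int(row0["n_windows"]),
            "n_frames": traj.n_frames}


def make_ideal_gas_membrane(seed: int, n_per_leaflet: int = 250,
                            n_frames: int = 2000):
    """Uniform free diffusion sampled at a 1-us frame interval.

    At D = 0.01 nm^2/ns the box-scale density modes decorrelate over ~1 us,
    so frames stored every 1000 ns are statistically independent and the
    per-shell standard errors of the RDF are exact rather than
    correlation-deflated.  The free propagator is sampled directly at the
    frame interval, so the wide spacing costs nothing.
    """
    spec = MembraneSpec(
        compositions={"outer": {"POPC": n_per_leaflet},
                      "inner": {"POPC": n_per_leaflet}},
        frame_stride=20_000,  # dt_sim 0.05 ns -> 1000 ns between frames
        n_frames=n_frames, seed=seed)
    return simulate(spec)


def ideal_gas_rdf_experiment(seed: int, shell_width: float = 1.0,
                             sim=None) -> dict:
    """g(r) of an unstructured membrane around a fixed point: 1 everywhere.

    Shells of 1 nm (the width of the annular-diffusion analysis) out to the
    inscribed radius keep the "every shell within 3 SE" check well posed:
    with independent frames the SEs are exact and the family of comparisons
    stays small.
    """
    traj, table, _ = sim if sim is not None else make_ideal_gas_membrane(seed)
    assign = assign_leaflets(traj, table)
    ref = fixed_point_reference(traj, _CENTER, table)
    curve = rdf_lateral(traj, table, "POPC", "whole_bilayer", ref, assign,
                        shell_width=shell_width,
                        r_max=min(traj.box[0, :2]) / 2.0, n_se_blocks=20)
    z = np.abs(curve.g - 1.0) / np.maximum(curve.g_se, 1e-12)
    # full-coverage shells (out to the box corners) for the count integral
    full = rdf_lateral(traj, table, "POPC", "whole_bilayer", ref, assign,
                       shell_width=shell_width, n_se_blocks=2)
    return {"max_abs_dev": float(np.abs(curve.g - 1.0).max()),
            "max_z": float(z.max()), "n_shells": len(curve.g),
            "count_integral": float(full.mean_counts.sum()),
            "n_molecules": table.n_lipids}


def make_well_membrane(seed: int, n_per_species_leaflet: int = 175,
                       n_frames: int = 4000, depth: float = 1.0,
                       width: float = 2.0, obstacle: float = 0.5):
    """Uniform D; POPS feels a square well of ``depth`` kT within ``width`` nm
    of the protein surface, POPC is the unbiased control."""
    spec = MembraneSpec(
        compositions={"outer": {"POPC": n_per_species_leaflet,
                                "POPS": n_per_species_leaflet},
                      "inner": {"POPC": n_per_species_leaflet,
                                "POPS": n_per_species_leaflet}},
        protein_radius=obstacle, n_ring_beads=6,
        wells={"POPS": SquareWell(depth, width)},
        n_frames=n_frames, seed=seed)
    return simulate(spec)


def well_enrichment_experiment(seed: int, n_replicates: int = 8,
                               n_frames: int = 400) -> dict:
    """Boltzmann check: POPS density inside the well exceeds the far field by
    e^depth; the excluded disc shows g = 0.

    The in/out occupancy ratio decorrelates on the box-diffusion timescale
    (~1 us), far longer than an affordable trajectory, so within-run error
    bars would be deflated.  Instead the experiment runs independent replicate
    membranes — each starts exactly at the stationary law, so every replicate
    is an unbiased sample — and takes the standard error across replicates.
    """
    ratios = []
    g_blocked_max = 0.0
    truth_val = None
    for k in range(n_replicates):
        traj, table, truth = make_well_membrane(
            (seed * 7919 + k) % (2 ** 31), n_frames=n_frames)
        well = truth.spec.wells["POPS"]
        truth_val = float(np.exp(well.depth))
        lo = truth.spec.protein_radius
        hi = lo + well.width
        assign = assign_leaflets(traj, table)
        ref = reference_frame(traj, table)
        curve = rdf_lateral(traj, table, "POPS", "whole_bilayer", ref, assign,
                            shell_width=0.25, exclusion_radius=lo,
                            n_se_blocks=2)
        in_well = (curve.r_edges[:-1] >= lo) & (curve.r_edges[1:] <= hi)
        far = curve.r_edges[:-1] >= 5.0
        g_in = float(np.average(curve.g[in_well],
                                weights=curve.shell_area[in_well]))
        g_far = float(np.average(curve.g[far], weights=curve.shell_area[far]))
        ratios.append(g_in / g_far)
        blocked = curve.r_edges[1:] <= lo
        g_blocked_max = max(g_blocked_max,
                            float(curve.g[blocked].max(initial=0.0)))
    ratios = np.asarray(ratios)
    return {"enrichment_ratio": float(ratios.mean()),
            "enrichment_true": truth_val,
            "se_ratio": float(ratios.std(ddof=1) / np.sqrt(n_replicates)),
            "g_in_excluded_region": g_blocked_max,
            "n_replicates": n_replicates, "n_frames": n_frames}


def density_mass_experiment(seed: int, n_frames: int = 150) -> dict:
    """Mass conservation of every (species, leaflet) density map on the
    asymmetric study bilayer, cholesterol normalized by last-frame counts."""
    spec = preset_bilayer("Asymm", n_frames=n_frames, seed=seed,
                          flip_rates={})  # constant membership -> mass 1 exact
    traj, table, _ = simulate(spec)
    ref = reference_frame(traj, table)
    assign = assign_leaflets(traj, table, ref)
    counts = leaflet_counts(assign, "last_frame").set_index(["species", "leaflet"])
    masses = {}
    for sp in table.lipid_species:
        for leaf in ("outer", "inner"):
            if counts.loc[(sp, leaf), "count"] == 0:
                continue
            grid = density_map_2d(traj, table, sp, leaf, assign, 0.2, ref)
            masses[f"{sp}_{leaf}"] = grid.mass()
    dev = max(abs(m - 1.0) for m in masses.values())
    return {"max_mass_dev": dev, "n_maps": len(masses), "masses": masses,
            "n_lipids": table.n_lipids}


def flip_rate_experiment(seed: int, n_seeds: int = 10, rate: float = 1e-3,
                         n_chol: int = 200, n_frames: int = 10_000,
                         min_dwell: int = 3) -> dict:
    """Poisson rate recovery: per seed, is the detected event count inside the
    central 95% Poisson interval implied by the true rate?

    The detection dwell is 3 frames here: synthetic leaflet labels are
    noise-free (flat leaflets, instantaneous exchange), so the dwell filter
    contributes only censoring — events whose follow-up flip lands within the
    dwell are absorbed, ~2 x (1 - e^(-rate x dwell)) of the total.  At 3
    frames that residual bias (~0.6%) is far below the Poisson sampling error;
    chatter suppression itself is exercised by the dwell-filter unit tests.
    """
    results = []
    for k in range(n_seeds):
        spec = MembraneSpec(
            compositions={"outer": {"CHOL": n_chol // 2},
                          "inner": {"CHOL": n_chol - n_chol // 2}},
            flip_rates={"CHOL": rate}, n_frames=n_frames,
            seed=(seed * 1009 + k) % (2 ** 31))
        traj, table, _ = simulate(spec)
        assign = assign_leaflets(traj, table)
        _, summary = detect_flipflops(assign, min_dwell=min_dwell)
        row = summary.set_index("species").loc["CHOL"]
        t_total = (traj.n_frames - 1) * traj.dt_frame
        lam = rate * n_chol * t_total
        lo, hi = stats.poisson.interval(0.95, lam)
        results.append({"n_events": int(row["n_events"]),
                        "rate_est": float(row["rate_per_molecule_per_ns"]),
                        "in_interval": bool(lo <= row["n_events"] <= hi)})
    n_in = sum(r["in_interval"] for r in results)
    return {"n_seeds": n_seeds, "n_in_interval": n_in,
            "mean_rate_est": float(np.mean([r["rate_est"] for r in results])),
            "rate_true": rate, "per_seed": results}


def make_coupled_membrane(seed: int, n_per_species_leaflet: int = 150,
                          n_frames: int = 4000):
    """POPS has both an attractive well (1 kT within 2 nm of the surface) and
    a slow annulus (0.5 x bulk D within 2.5 nm of the centre); POPC has
    neither — the density/mobility correlation test system."""
    spec = MembraneSpec(
        compositions={"outer": {"POPC": n_per_species_leaflet,
                                "POPS": n_per_species_leaflet},
                      "inner": {"POPC": n_per_species_leaflet,
                                "POPS": n_per_species_leaflet}},
        protein_radius=0.5, n_ring_beads=6,
        wells={"POPS": SquareWell(1.0, 2.0)},
        d_profiles={"POPS": RadialProfile((2.5,), (0.005, 0.01))},
        n_frames=n_frames, seed=seed)
    return simulate(spec)


def coupled_well_slowdown_experiment(seed: int, dt_eval: float = 2.0,
                                     sim=None) -> dict:
    """The density/mobility correlation: the species with an attractive well
    and a slow annulus shows BOTH a higher first-shell g(r) and a lower
    annulus-0 D ratio than the control species."""
    traj, table, truth = sim if sim is not None else make_coupled_membrane(seed)
    lo = truth.spec.protein_radius
    assign = assign_leaflets(traj, table)
    ref = reference_frame(traj, table)
    out = {}
    for sp in ("POPS", "POPC"):
        curve = rdf_lateral(traj, table, sp, "whole_bilayer", ref, assign,
                            shell_width=0.25, exclusion_radius=lo)
        first = (curve.r_edges[:-1] >= lo) & (curve.r_edges[1:] <= lo + 1.0)
        out[f"g_first_shell_{sp}"] = float(
            np.average(curve.g[first], weights=curve.shell_area[first]))
        prof = d_ratio_profile(d_annular(traj, table, sp, "whole_bilayer",
                                         ref, assign, dt_values=[dt_eval],
                                         n_blocks=5))
        out[f"ratio_annulus0_{sp}"] = float(prof.at(0, dt_eval)["ratio_to_bulk"])
    out["n_frames"] = traj.n_frames
    return out
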