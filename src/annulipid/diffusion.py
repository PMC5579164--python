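"""Timescale-dependent lateral diffusion, resolved by distance from the protein.

The lateral diffusion coefficient is estimated from the 2D Einstein relation

    D(dt) = MSD(dt) / (4 dt),

with MSD(dt) the mean squared minimum-image xy displacement over windows of
length dt, averaged over lipids and (overlapping) window origins.  To resolve
the protein's influence, the membrane plane is divided into concentric annuli
of width 1 nm around the protein's lateral centre of mass, and each
displacement window contributes to the annulus containing the lipid at the
window's START frame — the one convention that never discards data.  Annulus
index 0 spans 0-1 nm (0-10 A) from the centre.

Error bars are standard deviations over contiguous sub-trajectory blocks
(5 blocks by default), which accounts for the temporal correlation that
overlapping windows introduce.

Units: D in nm^2/ns internally; 1 nm^2/ns = 1e-5 cm^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ReferenceFrame, SpeciesTable, Trajectory, min_image_displacement
from .leaflets import INNER, OUTER, LeafletAssignment

__all__ = [
    "NM2_PER_NS_TO_CM2_PER_S",
    "DiffusionProfile",
    "msd_lateral",
    "d_of_dt",
    "d_annular",
    "d_ratio_profile",
    "block_errors",
    "unwrapped_xy",
]

NM2_PER_NS_TO_CM2_PER_S = 1e-5

WHOLE = "whole_bilayer"
DEFAULT_DT_GRID = (1.0, 2.0, 4.0, 6.0, 10.0, 20.0)


def unwrapped_xy(traj: Trajectory, particle_indices) -> np.ndarray:
    """Continuous xy paths from per-frame minimum-image steps.

    Valid when no particle travels more than half a box length between stored
    frames (checked at load time); returns (n_frames, n, 2) with the first
    frame at the wrapped coordinates.
    """
    idx = np.asarray(particle_indices)
    xy = traj.coords[:, idx, :2]
    steps = min_image_displacement(xy[:-1], xy[1:], traj.box[1:, None, :2])
    out = np.empty_like(xy)
    out[0] = xy[0]
    np.cumsum(steps, axis=0, out=out[1:])
    out[1:] += xy[0]
    return out


def _dt_to_frames(traj: Trajectory, dt_values) -> list[int]:
    dt_frame = traj.dt_frame
    ks = []
    for dt in dt_values:
        k = dt / dt_frame
        k_int = int(round(k))
        if k_int < 1 or abs(k - k_int) > 1e-6:
            raise ValueError(f"dt={dt} ns is not a positive multiple of the "
                             f"frame interval {dt_frame} ns")
        if k_int >= traj.n_frames:
            raise ValueError(f"dt={dt} ns exceeds the trajectory length")
        ks.append(k_int)
    return ks


def msd_lateral(traj: Trajectory, particle_indices, dt_values,
                origin_stride: int = 1) -> pd.DataFrame:
    """Lateral MSD(dt) averaged over particles and window origins.

    Returns a DataFrame (dt_ns, msd_nm2, n_windows).  Window origins advance
    by ``origin_stride`` frames; overlapping windows are allowed (their
    correlation is the business of block errors, not of the mean).
    """
    if origin_stride < 1:
        raise ValueError("origin_stride must be >= 1")
    paths = unwrapped_xy(traj, particle_indices)
    rows = []
    for dt, k in zip(dt_values, _dt_to_frames(traj, dt_values)):
        disp = paths[k:] - paths[:-k]
        disp = disp[::origin_stride]
        sq = (disp ** 2).sum(axis=-1)
        rows.append((float(dt), float(sq.mean()), int(sq.size)))
    return pd.DataFrame(rows, columns=["dt_ns", "msd_nm2", "n_windows"])


def d_of_dt(msd_table: pd.DataFrame) -> pd.DataFrame:
    """Einstein-relation D(dt) = MSD(dt)/(4 dt), in nm^2/ns and cm^2/s."""
    if (msd_table["dt_ns"] <= 0).any():
        raise ValueError("dt must be positive")
    out = msd_table.copy()
    out["D_nm2_ns"] = out["msd_nm2"] / (4.0 * out["dt_ns"])
    out["D_cm2_s"] = out["D_nm2_ns"] * NM2_PER_NS_TO_CM2_PER_S
    return out


@dataclass
class DiffusionProfile:
    """Annulus-resolved D values with block errors.

    ``table`` columns: species, leaflet, annulus, r_inner_nm, r_outer_nm,
    dt_ns, D_nm2_ns, D_cm2_s, n_windows, block_sd_nm2_ns (NaN where blocks
    were not computed), and after :func:`d_ratio_profile` also D_bulk_nm2_ns
    and ratio_to_bulk.  Annuli with zero observations carry NaN D, never 0.
    """

    table: pd.DataFrame
    annulus_width: float
    meta: dict = field(default_factory=dict)

    def at(self, annulus: int, dt: float) -> pd.Series:
        t = self.table
        row = t[(t["annulus"] == annulus) & np.isclose(t["dt_ns"], dt)]
        if row.empty:
            raise KeyError(f"no entry for annulus {annulus}, dt {dt}")
        return row.iloc[0]


def _annular_sums(paths, ann_idx, scope_mask, ks, origin_stride, n_annuli):
    """Per-(annulus, dt) sum of squared displacements and window counts."""
    sums = np.zeros((len(ks), n_annuli))
    counts = np.zeros((len(ks), n_annuli), dtype=np.int64)
    for j, k in enumerate(ks):
        disp = paths[k:] - paths[:-k]
        sq = (disp ** 2).sum(axis=-1)
        a = ann_idx[:-k]
        m = scope_mask[:-k] & (a < n_annuli)
        a = a[::origin_stride]
        m = m[::origin_stride]
        s = sq[::origin_stride]
        av = a[m]
        sums[j] = np.bincount(av, weights=s[m], minlength=n_annuli)[:n_annuli]
        counts[j] = np.bincount(av, minlength=n_annuli)[:n_annuli]
    return sums, counts


def d_annular(traj: Trajectory, species: SpeciesTable, species_name: str,
              leaflet: str, ref: ReferenceFrame, assign: LeafletAssignment,
              annulus_width: float = 1.0, dt_values=DEFAULT_DT_GRID,
              origin_stride: int = 1, r_max: float | None = None,
              n_blocks: int = 5) -> DiffusionProfile:
    """Annulus-resolved D(dt) for one species, with block-SD error bars.

    Each displacement window is assigned to the annulus (and, for per-leaflet
    scopes, the leaflet) of the lipid at the window's start frame.  Windows
    starting beyond the last annulus are discarded.  ``n_blocks`` contiguous
    sub-trajectories provide the per-quantity standard deviation (population
    convention); pass ``n_blocks=0`` to skip block errors.
    """
    if annulus_width <= 0:
        raise ValueError("annulus_width must be positive")
    if leaflet not in (OUTER, INNER, WHOLE):
        raise ValueError(f"leaflet must be outer/inner/{WHOLE}")
    beads = species.reference_beads(species_name)
    idx = beads["particle_id"].to_numpy()
    cols = np.flatnonzero(assign.species == species_name)

    if r_max is None:
        r_max = min(traj.box[0, 0], traj.box[0, 1]) / 2.0
    n_annuli = int(np.floor(r_max / annulus_width + 1e-9))
    if n_annuli < 1:
        raise ValueError("r_max smaller than one annulus")

    d = min_image_displacement(ref.protein_center_xy[:, None, :],
                               traj.coords[:, idx, :2], traj.box[:, None, :2])
    r = np.hypot(d[..., 0], d[..., 1])
    ann_idx = (r / annulus_width).astype(np.int64)
    if leaflet == WHOLE:
        scope = np.ones_like(ann_idx, dtype=bool)
    else:
        want = 1 if leaflet == OUTER else 0
        scope = assign.labels[:, cols] == want

    paths = unwrapped_xy(traj, idx)
    ks = _dt_to_frames(traj, dt_values)
    sums, counts = _annular_sums(paths, ann_idx, scope, ks, origin_stride, n_annuli)

    # block errors: recompute per contiguous frame block
    block_sd = np.full((len(ks), n_annuli), np.nan)
    if n_blocks >= 2:
        block_len = traj.n_frames // n_blocks
        if block_len <= max(ks):
            raise ValueError(
                f"blocks of {block_len} frames are shorter than the longest "
                f"dt window ({max(ks)} frames); reduce n_blocks or dt")
        per_block = np.full((n_blocks, len(ks), n_annuli), np.nan)
        for b in range(n_blocks):
            s = b * block_len
            e = s + block_len
            bs, bc = _annular_sums(paths[s:e], ann_idx[s:e], scope[s:e], ks,
                                   origin_stride, n_annuli)
            with np.errstate(invalid="ignore", divide="ignore"):
                per_block[b] = np.where(bc > 0, bs / np.maximum(bc, 1), np.nan)
        dts = np.asarray(dt_values, dtype=float)
        d_blocks = per_block / (4.0 * dts[None, :, None])
        finite = np.isfinite(d_blocks)
        valid = finite.all(axis=0)
        safe = np.where(finite, d_blocks, 0.0)
        mean = safe.sum(axis=0) / n_blocks
        var = (safe ** 2).sum(axis=0) / n_blocks - mean ** 2
        block_sd = np.where(valid, np.sqrt(np.maximum(var, 0.0)), np.nan)

    rows = []
    for j, dt in enumerate(dt_values):
        for a in range(n_annuli):
            n = int(counts[j, a])
            if n > 0:
                msd = sums[j, a] / n
                D = msd / (4.0 * float(dt))
            else:
                D = np.nan
            rows.append((species_name, leaflet, a, a * annulus_width,
                         (a + 1) * annulus_width, float(dt), D,
                         D * NM2_PER_NS_TO_CM2_PER_S, n, block_sd[j, a]))
    table = pd.DataFrame(rows, columns=[
        "species", "leaflet", "annulus", "r_inner_nm", "r_outer_nm", "dt_ns",
        "D_nm2_ns", "D_cm2_s", "n_windows", "block_sd_nm2_ns"])
    meta = {"annulus_width_nm": annulus_width, "origin_stride": origin_stride,
            "n_blocks": n_blocks, "r_max_nm": r_max,
            "window_assignment": "start_frame"}
    return DiffusionProfile(table, annulus_width, meta)


def d_ratio_profile(profile: DiffusionProfile, bulk_min_r: float = 5.0
                    ) -> DiffusionProfile:
    """Attach D(annulus)/D_bulk ratios; bulk = observation-weighted mean D over
    annuli whose inner edge lies at or beyond ``bulk_min_r`` (the far-field
    plateau, which sets in ~5 nm from the protein)."""
    t = profile.table.copy()
    out_frames = []
    for dt, grp in t.groupby("dt_ns", sort=False):
        bulk_rows = grp[(grp["r_inner_nm"] >= bulk_min_r - 1e-9) &
                        grp["D_nm2_ns"].notna() & (grp["n_windows"] > 0)]
        if bulk_rows.empty:
            raise ValueError(f"no populated bulk annuli beyond {bulk_min_r} nm "
                             f"for dt={dt}")
        w = bulk_rows["n_windows"].to_numpy(dtype=float)
        bulk = float(np.average(bulk_rows["D_nm2_ns"], weights=w))
        g = grp.copy()
        g["D_bulk_nm2_ns"] = bulk
        g["ratio_to_bulk"] = g["D_nm2_ns"] / bulk
        out_frames.append(g)
    table = pd.concat(out_frames).sort_index()
    meta = dict(profile.meta, bulk_min_r_nm=bulk_min_r)
    return DiffusionProfile(table, profile.annulus_width, meta)


def block_errors(traj: Trajectory, analysis, n_blocks: int = 5) -> dict:
    """Standard deviation of any per-trajectory analysis over contiguous blocks.

    ``analysis`` is a callable taking a Trajectory and returning a mapping of
    quantity name to float (or an ndarray).  The trajectory is cut into
    ``n_blocks`` equal contiguous blocks (remainder frames dropped) and the
    population standard deviation across blocks is returned per quantity.
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    block_len = traj.n_frames // n_blocks
    if block_len < 2:
        raise ValueError("trajectory too short for the requested blocks")
    results = []
    for b in range(n_blocks):
        sub = traj.slice_frames(b * block_len, (b + 1) * block_len)
        results.append(analysis(sub))
    first = results[0]
    if isinstance(first, dict):
        return {k: float(np.std([r[k] for r in results]))  # population SD
                for k in first}
    arr = np.stack([np.asarray(r, dtype=float) for r in results])
    return arr.std(axis=0)
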