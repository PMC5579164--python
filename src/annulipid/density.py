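"""Normalized 2D lipid density maps and lateral radial distribution functions.

Density maps histogram the reference-bead xy positions over frames in a
protein-centred frame and normalize by (bin area x n_frames x leaflet count),
so that a species whose leaflet membership is constant integrates exactly to
one.  The leaflet count is taken from the last frame — for phospholipids this
equals the constant membership, and for cholesterol it is the convention that
accounts for flip-flop.

The lateral RDF counts reference beads in annular shells around the protein's
lateral centre of mass and divides by the bulk density, with the shell areas
corrected analytically where a shell extends beyond the inscribed circle of
the periodic box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    ReferenceFrame,
    SpeciesTable,
    Trajectory,
    min_image_displacement,
    wrap_coords,
)
from .leaflets import INNER, OUTER, LeafletAssignment, leaflet_counts

__all__ = [
    "DensityGrid",
    "RdfCurve",
    "density_map_2d",
    "rdf_lateral",
    "disc_area_in_box",
    "shell_areas",
]

WHOLE = "whole_bilayer"


@dataclass
class DensityGrid:
    """Normalized 2D density for one (species, leaflet).

    ``values`` has units nm^-2 per lipid per frame; with a constant leaflet
    membership the grid integrates to 1: sum(values) * bin_area == 1.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    values: np.ndarray
    species: str
    leaflet: str
    meta: dict = field(default_factory=dict)

    @property
    def bin_area(self) -> float:
        return float((self.x_edges[1] - self.x_edges[0]) *
                     (self.y_edges[1] - self.y_edges[0]))

    def mass(self) -> float:
        """sum(value x bin area) — 1.0 for a species fully contained in the box
        with constant leaflet membership."""
        return float(self.values.sum() * self.bin_area)


@dataclass
class RdfCurve:
    """Lateral g(r) for one species around the protein centre."""

    r_edges: np.ndarray
    g: np.ndarray
    g_se: np.ndarray
    species: str
    scope: str                    # outer | inner | whole_bilayer
    bulk_density: float           # nm^-2
    mean_counts: np.ndarray       # mean bead count per shell per frame
    shell_area: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def r_mid(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])


# --------------------------------------------------------------------------
# shell geometry
# --------------------------------------------------------------------------

def disc_area_in_box(r, half_width: float):
    """Area of a disc of radius r centred in a periodic square of half-width h.

    Exact for r <= h*sqrt(2); the disc covers the whole square beyond that.
    Minimum-image displacement vectors live exactly in the square
    [-h, h) x [-h, h), so this is the correct support for shell areas.
    """
    r = np.atleast_1d(np.asarray(r, dtype=float)).copy()
    h = float(half_width)
    area = np.pi * r ** 2
    over = r > h
    if np.any(over):
        ro = r[over]
        seg = ro ** 2 * np.arccos(np.minimum(h / ro, 1.0)) - \
            h * np.sqrt(np.maximum(ro ** 2 - h ** 2, 0.0))
        area[over] = np.pi * ro ** 2 - 4.0 * seg
    area[r >= h * np.sqrt(2.0)] = (2.0 * h) ** 2
    return area


def shell_areas(r_edges, box_xy) -> np.ndarray:
    """Annular shell areas inside the periodic box (square boxes required for
    the beyond-inscribed-circle correction)."""
    Lx, Ly = float(box_xy[0]), float(box_xy[1])
    h = min(Lx, Ly) / 2.0
    r_edges = np.asarray(r_edges, dtype=float)
    if not np.isclose(Lx, Ly, rtol=1e-6) and r_edges[-1] > h:
        raise ValueError("shells beyond the inscribed circle require a square box")
    a = disc_area_in_box(r_edges, h)
    return np.diff(a)


# --------------------------------------------------------------------------
# density maps
# --------------------------------------------------------------------------

def _snap_edges(L: float, bin_size: float):
    n = int(round(L / bin_size))
    if n < 1 or abs(n * bin_size - L) > 1e-3 * L:
        raise ValueError(
            f"bin_size {bin_size} does not divide box length {L} "
            "(to within one part in 1e3)")
    return np.linspace(0.0, L, n + 1)


def density_map_2d(traj: Trajectory, species: SpeciesTable, species_name: str,
                   leaflet: str, assign: LeafletAssignment,
                   bin_size: float = 0.2, ref: ReferenceFrame | None = None
                   ) -> DensityGrid:
    """Normalized 2D headgroup density map for one species in one leaflet.

    Positions are translated per frame so the protein lateral centre sits at
    the grid centre (pass ``ref=None`` for a lab-fixed map), wrapped, and
    histogrammed; the histogram is divided by (bin area x n_frames x leaflet
    count), the leaflet count being the last-frame count of the species in
    that leaflet.
    """
    if leaflet not in (OUTER, INNER):
        raise ValueError("leaflet must be 'outer' or 'inner'")
    beads = species.reference_beads(species_name)
    cols = np.flatnonzero(assign.species == species_name)
    if not np.array_equal(assign.molecule_ids[cols], beads["molecule_id"].to_numpy()):
        raise ValueError("assignment does not match the species table")
    counts = leaflet_counts(assign, "last_frame")
    n_lip = float(counts.set_index(["species", "leaflet"])
                  .loc[(species_name, leaflet), "count"])
    if n_lip == 0:
        raise ValueError(f"species {species_name!r} absent from the {leaflet} leaflet")

    box0 = traj.box[0]
    if not np.allclose(traj.box, box0, rtol=1e-2):
        raise ValueError("box varies by more than 1% across frames; "
                         "a fixed density grid is not meaningful")
    x_edges = _snap_edges(box0[0], bin_size)
    y_edges = _snap_edges(box0[1], bin_size)

    idx = beads["particle_id"].to_numpy()
    want = 1 if leaflet == OUTER else 0
    lab = assign.labels[:, cols]
    xy = traj.coords[:, idx, :2].copy()
    if ref is not None:
        shift = (box0[:2] / 2.0) - ref.protein_center_xy
        xy += shift[:, None, :]
    xy = wrap_coords(xy, traj.box[:, None, :2])

    hist = np.zeros((len(x_edges) - 1, len(y_edges) - 1))
    for f in range(traj.n_frames):
        sel = lab[f] == want
        if sel.any():
            h, _, _ = np.histogram2d(xy[f, sel, 0], xy[f, sel, 1],
                                     bins=[x_edges, y_edges])
            hist += h
    bin_area = (x_edges[1] - x_edges[0]) * (y_edges[1] - y_edges[0])
    values = hist / (bin_area * traj.n_frames * n_lip)
    meta = {
        "n_frames": traj.n_frames,
        "n_lipids_norm": n_lip,
        "normalization": "bin_area * n_frames * last_frame_leaflet_count",
        "bin_size_nm": bin_size,
        "protein_centred": ref is not None,
    }
    return DensityGrid(x_edges, y_edges, values, species_name, leaflet, meta)


# --------------------------------------------------------------------------
# lateral RDF
# --------------------------------------------------------------------------

def rdf_lateral(traj: Trajectory, species: SpeciesTable, species_name: str,
                scope: str, ref: ReferenceFrame, assign: LeafletAssignment,
                shell_width: float = 0.2, r_max: float | None = None,
                exclusion_radius: float = 0.0, n_se_blocks: int = 10) -> RdfCurve:
    """Lateral radial distribution function around the protein centre.

    ``scope`` selects the outer leaflet, the inner leaflet, or the whole
    bilayer; for cholesterol the whole-bilayer scope is mandatory because
    flip-flop moves molecules between leaflets.  The bulk density is the
    scope's molecule count divided by (box area - protein disc area), with
    ``exclusion_radius`` the protein disc radius (0 disables the exclusion).
    Standard errors are estimated from ``n_se_blocks`` contiguous frame blocks
    so that frame-to-frame correlation is accounted for.
    """
    if scope not in (OUTER, INNER, WHOLE):
        raise ValueError(f"scope must be outer/inner/{WHOLE}")
    if species_name == "CHOL" and scope != WHOLE:
        raise ValueError("cholesterol RDF must use whole_bilayer scope "
                         "(leaflet membership changes through flip-flop)")
    if shell_width <= 0:
        raise ValueError("shell_width must be positive")
    beads = species.reference_beads(species_name)
    cols = np.flatnonzero(assign.species == species_name)
    idx = beads["particle_id"].to_numpy()

    box0 = traj.box[0]
    h = min(box0[0], box0[1]) / 2.0
    if r_max is None:
        r_max = h * np.sqrt(2.0)
    n_shell = int(np.ceil(r_max / shell_width))
    r_edges = np.arange(n_shell + 1) * shell_width
    areas = shell_areas(r_edges, box0[:2])
    if np.any(areas <= 0):
        keep = areas > 1e-12
        n_shell = int(keep.sum())
        r_edges = r_edges[:n_shell + 1]
        areas = areas[:n_shell]

    d = min_image_displacement(ref.protein_center_xy[:, None, :],
                               traj.coords[:, idx, :2], traj.box[:, None, :2])
    r = np.hypot(d[..., 0], d[..., 1])
    if scope in (OUTER, INNER):
        want = 1 if scope == OUTER else 0
        in_scope = assign.labels[:, cols] == want
    else:
        in_scope = np.ones_like(r, dtype=bool)

    # per-frame shell counts
    shell_idx = np.minimum((r / shell_width).astype(int), n_shell)  # n_shell = out of range
    counts = np.zeros((traj.n_frames, n_shell))
    for f in range(traj.n_frames):
        sel = in_scope[f]
        c = np.bincount(shell_idx[f, sel], minlength=n_shell + 1)[:n_shell]
        counts[f] = c

    box_area = box0[0] * box0[1]
    free_area = box_area - np.pi * exclusion_radius ** 2
    n_scope = in_scope.sum(axis=1)  # per frame
    bulk = n_scope.mean() / free_area
    if bulk <= 0:
        raise ValueError(f"no molecules of {species_name!r} in scope {scope!r}")

    g_frames = counts / areas[None, :] / bulk
    g = g_frames.mean(axis=0)

    n_blocks = max(2, min(n_se_blocks, traj.n_frames))
    edges = np.linspace(0, traj.n_frames, n_blocks + 1).astype(int)
    block_means = np.array([g_frames[a:b].mean(axis=0)
                            for a, b in zip(edges[:-1], edges[1:])])
    g_se = block_means.std(axis=0, ddof=1) / np.sqrt(n_blocks)

    meta = {
        "shell_width_nm": shell_width,
        "exclusion_radius_nm": exclusion_radius,
        "n_frames": traj.n_frames,
        "n_se_blocks": n_blocks,
    }
    return RdfCurve(r_edges, g, g_se, species_name, scope, float(bulk),
                    counts.mean(axis=0), areas, meta)
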