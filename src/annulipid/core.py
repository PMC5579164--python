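"""Trajectory containers, periodic-boundary geometry and the shared reference frame.

Everything downstream (densities, RDFs, annular diffusion, contacts) works on
the in-memory :class:`Trajectory` / :class:`SpeciesTable` pair produced either
by :func:`load_trajectory` (GRO/PDB + XTC/TRR/DCD through MDAnalysis) or by the
synthetic membrane generator.

Internal units are fixed: lengths in nm, times in ns.  Only orthorhombic
periodic boxes are supported; coordinates are treated as wrapped on input and
all displacement arithmetic uses the minimum-image convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Trajectory",
    "SpeciesTable",
    "ReferenceFrame",
    "TopologyError",
    "UnsupportedBoxError",
    "DEFAULT_NAMING",
    "load_naming_config",
    "load_trajectory",
    "min_image_displacement",
    "wrap_coords",
    "periodic_mean",
    "reference_frame",
    "lateral_distance_to_protein",
    "lateral_distances",
    "com_z_distance",
]

PROTEIN = "PROTEIN"

#: role labels used in SpeciesTable
ROLE_PROTEIN = "protein"
ROLE_HEADGROUP = "headgroup"   # phosphate bead of a phospholipid / SM
ROLE_ROH = "roh"               # cholesterol hydroxyl bead
ROLE_TAIL = "tail"

REFERENCE_ROLES = (ROLE_HEADGROUP, ROLE_ROH)


class TopologyError(ValueError):
    """Topology/trajectory inconsistency or unmappable particle naming."""


class UnsupportedBoxError(ValueError):
    """Raised for triclinic (non-orthorhombic) periodic boxes."""


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Ordered coordinate frames with per-frame orthorhombic box lengths.

    Parameters
    ----------
    coords : (n_frames, n_particles, 3) float array, nm
    times : (n_frames,) float array, ns
    box : (n_frames, 3) float array, nm
    """

    coords: np.ndarray
    times: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_particles, 3)")
        if self.times.shape != (self.coords.shape[0],):
            raise ValueError("times must have one entry per frame")
        if self.box.shape != (self.coords.shape[0], 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")
        if self.n_frames > 1:
            dts = np.diff(self.times)
            if np.any(dts <= 0):
                raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coords.shape[1]

    @property
    def dt_frame(self) -> float:
        """Time between stored frames (ns); frames must be evenly spaced."""
        if self.n_frames < 2:
            raise ValueError("dt_frame undefined for a single-frame trajectory")
        dts = np.diff(self.times)
        dt = float(np.median(dts))
        if not np.allclose(dts, dt, rtol=1e-3, atol=1e-6):
            raise ValueError("frames are not evenly spaced in time")
        return dt

    def slice_frames(self, start: int, stop: int) -> "Trajectory":
        """Contiguous sub-trajectory [start, stop) sharing the same particles."""
        return Trajectory(self.coords[start:stop], self.times[start:stop],
                          self.box[start:stop])


class SpeciesTable:
    """Per-particle classification: molecule id, species and role.

    Wraps a DataFrame with columns ``particle_id, molecule_id, species, role,
    residue_id``.  Species are lipid names (POPC, POPS, POPE, SM, CHOL, ...)
    or ``PROTEIN``; each lipid molecule carries exactly one reference bead
    (phosphate for phospholipids/SM, ROH for cholesterol).
    """

    def __init__(self, df: pd.DataFrame):
        required = {"particle_id", "molecule_id", "species", "role", "residue_id"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"SpeciesTable missing columns: {sorted(missing)}")
        self.df = df.sort_values("particle_id").reset_index(drop=True)
        if not np.array_equal(self.df["particle_id"].to_numpy(),
                              np.arange(len(self.df))):
            raise ValueError("particle_id must be 0..N-1 without gaps")
        lipids = self.df[self.df["species"] != PROTEIN]
        ref = lipids[lipids["role"].isin(REFERENCE_ROLES)]
        per_mol = ref.groupby("molecule_id").size()
        all_mols = lipids["molecule_id"].unique()
        if len(per_mol) != len(all_mols) or (per_mol != 1).any():
            raise ValueError("each lipid molecule needs exactly one reference bead")
        # cached reference-bead view, ordered by molecule_id
        self._ref = ref.sort_values("molecule_id").reset_index(drop=True)

    @property
    def n_particles(self) -> int:
        return len(self.df)

    @property
    def lipid_species(self) -> list[str]:
        out = [s for s in self.df["species"].unique() if s != PROTEIN]
        return sorted(out)

    @property
    def n_lipids(self) -> int:
        return len(self._ref)

    def reference_beads(self, species: str | None = None) -> pd.DataFrame:
        """Reference-bead rows (one per lipid molecule), optionally one species."""
        if species is None:
            return self._ref
        if species == PROTEIN:
            raise ValueError("protein has no lipid reference beads")
        out = self._ref[self._ref["species"] == species]
        if out.empty:
            raise ValueError(f"no molecules of species {species!r}")
        return out

    def protein_indices(self, residue_ids: Iterable[int] | None = None) -> np.ndarray:
        prot = self.df[self.df["species"] == PROTEIN]
        if residue_ids is not None:
            residue_ids = set(residue_ids)
            prot = prot[prot["residue_id"].isin(residue_ids)]
        return prot["particle_id"].to_numpy()

    def lipid_particle_indices(self) -> np.ndarray:
        """All particles belonging to lipid molecules (any role)."""
        return self.df.loc[self.df["species"] != PROTEIN, "particle_id"].to_numpy()


@dataclass
class ReferenceFrame:
    """Per-frame protein lateral centre and bilayer midplane height (nm).

    ``protein_center_xy`` is the periodic-aware lateral centre of the chosen
    protein selection (the TM region by convention); ``midplane_z`` is the mean
    z of all lipid reference beads, used for leaflet assignment.
    """

    protein_center_xy: np.ndarray   # (n_frames, 2)
    midplane_z: np.ndarray          # (n_frames,)

    def __post_init__(self) -> None:
        self.protein_center_xy = np.asarray(self.protein_center_xy, dtype=float)
        self.midplane_z = np.asarray(self.midplane_z, dtype=float)
        if self.protein_center_xy.ndim != 2 or self.protein_center_xy.shape[1] != 2:
            raise ValueError("protein_center_xy must be (n_frames, 2)")
        if self.midplane_z.shape != (self.protein_center_xy.shape[0],):
            raise ValueError("midplane_z length mismatch")

    @property
    def n_frames(self) -> int:
        return self.protein_center_xy.shape[0]

    def slice_frames(self, start: int, stop: int) -> "ReferenceFrame":
        return ReferenceFrame(self.protein_center_xy[start:stop],
                              self.midplane_z[start:stop])


# --------------------------------------------------------------------------
# periodic geometry
# --------------------------------------------------------------------------

def min_image_displacement(a, b, box):
    """Minimum-image displacement b - a; each component in [-L/2, L/2).

    Works element-wise on broadcastable arrays; ``box`` holds the periodic
    lengths for the dimensions being compared.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box lengths must be positive")
    d = b - a
    return d - box * np.floor(d / box + 0.5)


def wrap_coords(x, box):
    """Wrap coordinates into [0, L) per component."""
    x = np.asarray(x, dtype=float)
    box = np.asarray(box, dtype=float)
    return x - box * np.floor(x / box)


def periodic_mean(x, box_length, axis=None):
    """Mean position on a periodic axis via the circular-mean construction.

    Robust when the particle cloud straddles the box boundary (a plain mean is
    not).  Result is wrapped into [0, L).
    """
    theta = np.asarray(x, dtype=float) * (2.0 * np.pi / box_length)
    mean_angle = np.arctan2(np.sin(theta).mean(axis=axis),
                            np.cos(theta).mean(axis=axis))
    return wrap_coords(mean_angle * box_length / (2.0 * np.pi), box_length)


# --------------------------------------------------------------------------
# reference frame and distances
# --------------------------------------------------------------------------

def reference_frame(traj: Trajectory, species: SpeciesTable,
                    protein_residues: Iterable[int] | None = None) -> ReferenceFrame:
    """Compute the per-frame protein lateral centre and bilayer midplane.

    ``protein_residues`` restricts the lateral centre to a sub-selection (the
    TM region); by default all protein particles are used.  The midplane is
    the mean z of all lipid reference beads, so the protein never biases
    leaflet assignment.
    """
    ref_idx = species.reference_beads()["particle_id"].to_numpy()
    midplane = traj.coords[:, ref_idx, 2].mean(axis=1)

    prot_idx = species.protein_indices(protein_residues)
    if prot_idx.size == 0:
        raise ValueError("no protein particles in selection; "
                         "build a ReferenceFrame directly for protein-free systems")
    center = np.empty((traj.n_frames, 2))
    for ax in range(2):
        L = traj.box[:, ax]
        # circular mean per frame (vectorized over frames)
        theta = traj.coords[:, prot_idx, ax] * (2.0 * np.pi / L[:, None])
        ang = np.arctan2(np.sin(theta).mean(axis=1), np.cos(theta).mean(axis=1))
        center[:, ax] = wrap_coords(ang * L / (2.0 * np.pi), L)
    return ReferenceFrame(center, midplane)


def fixed_point_reference(traj: Trajectory, point_xy: Sequence[float],
                          species: SpeciesTable | None = None) -> ReferenceFrame:
    """ReferenceFrame with a static lateral reference point (protein-free runs)."""
    center = np.tile(np.asarray(point_xy, dtype=float), (traj.n_frames, 1))
    if species is not None:
        ref_idx = species.reference_beads()["particle_id"].to_numpy()
        mid = traj.coords[:, ref_idx, 2].mean(axis=1)
    else:
        mid = np.zeros(traj.n_frames)
    return ReferenceFrame(center, mid)


def lateral_distances(traj: Trajectory, ref: ReferenceFrame,
                      particle_indices) -> np.ndarray:
    """Minimum-image xy distance to the protein centre, per (frame, particle)."""
    if ref.n_frames != traj.n_frames:
        raise ValueError("reference frame does not match trajectory")
    idx = np.asarray(particle_indices)
    d = min_image_displacement(ref.protein_center_xy[:, None, :],
                               traj.coords[:, idx, :2],
                               traj.box[:, None, :2])
    return np.hypot(d[..., 0], d[..., 1])


def lateral_distance_to_protein(traj: Trajectory, ref: ReferenceFrame,
                                frame: int, particle: int) -> float:
    """xy-plane minimum-image distance of one particle in one frame (nm)."""
    return float(lateral_distances(traj.slice_frames(frame, frame + 1),
                                   ref.slice_frames(frame, frame + 1),
                                   [particle])[0, 0])


def com_z_distance(traj: Trajectory, selection, species: SpeciesTable) -> np.ndarray:
    """z-distance between a selection's centre of mass and the bilayer COM.

    Returns one signed value per frame (nm): positive when the selection sits
    above the bilayer centre.  Unweighted means are used (coarse-grained beads
    of near-equal mass); the bilayer is assumed not to straddle the z box
    boundary, which holds for membrane patches built around the box centre.
    """
    idx = np.asarray(selection)
    if idx.size == 0:
        raise ValueError("empty selection")
    lipid_idx = species.lipid_particle_indices()
    if lipid_idx.size == 0:
        raise ValueError("no lipid particles for the bilayer reference")
    sel_z = traj.coords[:, idx, 2].mean(axis=1)
    bil_z = traj.coords[:, lipid_idx, 2].mean(axis=1)
    return sel_z - bil_z


# --------------------------------------------------------------------------
# file ingestion
# --------------------------------------------------------------------------

_AMINO_ACIDS = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]

#: default residue/bead naming for MARTINI-style coarse-grained membranes,
#: matching the names the synthetic generator writes.
DEFAULT_NAMING: dict = {
    "residues": {
        "POPC": "POPC", "POPS": "POPS", "POPE": "POPE",
        "SM": "SM", "DPSM": "SM", "PSM": "SM",
        "CHOL": "CHOL", "CHO": "CHOL",
        "PROT": PROTEIN,
        **{aa: PROTEIN for aa in _AMINO_ACIDS},
    },
    "species": {
        "POPC": {"kind": "lipid", "reference_beads": ["PO4", "P"]},
        "POPS": {"kind": "lipid", "reference_beads": ["PO4", "P"]},
        "POPE": {"kind": "lipid", "reference_beads": ["PO4", "P"]},
        "SM": {"kind": "lipid", "reference_beads": ["PO4", "P"]},
        "CHOL": {"kind": "sterol", "reference_beads": ["ROH"]},
    },
}


def load_naming_config(path_or_mapping) -> dict:
    """Load a naming config (YAML path or mapping) and validate its shape."""
    if path_or_mapping is None:
        return DEFAULT_NAMING
    if isinstance(path_or_mapping, Mapping):
        cfg = dict(path_or_mapping)
    else:
        with open(path_or_mapping) as fh:
            cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping) or "residues" not in cfg or "species" not in cfg:
        raise ValueError("naming config needs 'residues' and 'species' sections")
    for sp, meta in cfg["species"].items():
        if "reference_beads" not in meta:
            raise ValueError(f"species {sp!r} lacks reference_beads")
    return cfg


def _species_table_from_universe(u, naming: dict) -> SpeciesTable:
    res_map = naming["residues"]
    sp_meta = naming["species"]
    records = []
    unmapped: set[str] = set()
    for res in u.residues:
        resname = res.resname.strip()
        species_name = res_map.get(resname)
        if species_name is None:
            unmapped.add(resname)
            continue
        if species_name == PROTEIN:
            for atom in res.atoms:
                records.append((atom.ix, res.resindex, PROTEIN, ROLE_PROTEIN,
                                int(res.resid)))
        else:
            meta = sp_meta.get(species_name)
            if meta is None:
                unmapped.add(resname)
                continue
            ref_names = set(meta["reference_beads"])
            ref_role = ROLE_ROH if meta.get("kind") == "sterol" else ROLE_HEADGROUP
            n_ref = 0
            for atom in res.atoms:
                if atom.name.strip() in ref_names:
                    role = ref_role
                    n_ref += 1
                else:
                    role = ROLE_TAIL
                records.append((atom.ix, res.resindex, species_name, role,
                                int(res.resid)))
            if n_ref != 1:
                raise TopologyError(
                    f"residue {resname} (resid {res.resid}) has {n_ref} reference "
                    f"beads {sorted(ref_names)}; exactly one required")
    if unmapped:
        raise TopologyError(
            "naming config does not map residue name(s): " + ", ".join(sorted(unmapped)))
    df = pd.DataFrame(records, columns=["particle_id", "molecule_id", "species",
                                        "role", "residue_id"])
    if len(df) != len(u.atoms):
        raise TopologyError("some atoms were not classified")
    if (df["species"] != PROTEIN).sum() == 0:
        raise TopologyError("no lipid molecules in topology")
    return SpeciesTable(df)


def _check_orthorhombic(dimensions) -> None:
    if dimensions is None:
        raise UnsupportedBoxError("trajectory has no box information")
    angles = np.asarray(dimensions[3:6], dtype=float)
    if not np.allclose(angles, 90.0, atol=1e-3):
        raise UnsupportedBoxError(
            f"triclinic box (angles {angles}) is not supported; orthorhombic only")


def load_trajectory(topology_path, trajectory_path=None, naming_config=None,
                    check_continuity: bool = True):
    """Read a topology frame (GRO/PDB) plus optional trajectory (XTC/TRR/DCD).

    Returns ``(Trajectory, SpeciesTable)``.  ``naming_config`` maps residue
    names to species and bead names to roles (defaults to the MARTINI-style
    names the synthetic generator writes).

    ``check_continuity`` asserts that no particle's minimum-image displacement
    between consecutive frames exceeds L/4, the regime in which minimum-image
    displacement arithmetic (used instead of trajectory unwrapping) is valid.
    """
    import MDAnalysis as mda

    topology_path = Path(topology_path)
    if not topology_path.exists():
        raise FileNotFoundError(topology_path)
    naming = load_naming_config(naming_config)
    try:
        if trajectory_path is None:
            u = mda.Universe(str(topology_path))
        else:
            trajectory_path = Path(trajectory_path)
            if not trajectory_path.exists():
                raise FileNotFoundError(trajectory_path)
            u = mda.Universe(str(topology_path), str(trajectory_path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # MDA raises assorted types on count mismatch
        raise TopologyError(f"failed to combine topology and trajectory: {exc}") from exc

    species = _species_table_from_universe(u, naming)

    n_frames = len(u.trajectory)
    coords = np.empty((n_frames, len(u.atoms), 3))
    times = np.empty(n_frames)
    box = np.empty((n_frames, 3))
    for i, ts in enumerate(u.trajectory):
        _check_orthorhombic(ts.dimensions)
        coords[i] = ts.positions / 10.0          # A -> nm
        times[i] = ts.time / 1000.0              # ps -> ns
        box[i] = np.asarray(ts.dimensions[:3], dtype=float) / 10.0
    if n_frames > 1 and np.allclose(times, times[0]):
        # format carried no time information; fall back to frame index (ns)
        times = np.arange(n_frames, dtype=float)

    traj = Trajectory(coords, times, box)
    if check_continuity and n_frames > 1:
        # lateral only: leaflet flip-flop legitimately jumps z by the bilayer
        # thickness, and displacement analysis is in the xy plane
        step = min_image_displacement(traj.coords[:-1, :, :2], traj.coords[1:, :, :2],
                                      traj.box[1:, None, :2])
        max_step = np.abs(step).max(axis=(0, 1))
        limit = traj.box.min(axis=0)[:2] / 4.0
        if np.any(max_step > limit):
            raise ValueError(
                f"per-frame displacement up to {max_step} nm exceeds L/4 {limit}; "
                "frames are too sparse for minimum-image displacement analysis")
    return traj, species
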