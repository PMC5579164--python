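"""Per-residue protein-lipid contact counting and structure mapping.

A contact is counted once per (protein residue, lipid molecule, frame) when
any selected bead pair lies within the cutoff — counting pairs only once per
molecule prevents bead-count bias between lipid species.  Tables are
max-normalized by the single highest count over the whole complex (one shared
scale across domains), and cross-system error bars are population standard
deviations of the normalized values over replicate systems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import PROTEIN, SpeciesTable, Trajectory, wrap_coords

__all__ = [
    "ContactTable",
    "count_contacts",
    "normalize_contacts",
    "contact_sd_across_systems",
    "map_contacts_to_structure",
]

HEADGROUP_ONLY = "headgroup_only"
ALL_LIPID_BEADS = "all_lipid_beads"


@dataclass
class ContactTable:
    """Residue x species contact counts.

    ``table``: DataFrame indexed by protein residue_id with one column per
    lipid species; raw counts are summed over frames, normalized values lie in
    [0, 1] with the global maximum over the whole table equal to 1.
    """

    table: pd.DataFrame
    normalized: bool = False
    meta: dict = field(default_factory=dict)


def count_contacts(traj: Trajectory, species: SpeciesTable, lipid_species,
                   bead_scope: str = HEADGROUP_ONLY, cutoff: float = 0.6,
                   frame_stride: int = 1) -> ContactTable:
    """Count residue-lipid contacts over frames.

    ``lipid_species`` is a list of species names; ``bead_scope`` selects the
    lipid beads considered (reference headgroup/ROH beads only, or every lipid
    bead); ``cutoff`` is the 3D centre-centre distance in nm.  Distances use
    the periodic minimum image (KD-tree with periodic box).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if bead_scope not in (HEADGROUP_ONLY, ALL_LIPID_BEADS):
        raise ValueError(f"bead_scope must be {HEADGROUP_ONLY!r} or {ALL_LIPID_BEADS!r}")
    lipid_species = list(lipid_species)
    if not lipid_species:
        raise ValueError("empty lipid species list")

    df = species.df
    prot = df[df["species"] == PROTEIN]
    if prot.empty:
        raise ValueError("no protein particles in the system")
    prot_idx = prot["particle_id"].to_numpy()
    prot_res = prot["residue_id"].to_numpy()
    residues = np.unique(prot_res)

    lip = df[df["species"].isin(lipid_species)]
    if lip.empty:
        raise ValueError(f"no lipid particles for species {lipid_species}")
    if bead_scope == HEADGROUP_ONLY:
        lip = lip[lip["role"].isin(("headgroup", "roh"))]
    lip_idx = lip["particle_id"].to_numpy()
    lip_mol = lip["molecule_id"].to_numpy()
    lip_sp = lip["species"].to_numpy()

    res_pos = {r: i for i, r in enumerate(residues)}
    sp_pos = {s: j for j, s in enumerate(lipid_species)}
    counts = np.zeros((len(residues), len(lipid_species)), dtype=np.int64)

    frames = range(0, traj.n_frames, frame_stride)
    n_used = 0
    for f in frames:
        box = traj.box[f]
        p = wrap_coords(traj.coords[f][prot_idx], box)
        q = wrap_coords(traj.coords[f][lip_idx], box)
        # boxsize requires points strictly inside [0, L)
        p = np.minimum(p, np.nextafter(box, 0.0))
        q = np.minimum(q, np.nextafter(box, 0.0))
        tp = cKDTree(p, boxsize=box)
        tq = cKDTree(q, boxsize=box)
        pairs = tp.query_ball_tree(tq, r=cutoff)
        seen = set()
        for i, hits in enumerate(pairs):
            ri = res_pos[prot_res[i]]
            for j in hits:
                key = (ri, lip_mol[j])
                if key not in seen:
                    seen.add(key)
                    counts[ri, sp_pos[lip_sp[j]]] += 1
        n_used += 1

    table = pd.DataFrame(counts, index=pd.Index(residues, name="residue_id"),
                         columns=lipid_species)
    meta = {"cutoff_nm": cutoff, "bead_scope": bead_scope,
            "n_frames_used": n_used, "frame_stride": frame_stride}
    return ContactTable(table, normalized=False, meta=meta)


def normalize_contacts(ct: ContactTable) -> ContactTable:
    """Divide every entry by the single global maximum over the whole complex.

    Idempotent; an all-zero table stays zero (with a warning).
    """
    if ct.table.empty:
        raise ValueError("empty contact table")
    peak = float(ct.table.to_numpy().max())
    if peak == 0:
        warnings.warn("contact table is all zeros; normalization is a no-op")
        return ContactTable(ct.table.astype(float), normalized=True,
                            meta=dict(ct.meta, peak=0.0))
    return ContactTable(ct.table / peak, normalized=True,
                        meta=dict(ct.meta, peak=peak))


def contact_sd_across_systems(tables) -> pd.DataFrame:
    """Per-(residue, species) population SD of normalized contacts across
    replicate simulation systems."""
    tables = list(tables)
    if len(tables) < 2:
        raise ValueError("need at least two systems")
    frames = [t.table if isinstance(t, ContactTable) else t for t in tables]
    ref = frames[0]
    for i, f in enumerate(frames[1:], start=2):
        if not ref.index.equals(f.index) or list(ref.columns) != list(f.columns):
            extra = set(f.index) ^ set(ref.index)
            raise ValueError(f"system {i} residue/species indexing differs "
                             f"(residue diff: {sorted(extra)})")
    stack = np.stack([f.to_numpy(dtype=float) for f in frames])
    sd = stack.std(axis=0)  # population convention
    return pd.DataFrame(sd, index=ref.index, columns=ref.columns)


def map_contacts_to_structure(ct: ContactTable, topology_path, out_path,
                              species_column: str | None = None) -> str:
    """Write a PDB with per-residue contact values in the B-factor column.

    ``species_column`` selects one species; by default the row-maximum over
    species is written.  Residues absent from the table get B-factor 0;
    table residues missing from the topology raise.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(topology_path))
    table = ct.table
    if species_column is not None:
        if species_column not in table.columns:
            raise ValueError(f"no species {species_column!r} in table")
        values = table[species_column]
    else:
        values = table.max(axis=1)

    topo_resids = set(int(r) for r in u.residues.resids)
    missing = [int(r) for r in values.index if int(r) not in topo_resids]
    if missing:
        raise ValueError(f"residues not in topology: {missing}")

    bf = np.zeros(len(u.atoms))
    lookup = {int(r): float(v) for r, v in values.items()}
    for res in u.residues:
        v = lookup.get(int(res.resid))
        if v is not None:
            bf[res.atoms.ix] = v
    if not hasattr(u.atoms, "tempfactors"):
        u.add_TopologyAttr("tempfactors", np.zeros(len(u.atoms)))
    u.atoms.tempfactors = bf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # PDB writer chatters about absent attrs
        u.atoms.write(str(out_path))
    return str(out_path)
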