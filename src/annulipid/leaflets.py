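"""Leaflet assignment, cholesterol flip-flop detection, and leaflet counts.

A lipid belongs to the outer leaflet in a given frame when its reference bead
(phosphate / ROH) sits above the per-frame bilayer midplane — the mean z of
all lipid reference beads.  A lipid exactly at the midplane is assigned inner
(deterministic tie-break).  Flip-flop events are extracted from the label
series with a dwell-time hysteresis: a leaflet change counts only once the new
label has persisted for ``min_dwell`` consecutive frames, which suppresses
midplane-crossing chatter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ReferenceFrame, SpeciesTable, Trajectory

__all__ = [
    "LeafletAssignment",
    "assign_leaflets",
    "detect_flipflops",
    "leaflet_counts",
]

OUTER, INNER = "outer", "inner"
_LABELS = np.array([INNER, OUTER])  # index by the boolean "is outer"


@dataclass
class LeafletAssignment:
    """Per-(frame, lipid) leaflet labels.

    ``labels`` is a (n_frames, n_lipids) uint8 array (1 = outer, 0 = inner);
    ``molecule_ids`` / ``species`` give the lipid order of the columns.
    """

    labels: np.ndarray
    molecule_ids: np.ndarray
    species: np.ndarray
    dt_frame: float  # ns between frames

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    @property
    def n_lipids(self) -> int:
        return self.labels.shape[1]

    def labels_str(self) -> np.ndarray:
        return _LABELS[self.labels]

    def slice_frames(self, start: int, stop: int) -> "LeafletAssignment":
        return LeafletAssignment(self.labels[start:stop], self.molecule_ids,
                                 self.species, self.dt_frame)

    def column(self, molecule_id: int) -> int:
        pos = np.flatnonzero(self.molecule_ids == molecule_id)
        if pos.size != 1:
            raise KeyError(f"molecule {molecule_id} not in assignment")
        return int(pos[0])


def assign_leaflets(traj: Trajectory, species: SpeciesTable,
                    ref: ReferenceFrame | None = None) -> LeafletAssignment:
    """Label every lipid in every frame as outer/inner.

    The midplane is recomputed per frame from the lipid reference beads (it is
    taken from ``ref`` when supplied, which must have been built from the same
    trajectory).  Emits a warning for frames where every lipid falls on one
    side — a sign of a collapsed or mis-centred bilayer.
    """
    beads = species.reference_beads()
    idx = beads["particle_id"].to_numpy()
    z = traj.coords[:, idx, 2]
    midplane = ref.midplane_z if ref is not None else z.mean(axis=1)
    labels = (z > midplane[:, None]).astype(np.uint8)  # ties -> inner
    one_sided = np.flatnonzero((labels.min(axis=1) == labels.max(axis=1)) &
                               (labels.shape[1] > 1))
    if one_sided.size:
        warnings.warn(f"all lipids on one side of the midplane in "
                      f"{one_sided.size} frame(s), first at {one_sided[0]}")
    dt = traj.dt_frame if traj.n_frames > 1 else 0.0
    return LeafletAssignment(labels, beads["molecule_id"].to_numpy(),
                             beads["species"].to_numpy(), dt)


def _dwell_filter(series: np.ndarray, min_dwell: int) -> list[tuple[int, int]]:
    """Accepted label changes in one label series under dwell hysteresis.

    Returns (frame, new_label) pairs: a change is accepted when the new label
    persists for >= min_dwell consecutive frames starting at ``frame``.
    Short excursions are absorbed into the surrounding accepted label.
    """
    n = len(series)
    # run-length encode
    change = np.flatnonzero(np.diff(series)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    events = []
    current = series[starts[0]]
    for s, e in zip(starts, ends):
        lab = series[s]
        if lab == current:
            continue
        if e - s >= min_dwell:
            events.append((int(s), int(lab)))
            current = lab
    return events


def detect_flipflops(assign: LeafletAssignment, min_dwell: int = 10):
    """Extract flip-flop events from the leaflet labels with hysteresis.

    Returns ``(events, summary)``: ``events`` is a DataFrame (species,
    molecule_id, frame, direction); ``summary`` aggregates per species the
    event count, the total rate in events/us, and the per-molecule rate in
    events per molecule per ns (the generator's flip-rate parameterization).
    """
    if min_dwell < 1:
        raise ValueError("min_dwell must be >= 1")
    rows = []
    for col in range(assign.n_lipids):
        for frame, lab in _dwell_filter(assign.labels[:, col], min_dwell):
            direction = "inner->outer" if lab == 1 else "outer->inner"
            rows.append((assign.species[col], int(assign.molecule_ids[col]),
                         frame, direction))
    events = pd.DataFrame(rows, columns=["species", "molecule_id", "frame",
                                         "direction"])
    t_total_ns = (assign.n_frames - 1) * assign.dt_frame
    summ_rows = []
    for sp in np.unique(assign.species):
        n_mol = int((assign.species == sp).sum())
        n_ev = int((events["species"] == sp).sum()) if len(events) else 0
        per_us = n_ev / (t_total_ns / 1000.0) if t_total_ns else np.nan
        per_mol_ns = n_ev / (n_mol * t_total_ns) if t_total_ns else np.nan
        summ_rows.append((sp, n_mol, n_ev, per_us, per_mol_ns))
    summary = pd.DataFrame(summ_rows, columns=[
        "species", "n_molecules", "n_events", "rate_events_per_us",
        "rate_per_molecule_per_ns"])
    return events, summary


def leaflet_counts(assign: LeafletAssignment, frame_policy: str = "last_frame"
                   ) -> pd.DataFrame:
    """Molecule counts per (species, leaflet).

    ``last_frame`` returns the final-frame counts — the convention used to
    normalize cholesterol density maps when flip-flop makes the per-frame
    membership non-constant.  ``per_frame`` returns the time-average (float).
    """
    if frame_policy not in ("last_frame", "per_frame"):
        raise ValueError("frame_policy must be 'last_frame' or 'per_frame'")
    rows = []
    for sp in np.unique(assign.species):
        cols = assign.species == sp
        lab = assign.labels[:, cols]
        if frame_policy == "last_frame":
            outer = float((lab[-1] == 1).sum())
        else:
            outer = float((lab == 1).sum(axis=1).mean())
        total = float(cols.sum())
        rows.append((sp, OUTER, outer))
        rows.append((sp, INNER, total - outer))
    return pd.DataFrame(rows, columns=["species", "leaflet", "count"])
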