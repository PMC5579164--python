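"""Synthetic two-leaflet membrane trajectories with known ground truth.

Each lipid is represented by its reference bead (phosphate / ROH) performing
overdamped 2D Brownian motion in a flat leaflet plane, with

* a species- and radius-dependent diffusion coefficient D(r) (piecewise
  constant in distance from the protein centre),
* an optional radial square-well attraction towards the protein, applied
  through Metropolis acceptance,
* a static reflective disc ("protein") whose surface is marked by a ring of
  beads in each leaflet plane, and
* Poisson leaflet exchange (cholesterol flip-flop) with logged events.

The generator's job is to realize the statistical structure the analyses
assume — a slow annulus near the protein, anionic-lipid enrichment, and
stochastic flip-flop — with parameters that are known exactly, so that every
estimator in the package can be validated against them.

Conventions: the Ito convention is used for state-dependent D (D evaluated at
the step's start, no drift correction); with piecewise-constant profiles the
spurious-drift term vanishes away from the level boundaries, and the annular
diffusion estimator uses the same start-point convention, so recovered and
injected D agree by construction.  Note that uncorrected Ito dynamics makes
the stationary density proportional to 1/D(r); enrichment ground truth is
therefore exact (Boltzmann) only for species with uniform D, which is how the
enrichment presets are configured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    PROTEIN,
    ROLE_HEADGROUP,
    ROLE_PROTEIN,
    ROLE_ROH,
    SpeciesTable,
    Trajectory,
    min_image_displacement,
    wrap_coords,
)

__all__ = [
    "RadialProfile",
    "SquareWell",
    "MembraneSpec",
    "GroundTruth",
    "preset_bilayer",
    "PRESET_COMPOSITIONS",
    "simulate",
    "write_fixture",
]

OUTER, INNER = "outer", "inner"


@dataclass(frozen=True)
class RadialProfile:
    """Piecewise-constant radial profile: value ``values[i]`` applies on
    ``[breaks[i-1], breaks[i])`` with open-ended first and last pieces.
    Radii are distances from the protein centre (nm)."""

    breaks: tuple = ()
    values: tuple = (0.01,)

    def __post_init__(self):
        if len(self.values) != len(self.breaks) + 1:
            raise ValueError("need len(values) == len(breaks) + 1")
        if any(b2 <= b1 for b1, b2 in zip(self.breaks, self.breaks[1:])):
            raise ValueError("breaks must be strictly increasing")

    @property
    def is_uniform(self) -> bool:
        return len(self.breaks) == 0

    @property
    def max_value(self) -> float:
        return max(self.values)

    def at(self, r):
        idx = np.searchsorted(np.asarray(self.breaks), np.asarray(r, dtype=float),
                              side="right")
        return np.asarray(self.values)[idx]


@dataclass(frozen=True)
class SquareWell:
    """Attractive square well of ``depth`` (kT) within ``width`` (nm) of the
    protein surface: U(r) = -depth for protein_radius <= r < protein_radius+width."""

    depth: float
    width: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("well width must be positive")


@dataclass
class MembraneSpec:
    """Full parameterization of a synthetic membrane run.

    Compositions are molecule counts per species per leaflet.  ``d_profiles``
    and ``wells`` default to a uniform D of ``default_d`` and no attraction.
    """

    compositions: dict                       # {"outer": {species: n}, "inner": {...}}
    box_xy: tuple = (19.0, 19.0)
    box_z: float = 10.0
    leaflet_offset: float = 2.0              # leaflet planes at mid-z +/- offset (nm)
    protein_radius: float = 0.0              # 0 -> no obstacle, no protein beads
    n_ring_beads: int = 12                   # beads per leaflet marking the disc rim
    d_profiles: dict = field(default_factory=dict)   # {species: RadialProfile}
    default_d: float = 0.01                  # nm^2/ns  (= 1e-7 cm^2/s)
    wells: dict = field(default_factory=dict)        # {species: SquareWell}
    flip_rates: dict = field(default_factory=dict)   # {species: ns^-1}
    dt_sim: float = 0.05                     # ns
    frame_stride: int = 20                   # -> 1 ns between stored frames
    n_frames: int = 1000
    seed: int = 0

    # -- derived helpers ---------------------------------------------------
    def profile(self, species: str) -> RadialProfile:
        return self.d_profiles.get(species, RadialProfile((), (self.default_d,)))

    @property
    def species_names(self) -> list:
        names = []
        for leaf in (OUTER, INNER):
            for sp in self.compositions.get(leaf, {}):
                if sp not in names:
                    names.append(sp)
        return names

    @property
    def n_lipids(self) -> int:
        return sum(sum(c.values()) for c in self.compositions.values())

    @property
    def dt_frame(self) -> float:
        return self.dt_sim * self.frame_stride

    def validate(self) -> None:
        if self.n_lipids == 0:
            raise ValueError("no lipid molecules in composition")
        for leaf, comp in self.compositions.items():
            if leaf not in (OUTER, INNER):
                raise ValueError(f"unknown leaflet {leaf!r}")
            for sp, n in comp.items():
                if n < 0:
                    raise ValueError(f"negative count for {sp}")
        if self.protein_radius < 0:
            raise ValueError("protein_radius must be >= 0")
        if self.protein_radius >= min(self.box_xy) / 4.0:
            raise ValueError("protein_radius must be < min(box_xy)/4")
        d_max = max([self.default_d] +
                    [self.profile(sp).max_value for sp in self.species_names])
        if d_max <= 0:
            raise ValueError("diffusion coefficients must be positive")
        # rms step must stay well below the 1-nm analysis annulus
        if math.sqrt(2.0 * d_max * self.dt_sim) >= 0.2:
            raise ValueError(
                "dt_sim too large: sqrt(2 D_max dt_sim) must be < 0.2 nm "
                "to avoid discretization bias at annulus boundaries")
        if self.n_frames < 1 or self.frame_stride < 1 or self.dt_sim <= 0:
            raise ValueError("n_frames, frame_stride, dt_sim must be positive")


#: post-protein-insertion leaflet compositions of the three study bilayers.
PRESET_COMPOSITIONS = {
    "Asymm": {
        OUTER: {"POPC": 193, "SM": 261, "CHOL": 220},
        INNER: {"POPC": 240, "POPS": 123, "POPE": 139, "CHOL": 121},
    },
    "Symm_O": {
        OUTER: {"POPC": 226, "SM": 230, "CHOL": 237},
        INNER: {"POPC": 226, "SM": 229, "CHOL": 237},
    },
    "Symm_I": {
        OUTER: {"POPC": 190, "POPS": 124, "POPE": 157, "CHOL": 127},
        INNER: {"POPC": 189, "POPS": 124, "POPE": 156, "CHOL": 127},
    },
}

#: whole-bilayer totals used to split the symmetric presets across leaflets
#: (outer leaflet receives the extra molecule of an odd count):
#: Symm_O 452 POPC / 459 SM / 474 CHOL; Symm_I 379 POPC / 248 POPS /
#: 313 POPE / 254 CHOL; Asymm totals are per-leaflet already.


def preset_bilayer(name: str, **overrides) -> MembraneSpec:
    """MembraneSpec for one of the study bilayers (Asymm, Symm_O, Symm_I).

    Defaults: ~19 x 19 nm patch, a 1.2-nm protein disc, bulk D of
    0.01 nm^2/ns for every species, cholesterol flip-flop at 1e-3 ns^-1.
    Keyword overrides replace any MembraneSpec field.
    """
    if name not in PRESET_COMPOSITIONS:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(PRESET_COMPOSITIONS)}")
    comps = {leaf: dict(c) for leaf, c in PRESET_COMPOSITIONS[name].items()}
    kwargs = dict(
        compositions=comps,
        protein_radius=1.2,
        flip_rates={"CHOL": 1e-3},
    )
    kwargs.update(overrides)
    return MembraneSpec(**kwargs)


@dataclass
class GroundTruth:
    """Realized generator parameters plus everything an estimator test needs:
    the per-lipid flip-event log, initial leaflet labels, and the analytic
    enrichment factor e^depth implied by each square well (exact for species
    with uniform D)."""

    spec: MembraneSpec
    seed: int
    initial_leaflet: np.ndarray          # per lipid, "outer"/"inner"
    flip_events: pd.DataFrame            # time_ns, frame, molecule_id, species, direction
    enrichment_factors: dict             # {species: e^depth}

    def flip_rate_estimate(self, species: str) -> float:
        """Realized flip rate (events per molecule per ns) from the event log."""
        n_mol = sum(self.spec.compositions[leaf].get(species, 0)
                    for leaf in (OUTER, INNER))
        t_total = (self.spec.n_frames - 1) * self.spec.dt_frame
        n_ev = int((self.flip_events["species"] == species).sum())
        return n_ev / (n_mol * t_total) if n_mol and t_total else 0.0


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

def _initial_positions(rng, n, box_xy, center, protein_radius, weight=None):
    """Positions drawn from the stationary spatial law of the dynamics.

    ``weight(r)`` is the (unnormalized) stationary density as a function of
    distance from the protein centre — e^(-U(r)) for the Metropolis well term
    times 1/D(r) for the uncorrected-Ito state-dependent diffusion — sampled
    by rejection inside the box with the protein disc excluded.  Starting at
    stationarity removes the equilibration transient, so enrichment ground
    truth holds from the first frame.
    """
    out = np.empty((n, 2))
    got = 0
    box_xy = np.asarray(box_xy)
    w_max = None
    while got < n:
        cand = rng.random((max(2 * (n - got), 64), 2)) * box_xy
        d = min_image_displacement(center, cand, box_xy)
        r = np.hypot(d[:, 0], d[:, 1])
        keep = r >= protein_radius
        if weight is not None:
            if w_max is None:
                rr = np.linspace(protein_radius, np.hypot(*box_xy) / 2, 4096)
                w_max = float(np.max(weight(rr)))
            keep &= rng.random(len(cand)) * w_max < weight(r)
        cand = cand[keep]
        take = min(len(cand), n - got)
        out[got:got + take] = cand[:take]
        got += take
    return out


def _build_species_table(spec: MembraneSpec, species_arr, n_ring) -> SpeciesTable:
    records = []
    pid = 0
    for i, sp in enumerate(species_arr):
        role = ROLE_ROH if sp == "CHOL" else ROLE_HEADGROUP
        records.append((pid, i, sp, role, i + 1))
        pid += 1
    n_lip = len(species_arr)
    for j in range(n_ring):
        records.append((pid, n_lip + j, PROTEIN, ROLE_PROTEIN, n_lip + j + 1))
        pid += 1
    df = pd.DataFrame(records, columns=["particle_id", "molecule_id", "species",
                                        "role", "residue_id"])
    return SpeciesTable(df)


def simulate(spec: MembraneSpec):
    """Run the Brownian-dynamics generator.

    Returns ``(Trajectory, SpeciesTable, GroundTruth)``.  Fully reproducible
    from ``spec.seed``.  When there is no obstacle, no well and every species
    has uniform D, the free-diffusion propagator is sampled directly at the
    frame interval (distributionally identical to stepping at ``dt_sim`` and
    much faster); otherwise the generator steps at ``dt_sim`` with Metropolis
    acceptance for the well term and rejection at the reflective disc.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    Lx, Ly = spec.box_xy
    box2 = np.array([Lx, Ly])
    center = box2 / 2.0
    mid_z = spec.box_z / 2.0
    z_plane = {OUTER: mid_z + spec.leaflet_offset, INNER: mid_z - spec.leaflet_offset}

    # molecule bookkeeping, outer leaflet first
    species_list, leaflet_list = [], []
    for leaf in (OUTER, INNER):
        for sp, n in spec.compositions.get(leaf, {}).items():
            species_list.extend([sp] * n)
            leaflet_list.extend([leaf] * n)
    species_arr = np.array(species_list)
    leaflet_arr = np.array(leaflet_list)
    n_lip = len(species_arr)

    pos = np.empty((n_lip, 2))
    for sp in spec.species_names:
        idx_sp = np.flatnonzero(species_arr == sp)
        if idx_sp.size == 0:
            continue
        prof = spec.profile(sp)
        well = spec.wells.get(sp)
        if well is None and prof.is_uniform:
            weight = None
        else:
            lo = spec.protein_radius
            hi = lo + (well.width if well else 0.0)
            depth = well.depth if well else 0.0

            def weight(r, lo=lo, hi=hi, depth=depth, prof=prof):
                u = np.where((r >= lo) & (r < hi), -depth, 0.0)
                return np.exp(-u) * (prof.max_value / prof.at(r))

        pos[idx_sp] = _initial_positions(rng, idx_sp.size, (Lx, Ly), center,
                                         spec.protein_radius, weight)
    z = np.where(leaflet_arr == OUTER, z_plane[OUTER], z_plane[INNER]).astype(float)

    # protein ring beads (static): one ring per leaflet plane
    if spec.protein_radius > 0:
        ang = 2.0 * np.pi * np.arange(spec.n_ring_beads) / spec.n_ring_beads
        ring = center + spec.protein_radius * np.column_stack([np.cos(ang), np.sin(ang)])
        prot_xyz = np.vstack([
            np.column_stack([ring, np.full(spec.n_ring_beads, z_plane[OUTER])]),
            np.column_stack([ring, np.full(spec.n_ring_beads, z_plane[INNER])]),
        ])
    else:
        prot_xyz = np.empty((0, 3))
    n_prot = len(prot_xyz)

    table = _build_species_table(spec, species_arr, n_prot)

    sp_idx = {sp: np.flatnonzero(species_arr == sp) for sp in spec.species_names}
    flip_species = [sp for sp, r in spec.flip_rates.items() if r > 0 and sp in sp_idx]
    well_species = [sp for sp in spec.wells if sp in sp_idx]
    nonuniform = [sp for sp in spec.species_names if not spec.profile(sp).is_uniform]

    free_case = (spec.protein_radius == 0 and not well_species and not nonuniform)

    n_frames = spec.n_frames
    coords = np.empty((n_frames, n_lip + n_prot, 3))
    events = []  # (time_ns, frame, molecule_id, species, direction)

    def record_frame(k):
        coords[k, :n_lip, 0] = pos[:, 0]
        coords[k, :n_lip, 1] = pos[:, 1]
        coords[k, :n_lip, 2] = z
        if n_prot:
            coords[k, n_lip:] = prot_xyz

    def do_flips(dt, time_ns, frame):
        for sp in flip_species:
            idx = sp_idx[sp]
            p = -np.expm1(-spec.flip_rates[sp] * dt)
            hit = idx[rng.random(idx.size) < p]
            for m in hit:
                if z[m] == z_plane[OUTER]:
                    z[m] = z_plane[INNER]
                    events.append((time_ns, frame, int(m), sp, "outer->inner"))
                else:
                    z[m] = z_plane[OUTER]
                    events.append((time_ns, frame, int(m), sp, "inner->outer"))

    record_frame(0)
    if free_case:
        # exact free-diffusion propagator at the frame interval
        sigma = np.empty(n_lip)
        for sp, idx in sp_idx.items():
            sigma[idx] = math.sqrt(2.0 * spec.profile(sp).values[0] * spec.dt_frame)
        for k in range(1, n_frames):
            pos += rng.normal(0.0, 1.0, (n_lip, 2)) * sigma[:, None]
            pos[:] = wrap_coords(pos, box2)
            do_flips(spec.dt_frame, k * spec.dt_frame, k)
            record_frame(k)
    else:
        # full stepper at dt_sim
        D = np.empty(n_lip)
        for sp, idx in sp_idx.items():
            prof = spec.profile(sp)
            if prof.is_uniform:
                D[idx] = prof.values[0]
        depth = np.zeros(n_lip)
        well_lo = spec.protein_radius
        well_hi = np.zeros(n_lip)
        for sp in well_species:
            depth[sp_idx[sp]] = spec.wells[sp].depth
            well_hi[sp_idx[sp]] = spec.protein_radius + spec.wells[sp].width
        has_well = depth != 0

        def radii(p):
            d = min_image_displacement(center, p, box2)
            return np.hypot(d[:, 0], d[:, 1])

        r_cur = radii(pos)
        dt = spec.dt_sim
        for k in range(1, n_frames):
            for _ in range(spec.frame_stride):
                for sp in nonuniform:
                    idx = sp_idx[sp]
                    D[idx] = spec.profile(sp).at(r_cur[idx])
                prop = pos + rng.normal(0.0, 1.0, (n_lip, 2)) * \
                    np.sqrt(2.0 * D * dt)[:, None]
                prop = wrap_coords(prop, box2)
                r_new = radii(prop)
                accept = np.ones(n_lip, dtype=bool)
                if spec.protein_radius > 0:
                    accept &= r_new >= spec.protein_radius
                if well_species:
                    u_old = np.where(has_well & (r_cur >= well_lo) &
                                     (r_cur < well_hi), -depth, 0.0)
                    u_new = np.where(has_well & (r_new >= well_lo) &
                                     (r_new < well_hi), -depth, 0.0)
                    du = u_new - u_old
                    uphill = accept & (du > 0)
                    if uphill.any():
                        accept[uphill] &= rng.random(int(uphill.sum())) < \
                            np.exp(-du[uphill])
                pos[accept] = prop[accept]
                r_cur[accept] = r_new[accept]
            t_ns = (k - 1) * spec.dt_frame
            # flips drawn once per frame interval (rates are slow vs dt_frame)
            do_flips(spec.dt_frame, t_ns + spec.dt_frame, k)
            record_frame(k)

    times = np.arange(n_frames) * spec.dt_frame
    box = np.tile([Lx, Ly, spec.box_z], (n_frames, 1))
    traj = Trajectory(coords, times, box)
    ev = pd.DataFrame(events, columns=["time_ns", "frame", "molecule_id",
                                       "species", "direction"])
    truth = GroundTruth(
        spec=spec, seed=spec.seed, initial_leaflet=leaflet_arr, flip_events=ev,
        enrichment_factors={sp: math.exp(w.depth) for sp, w in spec.wells.items()},
    )
    return traj, table, truth


# --------------------------------------------------------------------------
# fixture writing
# --------------------------------------------------------------------------

_BEAD_NAME = {ROLE_HEADGROUP: "PO4", ROLE_ROH: "ROH", ROLE_PROTEIN: "BB"}
_RESNAME = {PROTEIN: "PROT"}


def write_fixture(traj: Trajectory, species: SpeciesTable, truth: GroundTruth | None,
                  out_dir, basename: str = "membrane"):
    """Write a GRO topology frame + XTC trajectory (+ ground-truth metadata).

    Returns the paths written.  ``load_trajectory`` round-trips the output
    with the default naming config.
    """
    import MDAnalysis as mda

    if species.n_lipids == 0:
        raise ValueError("refusing to write a fixture with no lipid molecules")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    df = species.df
    n_atoms = len(df)
    resindex = df["molecule_id"].to_numpy()
    # remap molecule ids to dense residue indices
    uniq, dense = np.unique(resindex, return_inverse=True)
    u = mda.Universe.empty(n_atoms, n_residues=len(uniq), atom_resindex=dense,
                           trajectory=True)
    u.add_TopologyAttr("names", [_BEAD_NAME[r] for r in df["role"]])
    resnames = (df.drop_duplicates("molecule_id").sort_values("molecule_id")
                ["species"].map(lambda s: _RESNAME.get(s, s)).tolist())
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", (np.arange(len(uniq)) + 1) % 100000)

    gro_path = out_dir / f"{basename}.gro"
    xtc_path = out_dir / f"{basename}.xtc"

    u.atoms.positions = traj.coords[0] * 10.0
    u.dimensions = [traj.box[0, 0] * 10, traj.box[0, 1] * 10, traj.box[0, 2] * 10,
                    90, 90, 90]
    u.atoms.write(str(gro_path))

    with mda.Writer(str(xtc_path), n_atoms=n_atoms) as w:
        for k in range(traj.n_frames):
            u.atoms.positions = traj.coords[k] * 10.0
            u.dimensions = [traj.box[k, 0] * 10, traj.box[k, 1] * 10,
                            traj.box[k, 2] * 10, 90, 90, 90]
            u.trajectory.ts.time = traj.times[k] * 1000.0  # ns -> ps
            u.trajectory.ts.frame = k
            w.write(u.atoms)

    paths = {"gro": gro_path, "xtc": xtc_path}
    if truth is not None:
        meta = {
            "seed": truth.seed,
            "n_frames": traj.n_frames,
            "dt_frame_ns": truth.spec.dt_frame,
            "n_lipids": species.n_lipids,
            "box_xy_nm": list(truth.spec.box_xy),
            "protein_radius_nm": truth.spec.protein_radius,
            "default_d_nm2_ns": truth.spec.default_d,
            "compositions": {leaf: dict(c) for leaf, c
                             in truth.spec.compositions.items()},
            "flip_rates_per_ns": dict(truth.spec.flip_rates),
            "enrichment_factors": dict(truth.enrichment_factors),
            "initial_leaflet": truth.initial_leaflet.tolist(),
        }
        truth_path = out_dir / f"{basename}.truth.yaml"
        with open(truth_path, "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)
        events_path = out_dir / f"{basename}.flips.csv"
        truth.flip_events.to_csv(events_path, index=False)
        paths["truth"] = truth_path
        paths["flips"] = events_path
    return paths
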