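# Methods

This note records the models, conventions and numerical choices behind
`annulipid`, and what the synthetic-membrane validation does and does not
demonstrate about real trajectories.

## Geometry and units

Internal units are nm and ns throughout; diffusion coefficients are reported
both in nm²/ns and cm²/s (1 nm²/ns = 1e-5 cm²/s, covered by a unit test).
Only orthorhombic periodic boxes are supported; triclinic input raises an
explicit error.  Coordinates are treated as wrapped on input, and all
displacement arithmetic uses the minimum-image convention rather than
trajectory unwrapping.  That is valid only while no particle moves more than
a half box between stored frames; the loader asserts a stricter L/4 bound on
lateral per-frame displacements and refuses trajectories that violate it.
The z component is exempt from this check because cholesterol flip-flop
legitimately jumps a lipid by the bilayer thickness between frames.

The shared reference frame has two parts, both recomputed per frame:

- the **protein lateral centre**: the circular-mean (periodic-aware) xy
  centre of the chosen protein selection.  By convention the selection is
  the transmembrane region only — the ectodomain sways far from the bilayer
  and would drag the lateral centre off the TM axis.  Whether per-frame or
  trajectory-averaged centres are more faithful to published analyses is not
  decidable from the descriptions available; per-frame is implemented, and
  for a protein whose TM region drifts slowly the two agree closely.
- the **bilayer midplane**: the mean z of all lipid reference beads
  (phosphate for phospholipids and sphingomyelin, ROH for cholesterol).
  The protein never enters the midplane, so it cannot bias leaflet
  assignment.

## Leaflets and flip-flop

A lipid is "outer" in a frame when its reference bead lies strictly above
the midplane; a bead exactly at the midplane is assigned inner
(deterministic tie-break).  Flip-flop events are read off the label series
with dwell hysteresis: a label change counts only when the new label
persists for at least `min_dwell` frames (default 10).  No published
criterion defines a completed flip, so the dwell rule is this package's
operationalization.

The dwell filter trades noise immunity for a small censoring bias: a flip
whose follow-up flip lands within the dwell window is absorbed, removing
both events — roughly a fraction 2·(1 − e^(−rate·dwell)) of all events for
Poisson flipping.  At the cholesterol exchange rates and dwell defaults used
here this is ~2% and lies well inside Poisson counting error for
10-μs-scale trajectories; it is not corrected for.  The rate-recovery
validation uses a 3-frame dwell because synthetic labels carry no
midplane chatter, making the filter pure censoring there.

Leaflet counts support two policies.  `per_frame` returns time-averaged
occupancy; `last_frame` returns final-frame counts and is the policy used to
normalize cholesterol density maps, since flip-flop makes cholesterol's
per-frame membership non-constant.  For non-flipping species the two
coincide.

## Density maps

`density_map_2d` histograms reference-bead xy positions over frames in the
protein-centred frame (coordinates translated so the protein centre sits at
the grid centre, then wrapped) and divides by
`bin area × n_frames × N_leaflet` with `N_leaflet` the last-frame count.
For constant membership the map integrates to exactly 1; with flip-flop the
integral equals (mean per-frame count)/(last-frame count), an identity the
tests assert directly.  A lab-fixed map is available by omitting the
reference frame.  Bin edges are snapped to divide the box exactly
(default 0.2 nm, a free choice); the grid is fixed to the first frame's box
and the code refuses boxes that fluctuate by more than 1%.

## Lateral RDF

`g(r)` counts reference beads in annular shells (default width 0.2 nm)
around the protein lateral centre and divides by the bulk density, defined
as the scope's molecule count over (box area − protein disc area) —
excluding the disc is what lets g(r) plateau at 1 in an obstructed box.
Distances are measured to the TM centre of mass, not to the nearest protein
bead, so the density and diffusion profiles share one radial axis.  Shells
beyond the inscribed circle of the (square) box are truncated with the
exact circle-in-square overlap area, verified against 2D quadrature;
summing shell counts over the full range recovers the molecule count per
frame identically.  Cholesterol is analysed whole-bilayer only (enforced),
because per-leaflet scopes are ill-defined under flip-flop.

Per-shell standard errors come from contiguous frame blocks.  A caveat
that matters for error bars generally: shell-occupancy fluctuations contain
box-scale density modes that decorrelate over L²/(4π²D) — about a
microsecond at these D values — so block SEs are trustworthy only when
blocks are much longer than that, or when frames are spaced widely enough
to be independent.  The calibration experiments below are designed around
this.

## Annular diffusion

The estimator follows the 2D Einstein relation D(Δt) = MSD(Δt)/(4Δt),
with MSD averaged over lipids and overlapping window origins (stride 1 by
default; overlap inflates correlation, which block errors absorb, not the
mean).  Displacements are accumulated from per-frame minimum-image steps.
The plane is divided into annuli of width 1 nm; annulus 0 spans 0–10 Å
from the protein centre.  Each window is assigned to the annulus (and
leaflet) containing the lipid at the window's **start** frame — the one
convention that never discards windows and that the generator's ground
truth can reproduce exactly.  Annuli with no observations report missing
values, never zero.  The default reported timescale is Δt = 6 ns over a
{1, 2, 4, 6, 10, 20} ns grid, and D(r)/D_bulk ratios use an
observation-weighted bulk over annuli whose inner edge is ≥ 5 nm, where
the radial profile has plateaued.

Error bars are standard deviations (population convention) of the quantity
recomputed on five equal contiguous sub-trajectories, mirroring 5 × 2 μs
splits of a 10-μs run; whether such splits should overlap is not specified
anywhere, and non-overlapping contiguous blocks are used.

Two known estimator properties, both visible in the validation output:
windows that start near a reflective obstacle have geometrically restricted
paths, biasing near-wall D slightly low even for uniform-D systems (a
confinement effect of the measurement, ~5–10% in the first annulus at
Δt = 2 ns with a 0.5-nm disc); and windows starting just inside a D-level
boundary mix the two levels over long Δt, which is why recovery checks run
at short Δt.

## Contacts

A contact is one (protein residue, lipid molecule, frame) triple with any
selected bead pair within the cutoff; counting per molecule rather than per
bead pair prevents species with more beads from inflating their counts.
The cutoff default is 0.6 nm — common coarse-grained practice; no published
value constrains it — and both cutoff and bead scope (headgroup-only vs all
lipid beads) are exposed and recorded in output metadata.  Pair search uses
a KD-tree with periodic box support.  Normalization divides by the single
global maximum over the whole complex (one shared scale across domains,
idempotent by construction), and cross-system error bars are population
standard deviations of normalized values across replicate systems.
Normalized values can be written into PDB B-factors for blue–white–red
structure rendering.

## The synthetic membrane generator

Each lipid is a single reference bead performing overdamped 2D Brownian
motion in a flat leaflet plane (planes at mid-z ± 2 nm in a 19 × 19 × 10 nm
box).  Per step of `dt_sim` (default 0.05 ns): a Gaussian proposal with
per-axis variance 2·D(r)·dt_sim, D evaluated at the step's start (Itô
convention, no drift correction); Metropolis acceptance on the square-well
potential (U = −depth within `width` of the protein-disc surface); rejection
of moves entering the reflective disc; periodic wrap.  Frames are stored
every `frame_stride` steps (default 1 ns of simulated time; no convention
exists for frame spacing, and the value is recorded in the ground-truth
metadata).  Species with a flip rate swap leaflet planes as a Poisson
process, with every event logged.  A spec validator enforces
sqrt(2·D_max·dt_sim) < 0.2 nm so that discretization error at annulus and
well boundaries stays far below the 1-nm analysis resolution.

Three exact properties make the generator a usable oracle:

1. **Free case is exact.**  With uniform D, no well and no obstacle, the
   free propagator is sampled directly at the frame interval —
   distributionally identical to fine stepping at any spacing, which is also
   what lets calibration runs use microsecond frame spacing for independent
   frames at no cost.
2. **Stationary initialization.**  Initial positions are rejection-sampled
   from the stationary spatial law — e^(−U(r)) for the well term times
   1/D(r) for the Itô state-dependent diffusion — so enrichment ground truth
   holds from the first frame with no equilibration transient.
3. **Detailed balance for uniform D.**  With symmetric proposals, Metropolis
   makes e^(−U) exactly stationary, and rejection at the hard disc preserves
   uniformity exactly; the Boltzmann factor e^depth is therefore the exact
   enrichment oracle for uniform-D species.

One deliberate physical quirk: uncorrected Itô dynamics with
position-dependent D has stationary density ∝ 1/D(r), so a slow annulus
accumulates density even without a well.  This is harmless for
diffusion-profile recovery (window statistics condition on the start
position) and actually reinforces the qualitative density/mobility coupling
the joint consistency check looks for; quantitative Boltzmann checks are
confined to uniform-D species, where the stationary law is exact.

Preset compositions reproduce the study bilayers after protein insertion:
Asymm (outer 193 POPC / 261 SM / 220 CHOL; inner 240 POPC / 123 POPS /
139 POPE / 121 CHOL; 1297 lipids total), Symm_O (452/459/474) and Symm_I
(379 POPC / 248 POPS / 313 POPE / 254 CHOL), symmetric presets split evenly
across leaflets with the odd molecule assigned to the outer leaflet.
Fixtures are written as GRO + XTC through MDAnalysis with ground truth in a
YAML sidecar, and round-trip through the loader at format precision
(0.001 nm).

### What the generator does not emulate

Flat leaflets (no undulations or curvature), no lipid–lipid interactions or
excluded volume, no lipid tails or orientational order, a static protein
disc rather than a diffusing, corrugated protein, and instantaneous
flip-flop.  Passing the recovery tests therefore demonstrates that the
estimators are correct and calibrated for the statistical structure they
claim to measure — obstructed, radially varying diffusion; radial
enrichment; Poisson leaflet exchange — not that a real membrane satisfies
those models.  On real trajectories the same code measures the analogous
quantities, but undulations (leaflet assignment), protein shape (first-shell
geometry) and frame spacing (minimum-image validity) must be within the
stated assumptions.

## Calibration experiments

`annulipid.validation` packages the recovery runs that the test suite
asserts and `scripts/acceptance.py` reports.  Sizes were chosen so each runs
in seconds-to-a-minute on one CPU with statistical error well below the
tolerance checked:

- **Einstein recovery**: 500 lipids × 10⁴ frames at uniform
  D = 0.01 nm²/ns (1e-7 cm²/s, the bulk-lipid order of magnitude);
  D(Δt = 6 ns) recovers truth to ~0.1% against a 2% tolerance.
- **Annular recovery**: two-level profile (0.5 × bulk inside 2.5 nm of a
  0.3-nm disc), 700 lipids × 6000 frames; annulus-0/bulk ratio at
  Δt = 2 ns recovers 0.5 within a few percent.  The uniform null run
  confirms no annulus deviates from bulk beyond its block SD band.
- **RDF calibration**: the ideal-gas run stores frames every 1000 ns so
  they are independent (the free propagator is exact at any interval) and
  uses 1-nm shells to the inscribed radius, keeping the per-shell 3-SE
  check well posed; the Boltzmann-well run uses 8 independent replicate
  membranes, each starting at stationarity, with the SE taken across
  replicates — within-run error bars would be deflated by the ~μs
  occupancy correlation time.
- **Density mass**: all seven (species, leaflet) maps of the Asymm bilayer
  integrate to 1 to 1e-12 (machine precision in practice), cholesterol via
  the last-frame-count path.
- **Flip-rate recovery**: 200 cholesterol at 1e-3 ns⁻¹ over 10 μs
  equivalent, ten seeds; detected event counts against the central 95%
  Poisson interval.
- **Density/mobility consistency**: a species given both a 1-kT well and a
  slow annulus shows a higher first-shell g(r) *and* a lower annulus-0
  D ratio than an unbiased control species in the same membrane.

## Known limitations

- Single-bead lipids mean bead-scope distinctions in contact analysis only
  become meaningful on real multi-bead topologies.
- Block error bars inherit the usual requirement that blocks exceed the
  observable's correlation time; for occupancy-like observables at these D
  values that is ~1 μs, longer than desk-scale runs — the validation
  experiments route around this with independent frames or replicates, but
  error bars on short real trajectories should be read as lower bounds.
- The hysteresis flip detector under-counts by ~2·(1 − e^(−rate·dwell));
  negligible at the rates studied, but material for fast-flipping species.
- The RDF reference point is the TM lateral COM; a minimum-distance-to-
  surface variant would shift first-shell positions for non-circular
  proteins and is not implemented.
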