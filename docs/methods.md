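# Methods

## Scope

The package implements the *scaffolding* of an embedded-cluster
solid-state NMR protocol: periodic model handling, cluster construction,
charge self-consistency, engine input/output, snapshot averaging, and
the regression evaluation layer. All electronic structure (SCF, GIAO
shieldings, electron-density ESP charges, dispersion, PNO truncations,
MD forces) lives behind the engine boundary in `qm_io`: the package
writes decks and point-charge files and parses shielding output. The
mock backend stands in for the engine wherever a deterministic,
environment-sensitive model suffices to exercise the pipeline.

## Periodic model (`crystal`)

Cells are stored as lengths/angles; the Cartesian frame follows the
standard crystallographic convention (a ∥ x, b in the xy-plane), and
fractional↔Cartesian transforms round-trip to 1e-10. Symmetry operations
act on fractional coordinates as x′ = Rx + t with translations reduced
to [0, 1); CIF symmetry strings are parsed through gemmi and both the
`_symmetry_equiv_pos_as_xyz` and `_space_group_symop_operation_xyz`
dialects are accepted.

Molecule perception bonds atoms i, j when their distance is at most
(r_cov(i)+r_cov(j))·(1+tol) with tol = 0.25, the common heuristic;
covalent radii come from gemmi. Under periodic boundary conditions the
minimum image is found by explicit search over the 27 neighbour offsets
(exact for arbitrarily skewed cells), and molecules are unwrapped by
breadth-first propagation of the image offsets so they stay contiguous
across cell boundaries.

Symmetry expansion wraps each generated molecule by its *centroid* (not
per atom), keeping molecules intact; images coinciding within 1e-3 Å
(special positions) are merged, and distinct molecules with contacts
below 0.5 Å raise a clash error. Every generated atom carries the
identity (site_id, op_id, cell_offset), which uniquely names it in any
supercell and is the key for mapping per-site properties onto periodic
images.

Crystal structures must be hydrogen-complete; the package does not place
missing hydrogens (X-ray CIFs without H positions need preprocessing,
and how that is done materially affects shieldings, so it is left
explicit to the user).

## Cluster construction (`cluster`)

The QM2 shell contains every symmetry image (searched over ±2 cells)
with any-atom distance ≤ cutoff from QM1, sorted by that distance.
Hydrogen atoms count toward the distance criterion — for H-bonded
crystals the nearest contact usually *is* an H···O distance, and
excluding H would make the shell definition depend on protonation
conventions. The default cutoff is 3.0 Å, the midpoint of the range a
first-shell definition typically needs; it is a per-call parameter
because the value that captures "all touching neighbours" is
system-dependent. A cutoff beyond the guaranteed coverage radius of the
search block (twice the minimum perpendicular cell width times the
search half-width) is rejected explicitly rather than returning a
silently truncated shell.

The MM lattice places one point charge at every atom position of an
n×n×n supercell (default n = 9) *except* positions belonging to QM1/QM2
atoms, so the count identity N_pc = n³·N_cell − N_QM holds exactly and
whole-molecule removal of neutral molecules keeps the total MM charge at
zero. Removal is by atom membership, not by evicting whole central
cells: the charge lattice should begin immediately outside the QM
region.

Hydrogen relaxation uses a freeze mask freeing exactly the QM1
hydrogens. After an (external) optimization, `rebuild_cluster` pulls
each site's displacement back to the asymmetric unit through QM1's
generating operation and pushes it forward through every image's
operation, so all QM2 molecules and MM charges move consistently with
the space-group symmetry; motion of any frozen atom above 1e-6 Å is an
error.

Crystals with two alternative proton orientations (e.g. a labile S–H or
O–H) are handled as two independent cluster builds whose shielding
tables are averaged downstream with `average_tables`.

## Charge self-consistency (`embedding`)

Iteration 0 computes QM1 charges with no environment; each subsequent
iteration rebuilds the MM lattice from the previous charges (mapped by
site_id) and recomputes. Convergence is the per-atom maximum absolute
change ≤ tol, default tol = 0.01 e — the strictest common reading of a
scalar "threshold of 0.01"; an RMS metric is available by flag. Charges
are carried at full precision between iterations, neutrality is checked
to 1e-6 e at every step, and non-convergence within max_iter = 50 raises
an error carrying the full history (never a silent truncation).

The ESP-fitting machinery minimizes Σ_g (V_g − Σ_i q_i/|r_g − r_i|)²
subject to Σq_i = Q via the KKT system; the Coulomb kernel is evaluated
in atomic units (Å→bohr, 0.529177210903 Å/bohr). Rank-deficient systems
(degenerate grids, coincident atoms) fall back to the minimum-norm
solution with a warning. The sampling grid is a cubic lattice at 0.5 Å
spacing restricted to the shell between 1.4× the van-der-Waals radius
and 2.8 Å — a grid-based ESP dialect in the CHELPG family, documented as
this package's convention rather than claimed identical to any engine's.

Three deterministic providers exist for testing and demonstration: a
constant provider (immediate fixed point), a linear-response provider
q′ = q₀ + λMq with the analytic fixed point (I − λM)q = q₀ (used to
verify multi-iteration convergence against an independent solve), and a
polarizable ESP-refit provider whose "true" charges shift linearly with
the external potential at the nuclei (neutrality-projected) and are then
re-fitted from their own ESP. The polarization response of the default
toy systems is mild (~1e-3 e per iteration 1), so that provider
converges within one or two iterations at the 0.01 e threshold; the
multi-iteration behaviour of the loop is therefore exercised by the
linear-response provider, whose contraction rate is a free parameter.

## Engine contract (`qm_io`)

Input decks follow an ORCA-style dialect: a keyword line (method,
dispersion for DFT, RI approximation, grid, NMR), a point-charge file
reference, per-atom fragment tags (QM1 = fragment 1 with the large
basis, QM2 = fragment 2 with the smaller one), and an NMR block
requesting shieldings for the fragment-1 nuclei only. Correlated
methods (DLPNO-MP2, DLPNO-DSD-PBEP86) additionally emit the multilevel
pair-natural-orbital keywords: electron pairs touching fragment 1 at
the tighter tier ("NormalPNO"), the rest at the looser one ("LoosePNO").
Deck writing is a pure function of (cluster, spec) and byte-reproducible;
a golden-file test freezes the emitted dialect. The point-charge file is
a count line followed by `q x y z` records at fixed 6-decimal precision.

The mock backend computes σ = σ₀(element) + c(element)·V with V the
point-charge Coulomb potential (a.u.) at the nucleus from all QM2
partial charges and MM charges. Baselines are σ₀ = 30 ppm (H) and
150 ppm (C); response constants (40 ppm/a.u. for H, 120 for C) are sized
so typical toy-crystal fields shift σ by ~1–3 ppm, comparable to real
crystal-packing effects. The model is exactly invariant under rigid
motion of the whole cluster and symmetric charge arrangements produce
exactly equal shieldings, which the tests exploit as oracles.

## Snapshot averaging (`dynamics`)

The default schedule is 1 fs time steps, a 40 ps run, 1 ps of
equilibration, and 100 snapshots evenly separated by 0.3 ps. Snapshot
times are t_k = equil + k·interval for k = 1…100, i.e. 1.3 ps through
31.0 ps — the first frame is placed one full interval after
equilibration (a documented convention; placing one at exactly 1.0 ps
would be equally consistent with "evenly separated"). Schedules whose
sampling overruns the run length, or whose interval is not a whole
number of time steps, are rejected.

Snapshot geometries are used as produced by the (external) MD engine
with no re-minimization. The synthetic stand-in displaces QM1 hydrogens
by independent isotropic Gaussians (heavy atoms fixed, matching the
constrained-MD protocol) and is seed-reproducible. The vibrational
correction is Δσ = ⟨σ⟩_snapshots − σ_rigid per nucleus, computed once at
a cheap level of theory and applied additively to tables from any level;
by construction applying Δσ to the rigid table reproduces the snapshot
mean exactly.

## Evaluation (`stats`)

The regression direction is σ on δ (σ = aδ + b), with predicted shifts
obtained by inverting the fitted line — not by re-fitting δ on σ. R² is
the squared Pearson correlation of that fit. Error metrics are computed
from e = δ_calc − δ_exp: MAE, MaxAE with the worst nucleus labelled as
`nucleus(system)`, SDE as the sample standard deviation (n−1), and MSE
as the signed mean. Because OLS residuals average to zero, the MSE of
fit-referenced predictions vanishes identically — a useful internal
consistency check, and the reason absolute (TMS-referenced) shifts,
which do carry a systematic offset, are reported separately via
δ = σ_ref − σ.

Table rendering rounds half-even at display precision (2 decimals,
R² at 4). Corrections (`apply_correction`) require exact nucleus-label
agreement; a missing entry is an error, never a silent zero.

## Fixtures and synthetic data (`synthdata`)

The packaged benchmark covers six amino-acid molecular crystals: 26 ¹H
and 19 ¹³C nuclei, each with an experimental shift and shieldings at
five levels of theory (PBE, TPSS, B3LYP, DLPNO-DSD-PBEP86, DLPNO-MP2)
from full QM1/QM2/MM embedded-cluster calculations. The CSVs are
transcribed values, verified against frozen SHA-256 checksums at load
time, with any typographic minus normalized to ASCII. Ablation variants
(QM1-only, QM1/MM, GIPAW reference rows) are *not* packaged: they are
not derivable from the shipped per-nucleus data and would require
licensed crystal structures plus a quantum engine to regenerate, so the
loaders expose exactly the five full-embedding methods.

The toy-crystal generator places a bent three-atom polar molecule
(water-like geometry, reference charges −0.8/+0.4/+0.4 e) at a general
position of a P1 or P2₁ cell with a seed-derived rigid orientation.
The default cell (3.8 × 4.0 × 4.3 Å) gives nearest intermolecular
contacts of ~2.4–3.1 Å — van-der-Waals packing distances — so a 3.0 Å
cutoff yields a non-trivial QM2 shell and the mock shieldings feel the
crystal field at the few-ppm level. Cells too small for the molecule
(periodic images falling within bonding distance, which would silently
rewrite the perceived geometry) are rejected at generation time.

### What the synthetic layer does and does not show

Toy crystals exercise symmetry propagation, shell selection, charge
lattices, and self-consistency with exhaustive, independently coded
oracles, and the mock shielding model makes the full pipeline’s data
flow testable end to end (planted referencing lines are recovered to
within the noise level). They do not validate electronic-structure
accuracy, real CHELPG charges, basis-set effects, or the physics of the
vibrational correction — those depend on the external engine and real
crystal structures, and claims about them rest on the packaged benchmark
tables only. The 13/14-molecule QM-region sizes of the real amino-acid
clusters likewise require the licensed structures and are covered by
external-integration usage, not desk-scale tests.

## Numerical choices

* Bond tolerance 0.25; special-position merge 1e-3 Å; clash threshold
  0.5 Å; MM/QM clearance 1e-4 Å; frozen-atom motion tolerance 1e-6 Å.
* Charge neutrality tracked to 1e-6 e; convergence threshold 0.01 e
  (max-change metric).
* Coordinate round-trips to 1e-10; all lengths in Å, charges in e,
  shieldings/shifts in ppm, potentials in atomic units.
* Problem sizes in tests and the acceptance script: supercells n = 3–5
  and ±2-cell shell searches for toy systems — large enough for every
  identity checked to be non-trivial while keeping exhaustive oracles
  exact; the production default remains n = 9.

## Known limitations

* One molecule per asymmetric unit is assumed by the convenience
  builders (multi-molecule asymmetric units are perceived correctly but
  QM1 selection takes the first molecule).
* Disorder handling is limited to building each stated conformer
  separately and averaging shieldings.
* The minimum-image search uses ±1 cells, which is exact for molecules
  smaller than half the cell but would need a wider search for extreme
  aspect ratios.
* No space-group inference: operations must be supplied (CIF or
  explicit).
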