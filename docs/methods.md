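# Methods

## Scope and model

`lscdock` performs rigid-body protein–protein docking by exhaustive search
over the six rigid degrees of freedom: ligand orientations are enumerated
on a fixed quasi-uniform grid of Euler angles, and for each orientation
every lattice translation is scored at once with a 3D FFT.  The score is a
purely geometric *long-range shape complementarity*: no electrostatics,
desolvation or statistical potentials, no flexibility, no post-docking
refinement.  Both partners are treated as rigid clouds of van der Waals
spheres.

## Lattice discretization and layers

Each partner is mapped onto a cubic N×N×N lattice (default spacing
**1.2 Å**).  A lattice point is *inside* the protein when it lies within
the VDW radius of at least one atom (closed ball).  Inside points are then
partitioned with face (6-)connectivity, off-grid neighbors counting as
outside:

* **surface** — inside points with an outside face-neighbor (the spacer
  layer between interior and exterior);
* **near-surface** — remaining inside points with a surface face-neighbor
  (the layer typically occupied by atoms);
* **core** — all remaining inside points.

6-connectivity is the default because with 26-connectivity a single atom's
entire inside set touches an outside corner neighbor and becomes surface,
leaving no near-surface layer anywhere thin; the connectivity is a
parameter for sensitivity studies.

VDW radii come from a plain-text element-keyed table shipped with the
package (C 1.9, N 1.7, O 1.6, S 2.0, H 1.2, P 2.1, default 1.8 Å).  These
are conventional united-atom-style values; the table is a configuration
knob (`--radii-table`) so any preferred set can be substituted.  Hydrogens
are used if present in the input; no protonation or structure repair is
attempted.  All chains of one input file form a single rigid body; HETATM
records are excluded by default.

## The complex-valued score grids

With J the imaginary unit and r the Euclidean distance *in lattice-index
units* between two points, the receptor field is

| layer        | value                                                      |
|--------------|------------------------------------------------------------|
| surface      | −Σ exp[−(r−1)²] + J  (sum over the ±3 index box)           |
| near-surface | −1 + 2J·Σ exp(−r²)  (sum over the ±1 index box)            |
| core         | −1 + 10J                                                   |
| outside      | 0                                                          |

and the ligand field is 1−J on the surface, 1 − 2J·Σ exp(−r²) on the
near-surface, 1−10J in the core, 0 outside.  Both sums run over
near-surface and core points only.  The ±3 box on the surface term is what
gives the score its long range: atoms up to seven layers (≈8.4 Å) away
still contribute, with an exponential weight peaked at the adjacent-layer
distance r = 1.  Distances are measured in index units because the boxes
are defined in index space and the weight peaks at the lattice neighbor
distance only there.

Two conventions in these sums are not forced by the formulas and are
exposed as switches:

* **Self-inclusion** (`include_self`, default on): the ±1 sums include the
  center point's own r = 0 term when it is itself near-surface, because the
  only membership condition — the summed point must be near-surface or core
  — is satisfied by the point itself.  With the default, a near-surface
  point's imaginary magnitude is always ≥ 2.
* The ±3 surface sum uses the full cubic box as defined (points at
  Euclidean r > 3 in the corners are kept, with negligible weight
  exp(−4) ≈ 0.018 or less).

## Translational search and score sign

For one orientation the correlation
E(o,p,q) = Re[Σ R(l,m,n)·L(l+o, m+p, n+q)] (indices modulo N) is evaluated
for all N³ shifts via the cross-correlation theorem,
E = Re[IDFT(conj(DFT(conj(R)))·DFT(L))]; the FFT path is validated against
the direct triple sum in the test suite, not assumed.  A map index
(o,p,q) pairs receptor cell l with ligand reference cell l+o and therefore
realizes the ligand *displaced by −(o,p,q)* lattice steps; predictions
record that displacement, so the physical translation is
`unwrap(shift)·spacing` with `unwrap(s) = s if s ≤ N/2 else s − N`.

Expanding Re[R·L] per overlapping cell pair shows the raw correlation
behaves as an interaction **energy**: the receptor surface real part is a
negative (favorable) attraction field for the partner's interior, while
the imaginary products of opposite sign contribute large positive
penalties for atom-on-atom overlap (+99 for core on core).  Consequently:

* **`repulsive_core`** (default) ranks by the *negated* correlation, i.e.
  minimizes the printed energy.  Clash of the occupied layers then scores
  strongly negative and ligand interior resting on the receptor surface
  layer scores positive, which is the physically meaningful ranking.
* **`as_printed`** ranks by the raw correlation descending.  Because
  interpenetration is then rewarded, its global optimum buries the ligand
  inside the receptor; the mode is kept so the raw arithmetic can be
  audited.

No single conjugation of one grid makes every pairing simultaneously
attractive-at-contact and repulsive-at-clash (negating only the ligand
imaginary parts, for instance, makes every overlap contribution ≤ 0, so
complete separation always wins).  Rather than hard-coding the choice,
`sanity_audit` redocks a deterministic knob/socket fixture and checks the
global best pose for interface contact (receptor surface cells overlapped
by ligand near-surface/core) without core–core interpenetration (≤ 2% of
ligand core cells).  On this audit `repulsive_core` passes (contact 20,
clash 0/158) and `as_printed` fails (clash 146/165); `sign_mode=auto`
applies the passing mode and logs it.

## Rotational sampling

For an angular interval Δ (default **15°**) the ligand-axis directions are
a deterministic Fibonacci-spiral covering of the sphere with
K = round(4π/Δ_rad²) points (one per Δ² of solid angle, poles included so
entry 0 is the identity orientation), each combined with
M = round(360/Δ) spin angles.  At 15° this gives K = 183, M = 24,
**4392 orientations**; at 30°, 46·12 = 552.  The covering involves no
randomness; its mean nearest-neighbor direction separation at 15° is
14.2°.  K·M is the only free-parameter-free formula of this family that
reproduces 4392 at 15°, but any other quasi-uniform generator would differ
pose-by-pose while sampling at the same density.  The ligand rotates about
its centroid; the receptor stays fixed.

## Grid size

The box edge must cover `receptor diameter + ligand diameter +
2·(2·max_vdw + 2·spacing)` (diameters measured about the centroids, so
they bound every ligand rotation), rounded up to a 2/3/5-smooth FFT size,
capped at N = 256 by default.  The margin guarantees that no atom sphere
or ±3 neighborhood touches the boundary and that every contact pose is a
wrap-unambiguous translation — which is why no wraparound filtering of
best translations is needed.  Both centroids are placed at the grid center
before gridding.

## Evaluation

Pose quality is the ligand RMSD: the predicted receptor is superposed onto
the native receptor by Kabsch least squares over backbone atoms (N, CA, C,
O) paired by chain/residue number/atom name (unmatched atoms dropped with
a logged count), the transform is applied to the predicted ligand, and the
RMSD is taken over paired ligand Cα atoms.  A pose with ligand RMSD
strictly below 10 Å is a hit; the success rate at K is the percentage of
cases with ≥ 1 hit in the top K, and mean hits at K is the average hit
count in the top K.  Both are non-decreasing in K by construction.
Category labels (enzyme–inhibitor, antibody–antigen, other) are
user-supplied metadata in the case list, never inferred.

## Synthetic fixtures

`lscdock.fixtures` generates deterministic pseudo-complexes so the full
pipeline is testable without downloads: the receptor is a jittered-lattice
carbon cloud (2.0 Å lattice, ±0.15 Å jitter) filling a ball with a
hemispherical socket carved at its +x pole; the ligand is a matching knob
nested in the socket.  The carve clearance (3.5 Å beyond the knob's actual
atom-cloud extent) is chosen so the bound interface satisfies, by
construction, a no-clash bound (minimum cross distance ≥ 0.8 of summed
radii) and a real-interface bound (≥ 10 pairs within 1.2 of summed radii);
the generator verifies both at build time.  Every atom is its own residue
with a single CA carbon, so the Cα/backbone selections of the evaluation
apply directly.

What the fixtures do *not* emulate: real protein packing density,
secondary structure, chemical heterogeneity, side-chain texture, and
bound/unbound conformational change.  The knob is deliberately
near-spherical, which makes redocking forgiving of orientation error
(almost any orientation seated in the socket is a sub-10 Å hit); passing
the redocking tests therefore demonstrates that the geometry, scoring,
FFT search and evaluation plumbing are consistent — not that the method
reaches any particular accuracy on real complexes.  Default redocking
problem size: 300 receptor atoms, 80 ligand atoms, N = 36 grid, 4392
orientations (≈ 20 s on one CPU); these sizes are the package's chosen
desk-scale study conditions.

## Numerical choices

* FFT correlation vs direct sum agrees to ~1e−9 relative on random grids;
  the test tolerance is 1e−6 relative.
* Best-translation ties break to the lexicographically smallest map index,
  then ranking ties to the lower rotation index — both for bit-for-bit
  reproducible outputs (prediction TSVs from identical inputs are
  byte-identical).
* The inside test is a closed ball (≤ radius).
* Degenerate inputs: single-atom partners dock (everything is surface or
  near-surface; under `repulsive_core` all overlap terms are then ≤ 0 and
  the optimum is a non-clashing placement at score 0); superposition
  requires ≥ 3 non-collinear atoms.

## Known limitations

* Scores are shape-only; ranking across dissimilar real complexes is
  expected to be weaker than for the geometric fixtures.
* One pose per orientation is retained (no clustering), so near-duplicate
  translations of distinct orientations can fill adjacent ranks.
* The rotational sample reproduces the documented sampling *density*, not
  any specific historical program's pose list.
* PDB input only (no mmCIF); no missing-atom modeling.
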