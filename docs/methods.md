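# Methods

`g4kit` annotates G-quadruplex (G4) architecture from atomic coordinates and
implements the accompanying solution-biophysics calculations (CD melting
fits, theoretical oligonucleotide masses).  This note records the models,
conventions and numerical choices behind each stage, what the bundled
synthetic-structure generator does and does not emulate, and the known
limits of the approach.

## Structure model and I/O

Coordinates are kept in Angstrom, right-handed Cartesian, exactly as
deposited; PDB and mmCIF parsing/writing is delegated to gemmi.  Alternate
locations are resolved deterministically (highest occupancy, ties toward
altloc `A`).  The sugar ring oxygen is accepted under both of its customary
names, `O4'` and `O1'`.  Deposited nucleic-acid models carry no hydrogens,
so every hydrogen-bond criterion in the package uses donor/acceptor heavy
atoms only.  Symmetry mates (e.g. the crystallographic two-fold that
completes a 5'-5' stacked dimer from a single-strand asymmetric unit) are
generated only from an explicitly supplied rotation + translation; no
space-group expansion is attempted.

## Tetrad detection

A G-tetrad is four guanines in a closed directed Hoogsteen cycle, each
residue donating N1→O6 and N2→N7 to its neighbor.  Detection:

1. build a directed graph over guanines with a candidate edge u→v when
   min(N1u–O6v, N2u–N7v) ≤ `dist_cutoff` + 1.0 Å (`dist_cutoff` default
   3.4 Å);
2. enumerate directed 4-cycles;
3. accept a cycle when the **mean of its eight Hoogsteen distances** is
   within `dist_cutoff` and the 44 base ring atoms fit one least-squares
   plane within 1.0 Å rms;
4. deduplicate by canonical rotation (cycle starts at the lowest
   (chain, residue number)).

The mean-distance rule, rather than a hard per-bond gate, is deliberate:
in moderate-resolution or noisy coordinates individual bonds straddle any
fixed threshold, while the eight-bond mean has √8-fold smaller variance.
Deposited-model Hoogsteen distances are typically 2.6–3.0 Å, so 3.4 Å is
permissive; false positives are suppressed by the cycle and planarity
requirements.  On ≤ 12 guanines the graph search is verified in the test
suite against exhaustive enumeration of all 4-subsets and cyclic orders.

Hydrogen-bond **directionality** (clockwise vs anticlockwise) depends on a
viewpoint the observable itself does not fix.  The convention here: viewed
from the tip of a caller-supplied reference normal (for assembled cores,
the 5'→3' axis), a right-handed circulation of the donor→acceptor cycle is
"anticlockwise".  Reversing the reference normal provably flips every
call, so both readings of a published pattern are reproducible.

## Core assembly, topology, grooves, loops, ions

Tetrads stack into a core when centroids are within 4.5 Å and plane
normals within 30° (sign-free).  Strand columns are built layer-by-layer
by minimum ring-centroid matching under a bijective optimal assignment
(`scipy.optimize.linear_sum_assignment`); ambiguous links (> 6 Å) are
flagged, not silently accepted.  The core axis runs 5'→3' from the tetrad
holding the 5'-most core guanine of the lowest-sorting chain.

* **Topology** — each column's 5'→3' progression is the projection of its
  sequence-ordered C1' displacement onto the axis: 4 columns one way =
  parallel, 2+2 = antiparallel, 3+1 = hybrid.  In multi-unit (dimeric)
  cores each monomer unit is classified from its own column segments and
  the core call is the unit consensus.
* **Grooves** — per adjacent column pair, the per-layer width is the P–P
  distance of layer-mate guanines; the mean over defined layers is
  classified narrow < 12 Å ≤ medium < 19 Å ≤ wide.  The thresholds are
  package defaults chosen to separate the well-known narrow (~9 Å),
  medium (~16 Å) and wide (~21 Å) groove regimes of antiparallel and
  parallel G4s; both thresholds are configurable and per-layer widths are
  always reported so alternative summaries can be derived.
* **Loops** — the residues between consecutive G-tracts of a chain.
  A loop is *propeller* when its anchor guanines attach at opposite faces
  of the chain's core span, *lateral* when same face and adjacent columns,
  *diagonal* when same face and diagonal columns; lateral loops record the
  groove they span.
* **Channel ions** — an ion is assigned to a layer interval when it lies
  within 3.6 Å of ≥ 4 guanine O6 atoms drawn from exactly two adjacent
  tetrads; it is an *interface* ion when those tetrads belong to different
  monomer units (different chains).

## Non-tetrad interactions

* **C·C⁺ pairs** — protonation is invisible in X-ray models, so the call
  is purely geometric: N3–N3 ≤ 3.5 Å plus at least one of the two
  symmetric N4–O2 contacts, base planes within 35°.  A short N3–N3
  contact between cytosines is taken to imply hemiprotonation.
* **Quadruple base pair** — two coplanar C·C⁺ pairs (four rings within
  1.0 Å rms of one plane) joined by at least one donor–acceptor bond on
  each junction of a perfect matching between the pairs' bases; a
  quadruple additionally records the tetrad it stacks against, if any.
* **Interface register (Form-1/1 vs Form-1/7)** — guanines of the two
  interface tetrads are matched by nearest lateral (axis-projected) ring
  centroids.  Residue positions are mapped to (repeat ordinal,
  intra-repeat index) with a 6-nucleotide repeat by default.  Because both
  G1 and G7 occupy intra-repeat index 1, and because a two-fold-related
  partner cannot match every guanine's repeat ordinal simultaneously (the
  mirror flips the cyclic column order, so G1-on-G1 forces G7-on-G19),
  the register is named from the partner of the first-repeat guanine:
  G1 over G1 → Form-1/1, G1 over a G7-type guanine → Form-1/7.
* **Base-on-tetrad stacking** — ring centroid within 4.5 Å of the tetrad
  plane, plane normals within 30°, and lateral projection inside the
  convex hull of the tetrad ring atoms grown by a 2 Å margin.  The margin
  is configurable; "stacks onto" has no universal definition.
* **Ion coordination** — all N/O atoms within 3.6 Å; the geometry label
  is a heuristic that reports "antiprismatic" for eight ligands splitting
  4+4 between two separated, near-parallel planes.
* **Water bridges** — a water hydrogen-bonded (≤ 3.4 Å) to polar atoms of
  two or more distinct residues, reported per partner pair.

## Torsions and sugar pucker

Backbone torsions α–ζ follow the standard atom definitions; χ is
O4'–C1'–N9–C4 (purines) / O4'–C1'–N1–C2 (pyrimidines); all angles are
degrees in (−180, 180] with the IUPAC sign convention (validated against
an independent two-plane oracle and biotite).  syn is χ ∈ (−90°, 90°],
right-closed by declared convention.  Sugar pseudorotation uses the
Altona–Sundaralingam relation

    tan P = ((ν4 + ν1) − (ν3 + ν0)) / (2 ν2 (sin 36° + sin 72°)),

with P shifted by 180° when ν2 < 0, amplitude ν2/cos P, and 36°-wide
classes starting at C3'-endo for P ∈ [0°, 36°).  Missing atoms degrade to
per-field undefined values with a completeness flag rather than
exceptions, because deposited loop residues are routinely disordered.

## Melting curves

CD melting signals are min–max normalized, (y − min)/(max − min), and Tm
is the inflection of a least-squares Boltzmann sigmoid
y(T) = bottom + (top − bottom)/(1 + exp((Tm − T)/s)), initialized at the
0.5-crossing (mid-span fallback), s₀ = span/10.  Baselines float by
default (they may be pinned at 0/1); floating baselines matter for the
two-component fit: when a biphasic curve's upper transition is truncated
by the temperature window, min–max normalization applies an affine map
that a pure unit-sigmoid mixture cannot absorb, while the affine-wrapped
mixture recovers the component Tm's exactly on noiseless input.  The
double fit uses multi-start initialization (0.25/0.75 crossings and
mid-span ± span/4), reports tm1 < tm2 with component fraction f ∈ [0, 1],
and falls back to the single-sigmoid fit when the components collapse
within 1 °C.  The automatic model choice compares residuals with an
extra-parameter F statistic at p < 0.01.  Loss is unweighted least
squares.  A fit-range option restricts the fitted window.  Raw CD traces
for the motivating system are not publicly deposited, so fitting accuracy
is established by parameter-recovery simulation (Tm 85 °C, slope 3 °C,
noise σ = 0.02 over 200 seeds: median |T̂m − Tm| < 0.3 °C; the biphasic
46.38/89.07 °C pair at σ = 0 to 0.1 °C), not against printed values.

## Oligonucleotide masses

Average-isotopic molecular weight per strand is the sum of internal
residue masses (dA 313.21, dC 289.18, dG 329.21, dT 304.20 Da) minus
61.96 Da — the standard vendor convention for synthesized 5'-OH linear
DNA — plus 79.98 Da when a 5'-phosphate is requested; oligomer mass is
`copies ×` the strand mass.  At the 0.1 kDa resolution used for
oligomer-state assignment against SEC-MALS, competing end-group
conventions agree.  d(GGGGCC)₄: 7 518.84 Da → 7.5 kDa per strand,
15.0 kDa for the dimer.

## The synthetic generator

`synthetic_data.build_g4` produces idealized quadruplexes engineered for
detector-relevant geometry, not stereochemical realism:

* guanine/cytosine base heavy atoms come from the ideal CCD templates
  bundled with biotite, planarized;
* the in-plane placement of the guanine under exact four-fold symmetry is
  solved by least squares so the cyclic N1–O6 and N2–N7 contacts equal
  the requested gap (default 2.9 Å, hit to ± 0.05 Å), with weak
  regularizers holding the O6 cage (~2.4 Å) and base centroid (~4.6 Å)
  radii at experimentally typical values;
* layers stack at 3.3 Å rise / 30° twist; K⁺ ions sit at layer-interval
  midpoints on the axis (O6 distances ≈ 2.8 Å);
* sugars are reduced to a C1' anchor on the exterior bisector of
  C8–N9–C4 (a well-conditioned χ axis) plus an O4' placed to realize the
  requested glycosidic angle: all-anti (−120°) for parallel, a
  syn (+60°)/anti checkerboard for antiparallel, a syn column for hybrid;
* phosphates sit at groove-defining radii: a common 11.3 Å radius for
  four 16 Å medium grooves (parallel preset), or a closed-form
  radius/azimuth-offset pair producing alternating 21.6/8.7 Å wide/narrow
  grooves (antiparallel preset);
* loops are schematic cytosine arcs with correct attachment faces and
  radially oriented base planes (so they never stack on tetrads);
  dimer builds apply a two-fold perpendicular to the axis, stack the
  mates 5'-to-5' with one interface cation, and rotate the partner by one
  column step for register 1 (Form-1/7);
* `noise_sigma` is the RMS positional displacement per atom in Å
  (isotropic Gaussian, per-component σ/√3), the scale on which overall
  coordinate error of a crystallographic model is usually quoted, applied
  last under a single seeded RNG stream.

What the generator does **not** emulate: real sugar rings and full
backbones (only `backbone_from_torsions` builds torsion-exact
P–O5'–C5'–C4'–C3'–O3' chains, for validating the torsion extractor),
solvent, crystal-packing contacts, sequence-dependent loop conformations,
or correlated/anisotropic coordinate error.  Passing round-trip tests on
builder output therefore demonstrates the correctness and noise behavior
of the detectors, not their performance on every pathology of real
crystallographic data; the same detectors run unchanged on deposited
PDB/mmCIF files via `g4kit analyze`.

### Noise limits of torsion-level labels

Under the RMS-displacement noise model, a torsion read from four atoms on
~1.4 Å bonds acquires a standard deviation of roughly 7°·(σ/0.1 Å).  At
σ = 0.3 Å this is ~20° against the 30° margin between canonical anti
(−120°) and the −90° syn/anti boundary, so per-residue syn/anti labels
are no longer identifiable — measured over 250 randomized builds, ~60% of
structures show at least one flipped label at σ = 0.3, while topology,
tetrad/ion counts, groove classes and interface registers remain 100%
correct there.  The test suite therefore asserts glycosidic patterns at
σ = 0.1 (where 250/250 builds recover every label) and the geometric
annotations at σ up to 0.3.  This is an information limit of the torsion
observable, not a detector artifact.

## Problem sizes used in the automated checks

Round-trip recovery runs 20 seeds per architecture (three monomer
topologies and both dimer registers) with noise alternating between 0.15
and 0.3 Å RMS, plus 20 seeds per topology at 0.1 Å for glycosidic
patterns; melting recovery uses 200 replicate curves; each geometry
primitive is checked on 1 000 random instances against an independently
coded oracle (two-plane dihedral, covariance eigenvector, quaternion
superposition).

## Known limitations

* Tetrad detection assumes standard guanine atom nomenclature; modified
  guanines (e.g. 8-bromo-dG) participate only if their carrier residue is
  named as a guanine variant the classifier recognizes.
* Groove thresholds are heuristics for canonical G4 regimes; unusual
  architectures (left-handed Z-G4, bulged cores) receive whatever the
  generic classifiers produce.
* The C·C⁺ call cannot distinguish hemiprotonated pairs from neutral
  C·C pairs with similar geometry.
* Topology classification requires ≥ 2 core guanines per column per unit
  and fails (with a diagnostic) on columns perpendicular to the axis.
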