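# Methods

This note records the model, the numerical choices, and what the synthetic
test geometry does and does not establish.

## The screening model

The screen treats glycan–protein binding as a rigid steric filter anchored on
a known bound pose of a minimal determinant:

* **Conformational model.** A glycan's conformers are the Cartesian product
  of discrete stable rotamers of its flexible glycosidic torsions: the
  exocyclic ω angle (O-glycosidic–C6–C5–O5) of every 1-6 and 2-6 linkage
  takes {+60°, −60°, 180°}; the φ angle of every 2-3 sialic-type linkage
  (C1–C2–O–C3) takes {−60°, 180°}.  All other torsions are fixed at
  linkage-class defaults.  There is no continuous sampling and no
  post-graft relaxation: the specificity logic depends on branches *not*
  being allowed to wiggle out of a clash beyond the discrete set, so this is
  a modeling commitment, not a shortcut.
* **Clash metric.** For each conformer, every branch heavy atom is compared
  with every protein heavy atom; an overlapping pair (d < r₁+r₂, Bondi
  radii) contributes the buried *surface* area of both spherical caps,
  A = 2πr₁h₁ + 2πr₂h₂, hᵢ = rᵢ − (d² + rᵢ² − rⱼ²)/(2d).  Separated spheres
  contribute 0; an engulfed sphere contributes its full 4πr²min.  Surface
  area (not lens volume, not one cap) is the only reading under which
  normalizing by a carbon sphere's surface, 4π(1.70 Å)² = 36.3 Å², is
  dimensionally meaningful.  A conformer's clash score is the normalized
  sum; a glycan's score is the **minimum over its rotamers** (binding needs
  only one viable conformer, and the screen reports one score per glycan);
  binder ⇔ score **strictly** < 1.0 (a score of exactly 1.0 — one fully
  occluded carbon — is a non-binder).
* **What is excluded from the sum.** Pairs involving the retained bound
  determinant are not scored: the validated pose necessarily touches the
  protein, and scoring it would contaminate the branch signal.
  Branch-versus-determinant overlap is computed separately as a diagnostic
  (`intra_flag`), ignoring pairs closer than 2.5 Å (the glycosidic bond and
  its geminal neighbours are covalent geometry, not strain).
* **Grafting.** The library glycan is built in full, its determinant ring
  heavy atoms (O5, C1–C5 per residue) are superposed onto the bound
  determinant by Kabsch/SVD (proper rotation enforced), and all non-core
  atoms — extra residues, sulfates, the aglycon — are carried by that
  transform.  Ring atoms only: exocyclic atoms would bias the fit across
  rotamers.  The bound coordinates always win; protein and determinant are
  bitwise unchanged.  An alignment RMSD gate (default 0.8 Å) rejects
  correspondence failures.  Glycans whose determinant occurs internally
  (linked onward through its anomeric carbon) keep their reducing-end chain
  as one more branch, grafted at the anomeric position in place of the
  methyl aglycon.
* **Aglycon convention.** Screening uses methyl glycosides: a glycan with no
  stated aglycon receives an O-methyl at the anomeric oxygen, in the
  exo-anomeric orientation (CM–O1–C1–H1 = +60°; the anti orientation would
  park the methyl in the 1,3-diaxial pocket under the ring).  An undefined
  reducing-end anomer is preserved by the parser and substituted with α at
  screening time, matching array-catalog practice for this antigen.

## 3D building

Residues are instantiated from idealized templates: a chair-geometry
pyranose ring (bond lengths ≈1.53 Å, alternating ±0.25 Å pucker) with every
exocyclic group placed axially or equatorially per the residue's
stereochemistry, hydrogens included.  D-aldohexoses are built 4C1; L-fucose
is the mirrored 6-deoxy-galactose template (1C4); Neu5Ac/Neu5Gc/KDN carry
the anomeric center at C2 with an equatorial carboxylate (α), a glycerol
tail, and N-acetyl (or hydroxyl for KDN) at C5.  Glycosidic bonds use
C(anomeric)–O = 1.43 Å and 117° at the bridging oxygen.  Default torsions
per linkage class are configurable (`LinkageGeometry`); the shipped values
are exo-anomeric-consistent (φ ≈ ±60° by anomer, ψ ≈ 0° against the aligned
proton, ψ = 180° heavy-atom for 6-linkages), with the β1-3 class pinned to
the TF solution conformation φ = 61.5°, ψ = 6.2°.  No force-field
minimization is applied — template assembly with literature-standard
geometry replaces it, and the defaults are overridable where users have
force-field-derived values.  Builds are deterministic: identical tree and
assignment give bitwise-identical coordinates.  A heavy-atom distance
< 1.0 Å inside a built conformer warns (such rotamers exist by construction
for crowded glycans and are typically the ones the min-rule discards) but
does not abort.

## STD-NMR prediction

The isolated spin-pair approximation: predicted saturation transfer to
ligand proton *j* is proportional to Σᵢ Rᵢⱼ⁻⁶ over protein protons *i*.  No
distance cutoff is applied by default (R⁻⁶ makes the sum converge quickly; a
cutoff is available).  Methyl groups are pooled by an explicit atom-name
grouping — three protons, one summed entry — rather than inferred.  Profiles
are normalized to the largest entry = 100; comparison with an experimental
profile uses Spearman rank correlation plus mean absolute deviation of
normalized intensities over shared labels (≥3 required), and pose ranking
sorts by correlation, ties by deviation, preserving input order.  Hydrogens
are mandatory here, while clash scoring is heavy-atom-only: each computation
uses what its data source can support (crystal structures lack protons; NMR
observes them).

## Synthetic test geometry

Real inputs (a crystal Fab, a docked pose, a glycan database) are not
required by any test.  Two pocket generators stand in for the combining
site:

* **Spherical shell** (`make_toy_pocket`): carbon pseudo-atoms on a
  Fibonacci-lattice sphere (radius > determinant extent + 2 Å, spacing
  ≈1.8 Å, seeded jitter) with a cone cleared around an opening direction.
  Carbon-only walls keep expected scores closed-form.  Suitable for
  direction-level checks: a 6-branch escapes an opening aimed along the
  GalNAc O6 exit and crashes into the wall when the opening is rotated 180°.
* **Contoured canyon** (`make_contoured_pocket` / `make_specificity_pocket`):
  wall atoms placed along rays from the determinant centroid at the smallest
  distance that keeps them ≥ gap (3.8 Å) from every determinant heavy atom,
  so the wall hugs the ligand like a real combining-site surface, with two
  carved escape channels: a 30° half-angle cone around the α-anomeric exit
  (the methyl aglycon) and a 62° cone around the GalNAc O6 exit (wide enough
  for the ω-rotamer fan of 6-branches).  These three numbers were chosen
  geometrically so that the tolerated exits clear the wall and everything
  else meets it; with them the pocket reproduces the full qualitative
  array-specificity pattern — TF itself and all 6-position extensions score
  < 1.0, every 2-/3-position Gal extension, the 3-O-sulfate, and the
  β-aglycon model score > 1.0.

What passing these tests shows: the pipeline's geometry, bookkeeping and
classification logic are correct on a pocket whose answer is known by
construction.  What it does not show: agreement with any particular
antibody's measured clash scores, which depend on a real crystal structure,
a docked determinant pose, and force-field-minimized glycans, none of which
are modeled here.  The synthetic pockets have no electrostatics, no
flexibility, and no solvent; their walls are carbon-only.

The synthetic glycan library generator plants a motif in an exact fraction
of sequences (motif extended by random residues at free positions) and
verifies decoys motif-free before accepting them; lists are seeded and
reproducible bit-for-bit.  The STD scenario rotates the ligand inside a
hydrogenated pocket to create distinguishable poses and derives the
"experimental" table from the reference pose with 3% multiplicative noise,
making the ground-truth ranking known.

## Numerical choices and degenerate inputs

* Monte-Carlo validation of the overlap formula measures deviation relative
  to the smaller sphere's total surface (4πr²min).  A relative-to-overlap
  criterion is ill-posed near tangency, where the true area → 0 while a
  finite-sample estimate has fixed absolute noise; the chosen normalization
  gives a 10⁶-point estimator a standard error ≤ 0.05% for every geometry.
* Kabsch superposition flags rank-deficient (collinear) point sets rather
  than returning an arbitrary rotation; reflections are prevented by the
  determinant correction.
* Dihedrals follow the IUPAC sign convention, range (−180°, 180°], with
  collinear triples rejected; torsion edits rotate exactly the subtree on
  the distal side of the bond and refuse ring bonds.
* PDB I/O (via gemmi) resolves alternate locations by highest occupancy,
  preserves residue numbering verbatim, retains waters (removable by
  selection), and writes multi-MODEL files for rotamer series.  Coordinates
  are Å throughout; PDB precision (10⁻³ Å) bounds round-trip fidelity.
* Screening is fault-isolating: a sequence that fails to parse or graft
  yields a row with an error note; motif-free sequences are skipped with a
  reason; the run continues.
* Problem sizes in the shipped tests and the acceptance script (a ~150-atom
  wall, 23-sequence catalog, 10³-sequence library, 200 Monte-Carlo triples
  at 10⁶ points) were chosen so the whole suite completes in about a minute
  while every statistical check retains comfortable margins.

## Known limitations

* Idealized templates are not energy-minimized structures; ring substituent
  orientations are correct axially/equatorially but bond-angle strain and
  exocyclic fine structure are not modeled.  Grafted models are starting
  points for refinement, not final structures.
* The rotamer sets cover ω and sialyl-φ flexibility only; other linkages are
  rigid at class defaults.  Glycans whose binding depends on minor-rotamer
  φ/ψ excursions can be misclassified near the threshold.
* Binder/non-binder is a steric verdict: no energetics, no affinity
  ranking, no induced fit, and biological plausibility of a sequence is out
  of scope.
* The IUPAC-condensed parser covers the dialect used by glycan array
  catalogs (branches, 2-linkage sialic acids, sulfate prefixes, ambiguous
  2-3/6 expansion as an explicit operation); it does not read GlycoCT or
  WURCS.
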