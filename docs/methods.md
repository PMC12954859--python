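# Methods

## Scope and model

`restraintforge` implements the generation and validation of geometry
restraints for small-molecule components (ligands and nonstandard amino
acids) of macromolecular models. A *restraint* is a prior used during
refinement: a target ("ideal") value plus an estimated standard
deviation (e.s.d.) for a bond length, valence angle, torsion angle,
chiral volume or planar group. The package turns a component
description (atoms, bonds, coordinates) into a complete restraint
dictionary, scores geometries against a reference table of
experimentally derived ideal values, and verifies dictionaries by a
minimization round-trip.

The toolkit deliberately treats optimized geometries as *data*: the
expensive geometry providers (quantum-chemical optimizers) live outside
the package, and the pipeline consumes an ordered list of candidate
coordinate sets per component, accepting the first that validates.
Metals, metal clusters and single-atom components are excluded at the
filtering stage because their restraints depend on coordination
environment and electronic state, which this formalism cannot express.

## Filtering

A component is rejected with the first matching reason in a fixed
order: obsolete entry, single atom, element outside the allowed set,
standard residue, curated skip-list. The allowed-element set is
`{H, D, B, C, N, O, F, Si, P, S, Cl, Se, Br, I}`: everything a typical
organic ligand contains, and nothing whose restraints would require
metal-coordination or noble-gas handling. The standard-residue set and
the skip-list are policy inputs, not computations — the criteria by
which an entry was previously hand-validated are not reconstructible
from the entry itself.

## Graph perception

The molecular graph mirrors the bond list. Rings are the smallest set
of smallest rings from a minimum cycle basis, with ties broken by
sorted atom names for determinism. Aromaticity trusts explicit
aromatic bond flags and additionally marks six-membered rings with
alternating single/double orders (Kekulé benzenoids); no electron
counting is attempted, which keeps perception simple, deterministic and
testable at the cost of missing exotic aromatic systems.

Hybridization is rule-based, per heavy atom:

- degree >= 4 → sp3 (hypervalent centres such as phosphate P and
  sulfone S stay tetrahedral regardless of formally double bonds);
- a triple bond, or two double bonds on a two-coordinate atom
  (cumulene) → sp;
- aromatic, or at least one double bond → sp2;
- otherwise sp3. Hydrogens are labelled `terminal`.

The degree guard matters: without it a phosphate phosphorus would be
typed sp2 and acquire a planarity restraint over a tetrahedral centre,
which is chemically wrong and internally inconsistent.

## Protonation variants

Two protonation states are distinguished: *in notitia* — the state as
recorded in the component dictionary, typically with acids protonated —
and *in situ* — the state expected inside a protein at physiological
pH, with acids deprotonated. The acidic-proton pattern is the minimal
chemically standard set: H on an oxygen single-bonded to a carbon
carrying C=O (carboxylic), to a sulfur carrying at least two S=O
(sulfonic), or to a phosphorus carrying at least one P=O (phosphate,
phosphonate). Removing a proton decrements the bearing oxygen's formal
charge. Basic sites (e.g. histidine-like imidazoles) are not
enumerated; their microstates are curated work outside this package's
scope. Components without acidic protons yield a single variant.

Polymerizable amino acids additionally have their terminus atoms (H2,
OXT, HXT) removed before dictionary emission so the restraints suit the
in-chain form; trimming is idempotent and charge-neutral.

## Restraint generation

Ideal values are measured directly from the supplied geometry: one bond
term per bond, one angle term per pair of distinct neighbours around
each centre (hydrogen-containing triples included — riding-hydrogen
schemes need them), chiral volumes (signed triple products) for sp3
centres with at least three heavy neighbours, and planar groups.

Torsion periodicity comes from the hybridization of the central bond's
end atoms: sp3–sp3 threefold, sp2–sp2 twofold with the ideal snapped to
the nearer of 0°/180°, sp2–sp3 sixfold; non-aromatic ring bonds get a
onefold restraint at the measured value, aromatic ring-internal bonds
get none (the plane restraint covers them), and bonds with an sp end
get none (a dihedral about a linear axis is undefined). One
representative torsion is emitted per eligible central bond, with
reference atoms chosen heaviest-element-first then lexicographically.
The format also carries discrete-ideal torsions (period 0 with a list
of alternative values) for bonds whose minima are not evenly spaced;
these are read and written but never generated automatically, because
deriving them requires curated conformer sets.

Hydrogen completeness is enforced as a dictionary invariant: every
hydrogen must appear in at least one bond and one angle restraint, and
in a positioning torsion whenever a non-degenerate four-atom path
exists — additional torsions are appended as needed, including across
aromatic ring bonds. Violations are a generation error, not a warning.

E.s.d. policy: reference spreads are floored (`max(sd, floor)`, floors
0.005 Å for bonds and 0.75° for angles) and then doubled
(`esd = 2 × floored sd`), since raw knowledge-base spreads are too
tight for refinement at typical macromolecular resolutions. The floors
are applied before the multiplier because they repair deficient spreads
(a single-observation type can have sd = 0), whereas the doubling is a
refinement-use policy. Terms without a reference entry fall back to
configurable defaults (bond 0.02 Å, angle 1.5°, torsion 30°/20°/10° for
periods 3/2/1, plane 0.02 Å), chosen at conventional restraint-library
magnitudes and exposed in `EsdPolicy`.

Dictionaries serialize to a monomer-library-style CIF
(`_chem_comp_bond`, `_chem_comp_angle`, `_chem_comp_tor`,
`_chem_comp_chir`, `_chem_comp_plane_atom`); discrete torsions are
written as one row per alternative value sharing a torsion id. Reading
is tolerant of column reordering and inverts writing exactly.

## Validation

Each measured bond and angle is assigned a chemical-type key — per-atom
tokens `element.hybridization[.ar|.ring]`, sorted ends for bonds,
sorted ends around a fixed centre for angles — and looked up in a
reference table of `(ideal, sd, n_obs)` rows. The key granularity is a
deliberate, configurable stand-in for knowledge-base fragment typing:
fine enough to separate e.g. C–O single from C=O double environments,
coarse enough to be computable from the graph alone.

The score per term is `Z = |observed − ideal| / sd`, and the geometry's
classification follows the maximum |Z| over matched terms with strict
thresholds: `< 2` **awesome**, `< 4` **superior**, `< 6`
**satisfactory**, else **fail** (a max|Z| of exactly 6.0 fails).
Root-mean-square Z is reported separately for bonds and angles.

Scoring is two-pass. Pass 1 uses raw reference spreads; terms with
sd = 0 cannot be scored and are held back. If pass 1 passes with no
zero-sd terms it decides. Otherwise pass 2 rescoring with the floors
applied decides, and a geometry that only passes this way is downgraded
to **satisfactory (reasonable std)** regardless of its Z — passing on
raw spreads never earns that flag. Terms with no reference entry at
all are counted as unmatched and excluded from the verdict; surfacing
the count keeps the verdict honest without failing components that
merely contain rare chemistry.

For polymerizable amino acids only side-chain terms are scored (the
backbone ideal values are maintained by dedicated libraries); terms
whose atoms all belong to the backbone name set
`{N, CA, C, O, OXT, H, H2, HA, HXT}` are excluded and the verdict is
tagged **(side chain)**.

## Minimization round-trip

The self-consistency check minimizes a geometry under its own
dictionary: restraints built from an ideal geometry should maintain
that geometry, so the Kabsch-superposed RMSD between start and final
coordinates should be ~0, and a deliberately corrupted ideal should
pull the minimizer away (detected at RMSD > 0.05 Å).

The energy model is the sum of squared e.s.d.-scaled residuals per
term. Torsion residuals are wrap-aware and taken to the nearest
symmetry copy (`k·360/period`) or nearest discrete alternative.
Chirality restraints store only a sign, so the term is a one-sided
hinge: a penalty applies when `sign × volume` drops below a 1.0 Å³
margin, which is zero at any reasonable tetrahedral geometry of the
correct hand and strongly positive for the mirror image. Planarity
uses the best-fit plane (SVD of the centred coordinates) recomputed at
every evaluation; its gradient is taken with the plane held fixed,
which is *exact* by the envelope theorem because the plane parameters
minimize the same sum of squares. The nonbonded term is purely
repulsive: a quadratic one-sided penalty `(cutoff − d)²` for
non-bonded pairs (graph distance ≥ 4) closer than
`0.8 × (r_vdW,i + r_vdW,j)`; the quadratic form keeps gradients
smooth.

All gradients are analytic (verified against central finite differences
at step 1e−5 to relative 1e−4 in the suite; in practice agreement is
~1e−10). Descent is L-BFGS-B with gradient tolerance 1e−4 per Å and a
2000-iteration cap; runs are deterministic for identical inputs.
Angles are degrees externally and radians internally. Kabsch
superposition uses the SVD covariance construction with the determinant
sign corrected so that no reflection is ever applied.

## Pipeline

Per component: filter → enumerate protonation variants → for the
in-situ variant, validate the candidate geometries in order and accept
the first non-failing one → build its dictionary (side-chain scoring
and terminus trimming for amino acids) → round-trip check. The
in-notitia variant is processed only after the in-situ variant passes
— no effort is spent on a protonated form whose parent geometry already
failed. If only one variant's geometry is supplied, the other variant
reuses it with the acidic protons stripped; this is logged as
approximate, since a real deployment would optimize each protonation
state separately. Outcomes aggregate into a classification ×
(method, variant) cross-tabulation whose cells always sum to the number
of processed variant records.

## Synthetic fixtures

The fixtures module builds six components with idealized internal
coordinates (C–C 1.53 Å, aromatic C–C 1.39 Å, C–H 1.09 Å, tetrahedral
109.47°, trigonal 120° — conventional textbook values, hard-coded and
documented, not fitted): n-alkanes (staggered, all-trans), benzene, an
acetic-acid/acetate pair, an alanine-like amino acid with terminus
atoms, and a methyl-phosphate ester with two acidic protons. The
phosphate's P centre is exactly tetrahedral and its P–O single bonds
share one length so that every chemical-type class carries a single
geometric value — a property real molecules lack but that makes a
mean-based reference table exactly consistent with the dictionary.

`make_reference_table` derives a table *from* a dictionary: one entry
per type key, ideal = mean of that key's ideals plus an optional bias
(targetable at a single key), a stated spread, and synthetic
observation counts. Bias `b` against spread `s` constructs a maximum
|Z| of exactly `b/s`, making every classification band reachable on
demand; a zero spread exercises the floor path.

What the fixtures do **not** emulate: conformational strain, crystal
packing, intramolecular hydrogen bonding, non-Gaussian or bimodal
reference distributions, and the fragment-typing granularity of a real
knowledge base. Passing tests therefore demonstrate the correctness of
the machinery (measurement, scoring, classification, minimization), not
the chemical accuracy of any particular geometry provider.

Perturbations add independent Gaussian noise per Cartesian component
with an explicit seed; there is no global random state anywhere in the
package.

## Problem sizes and numerical choices

The shipped fixtures span 5–14 atoms; suites and the acceptance script
run in seconds on one core, which is ample for property-style checks
whose truth does not depend on molecule size. Degenerate inputs are
errors, not silent results: overlapping atoms (< 0.1 Å), missing
coordinates, disconnected hydrogens, non-finite starting energies and
sub-3-point or collinear superpositions all raise. Chiral volumes
within ±0.1 Å³ of zero are treated as indeterminate (`both`). Torsion
comparisons are performed modulo 360° with wrap-aware distances, and
values are stored in (−180°, 180°].

## Known limitations

- Aromaticity perception misses non-Kekulé and heteroaromatic rings
  unless bonds are explicitly flagged aromatic.
- Discrete-ideal torsion lists are format-supported but never
  generated.
- The chirality energy term restrains handedness, not volume magnitude.
- Reference-table typing is graph-local; it cannot distinguish
  environments that differ only beyond the first shell.
- No link records between residues, no conformation-dependent ideals,
  no force-field export.
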