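# restraintforge

Geometry-restraint generation and validation for the small-molecule
components of macromolecular models.

Refinement of a protein–ligand structure needs *a priori* chemical
information for every component: ideal values and uncertainties
(e.s.d.) for bonds, angles, torsions, chiral volumes and planar groups,
collected per component in a restraint dictionary (CIF). Standard
residues ship with curated libraries, but most ligands do not, and
generating trustworthy restraints for them is a recurring bottleneck
for crystallographers and for anyone maintaining a restraint library.

`restraintforge` provides the desk-scale machinery around that problem:

- **`component_io`** — read/write CCD-style component CIFs and MDL
  molblocks; filter components by the standard rules (obsolete entries,
  single atoms, metals/noble gases, standard residues, curated
  skip-lists).
- **`chemgraph`** — graph perception (rings, aromaticity, rule-based
  hybridization), protonation variants (*in situ* deprotonated acids vs
  the *in notitia* recorded form), polymer-terminus trimming
  (H2/OXT/HXT).
- **`restraint_gen`** — measure internal coordinates from a geometry
  and emit a complete dictionary: torsion periodicity from
  hybridization (sp3–sp3 → 3, sp2–sp2 → 2, sp2–sp3 → 6), planes over
  aromatic rings and sp2 centres, chiral-volume signs, guaranteed
  hydrogen-restraint completeness, and the e.s.d. policy
  `esd = 2 × max(sd, floor)` with floors 0.005 Å / 0.75°.
- **`validation`** — Z-scores `|observed − ideal| / sd` against a
  reference table of experimentally derived values; classification by
  maximum |Z|: < 2 *awesome*, < 4 *superior*, < 6 *satisfactory*, else
  *fail*, with the *reasonable std* flag for geometries that pass only
  under floored spreads and *(side chain)* scoring for amino acids.
- **`geomin`** — restraint-driven minimization (harmonic residuals plus
  a purely repulsive nonbonded term, analytic gradients, L-BFGS-B) and
  Kabsch superposition RMSD, used to verify that a dictionary
  reproduces its own ideal geometry.
- **`pipeline`** — the per-component orchestration: filter → variants →
  candidate geometries in method order (first pass accepted) →
  dictionary → round-trip, with *in notitia* gated behind a passing
  *in situ*; plus cross-tabulated summaries.
- **`fixtures`** — synthetic components (alkanes, benzene,
  acetic-acid/acetate, an alanine-like amino acid, a methyl phosphate)
  and reference tables constructed to be exactly consistent with a
  dictionary or biased by a chosen number of standard deviations.

## Worked example

```python
from restraintforge import (
    build_dictionary, classify, measure_geometry, perceive,
    roundtrip_check, validate_geometry, zscore,
)
from restraintforge import fixtures as fx

comp = fx.make_component(fx.FixtureSpec("acetic_acid"))
graph = perceive(comp)
measured = measure_geometry(comp, graph)
dictionary = build_dictionary(comp, measured, graph=graph)

table = fx.make_reference_table(dictionary, graph, sd_bond=0.009, sd_angle=1.0)
print(validate_geometry(measured, graph, table).summary_text())

print("Z(1.681 vs 1.623+-0.009) =", round(zscore(1.681, 1.623, 0.009), 4))
print("classification:", classify(zscore(1.681, 1.623, 0.009))[0].value)

rt = roundtrip_check(dictionary, comp.coords,
                     elements={a.name: a.element for a in comp.atoms})
print("round-trip RMSD: %.5f A (converged=%s)" % (rt.rmsd_to_start, rt.converged))
```

prints

```
ACY [in_situ]: awesome  max|Z|=0.00 rmsZ(bonds)=0.00 rmsZ(angles)=0.00 unmatched=0
Z(1.681 vs 1.623+-0.009) = 6.4444
classification: fail
round-trip RMSD: 0.00000 A (converged=True)
```

The acetic-acid geometry scores *awesome* against a reference table
built from its own ideals (every Z is 0). A phosphoester P–O bond
observed at 1.681 Å against a tight reference of 1.623 ± 0.009 Å gives
Z ≈ 6.44 — just past the satisfactory cutoff of 6, so that geometry
fails validation on a single bond. The round-trip confirms the
generated dictionary is self-consistent: minimizing the source geometry
under it moves the atoms by 0 Å.

The same operations are available from the shell:

```sh
forge fixtures --kind acetic_acid -o work/
forge generate work/ACY.cif --table work/ACY_reference.tsv -o ACY_restraints.cif
forge validate work/ACY.cif --table work/ACY_reference.tsv
forge minimize work/ACY.cif --restraints ACY_restraints.cif
forge pipeline work/ --table work/ACY_reference.tsv --out out/
forge config --show
```

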