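"""Synthetic components, perturbations and self-consistent reference tables.

Everything downstream (graph perception, restraint generation, Z-score
validation, minimization round-trips) is exercised on the small
components built here, so no external structure downloads are needed.
Geometries are constructed from idealized internal coordinates using
conventional textbook values (C-C 1.53 A, aromatic C-C 1.39 A, C-H
1.09 A, tetrahedral angle 109.47 deg, trigonal 120 deg); these literals
are modelling conventions of this module, not measured claims.

Reference tables are derived *from* a dictionary so they are exactly
consistent with it (bias 0) or deliberately offset (bias b induces a
maximum |Z| of b/sd on the targeted keys), which makes classification
outcomes constructible in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .component_io import Atom, Bond, BondOrder, Component, ComponentClass
from .chemgraph import MolecularGraph
from .restraint_gen import RestraintDictionary
from .validation import ReferenceEntry, ReferenceTable

__all__ = [
    "FixtureSpec",
    "make_component",
    "perturb",
    "make_reference_table",
    "FIXTURE_KINDS",
]

FIXTURE_KINDS = (
    "alkane_chain",
    "benzene",
    "acetic_acid",
    "acetate",
    "alanine_like",
    "phosphate_like",
)

TET = 109.47122063  # tetrahedral angle, degrees
CC = 1.53  # sp3 C-C, Angstrom
CH = 1.09
CC_AR = 1.39
CH_AR = 1.08


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    n: int = 1  # chain length for alkane_chain
    seed: int = 0
    noise_sigma: float = 0.0  # Angstrom, applied via perturb()

    def __post_init__(self):
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.n < 1:
            raise ValueError("chain length must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           r: float, theta: float, phi: float) -> np.ndarray:
    """Place atom D at distance r from C, angle theta (deg) B-C-D and
    dihedral phi (deg) A-B-C-D (natural extension reference frame)."""
    theta_r, phi_r = math.radians(theta), math.radians(phi)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([
        -r * math.cos(theta_r),
        r * math.sin(theta_r) * math.cos(phi_r),
        r * math.sin(theta_r) * math.sin(phi_r),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


class _Builder:
    def __init__(self) -> None:
        self.atoms: list[Atom] = []
        self.bonds: list[Bond] = []
        self.coords: dict[str, np.ndarray] = {}

    def add(self, name: str, element: str, pos, charge: int = 0,
            bond_to: Optional[str] = None,
            order: BondOrder = BondOrder.SINGLE) -> None:
        self.atoms.append(Atom(name, element, charge))
        self.coords[name] = np.asarray(pos, float)
        if bond_to is not None:
            self.bonds.append(Bond(bond_to, name, order))

    def add_int(self, name: str, element: str, ref: tuple[str, str, str],
                r: float, theta: float, phi: float, charge: int = 0,
                order: BondOrder = BondOrder.SINGLE) -> None:
        """Add an atom by internal coordinates relative to three placed
        atoms (a, b, c); bonds the new atom to c."""
        a, b, c = ref
        pos = _place(self.coords[a], self.coords[b], self.coords[c], r, theta, phi)
        self.add(name, element, pos, charge, bond_to=c, order=order)

    def bond(self, a: str, b: str, order: BondOrder = BondOrder.SINGLE) -> None:
        self.bonds.append(Bond(a, b, order))

    def component(self, cid: str, name: str,
                  comp_class: ComponentClass = ComponentClass.NON_POLYMER,
                  smiles: Optional[str] = None) -> Component:
        return Component(
            id=cid,
            atoms=list(self.atoms),
            bonds=list(self.bonds),
            name=name,
            coords={k: tuple(v) for k, v in self.coords.items()},
            smiles=smiles,
            comp_class=comp_class,
            coord_source="ideal",
        )


def _chain(n: int) -> Component:
    """All-trans alkane C_nH_{2n+2} with staggered hydrogens."""
    b = _Builder()
    b.add("C1", "C", (0.0, 0.0, 0.0))
    b.add("C2", "C", (CC, 0.0, 0.0), bond_to="C1")
    # virtual pseudo-substituent of C1, anti to where C3 will go
    b.add("X", "C", (CC * math.cos(math.radians(TET)),
                     CC * math.sin(math.radians(TET)), 0.0))
    for i in range(3, n + 1):
        b.add_int(f"C{i}", "C",
                  (f"C{i-3}" if i > 3 else "X", f"C{i-2}", f"C{i-1}"),
                  CC, TET, 180.0)
    h = 0
    for i in range(1, n + 1):
        ci = f"C{i}"
        if i == 1:
            ref = ("C3" if n >= 3 else "X", "C2", "C1")
            phis = (60.0, 180.0, -60.0)
        elif i == n:
            # reference a hydrogen of C1 for ethane so the conformation
            # is staggered; longer chains reference the backbone
            ref = (f"C{n-2}" if n >= 3 else "H1", f"C{n-1}", ci)
            phis = (60.0, 180.0, -60.0)
        else:
            ref = (f"C{i-2}" if i >= 3 else "X", f"C{i-1}", ci)
            phis = (60.0, -60.0)
        for phi in phis:
            h += 1
            b.add_int(f"H{h}", "H", ref, CH, TET, phi)
    comp = b.component(f"ALK{n}", f"n-alkane chain of {n} carbons")
    # drop the virtual atom
    atoms = [a for a in comp.atoms if a.name != "X"]
    coords = {k: v for k, v in comp.coords.items() if k != "X"}
    return replace(comp, atoms=atoms, coords=coords)


def _methane() -> Component:
    b = _Builder()
    b.add("C1", "C", (0.0, 0.0, 0.0))
    b.add("H1", "H", (CH, 0.0, 0.0), bond_to="C1")
    s, c = math.sin(math.radians(TET)), math.cos(math.radians(TET))
    for k, name in enumerate(("H2", "H3", "H4")):
        ang = math.radians(60.0 + 120.0 * k)
        b.add(name, "H", (CH * c, CH * s * math.cos(ang), CH * s * math.sin(ang)),
              bond_to="C1")
    return b.component("MTH", "methane fixture")


def _benzene() -> Component:
    b = _Builder()
    r_c = CC_AR  # hexagon edge equals circumradius
    r_h = CC_AR + CH_AR
    for i in range(6):
        ang = math.radians(60.0 * i)
        b.add(f"C{i+1}", "C", (r_c * math.cos(ang), r_c * math.sin(ang), 0.0))
    for i in range(6):
        b.bond(f"C{i+1}", f"C{(i % 6) + 2 if i < 5 else 1}", BondOrder.AROMATIC)
    for i in range(6):
        ang = math.radians(60.0 * i)
        b.add(f"H{i+1}", "H", (r_h * math.cos(ang), r_h * math.sin(ang), 0.0),
              bond_to=f"C{i+1}")
    return b.component("BNZ", "benzene fixture", smiles="c1ccccc1")


def _acetic_acid(deprotonated: bool) -> Component:
    b = _Builder()
    b.add("C1", "C", (0.0, 0.0, 0.0))  # methyl carbon
    b.add("C2", "C", (1.50, 0.0, 0.0), bond_to="C1")  # carboxyl carbon
    b.add("X", "C", (-0.5, 1.0, 0.0))  # virtual reference
    b.add_int("O1", "O", ("X", "C1", "C2"), 1.23, 121.0, 0.0,
              order=BondOrder.DOUBLE)
    if deprotonated:
        b.add_int("O2", "O", ("X", "C1", "C2"), 1.26, 117.0, 180.0, charge=-1)
    else:
        b.add_int("O2", "O", ("X", "C1", "C2"), 1.34, 113.0, 180.0)
        b.add_int("HO2", "H", ("C1", "C2", "O2"), 0.97, 106.0, 180.0)
    for i, phi in ((1, 60.0), (2, 180.0), (3, -60.0)):
        b.add_int(f"H1{i}", "H", ("O1", "C2", "C1"), CH, TET, phi)
    comp = b.component("ACT" if deprotonated else "ACY",
                       "acetate fixture" if deprotonated else "acetic acid fixture",
                       smiles="CC(=O)[O-]" if deprotonated else "CC(=O)O")
    atoms = [a for a in comp.atoms if a.name != "X"]
    coords = {k: v for k, v in comp.coords.items() if k != "X"}
    return replace(comp, atoms=atoms, coords=coords)


def _alanine_like() -> Component:
    """Alanine-style amino acid in the neutral CCD form, with the
    terminus atoms (H2 on N, OXT/HXT on the carboxyl) present."""
    b = _Builder()
    b.add("N", "N", (0.0, 0.0, 0.0))
    b.add("CA", "C", (1.47, 0.0, 0.0), bond_to="N")
    b.add("X", "C", (-0.5, 1.0, 0.0))
    b.add_int("C", "C", ("X", "N", "CA"), 1.53, 110.0, 150.0)
    b.add_int("CB", "C", ("X", "N", "CA"), 1.53, 110.5, 30.0)
    b.add_int("HA", "H", ("X", "N", "CA"), CH, 108.0, -90.0)
    b.add_int("O", "O", ("N", "CA", "C"), 1.23, 120.5, -30.0,
              order=BondOrder.DOUBLE)
    b.add_int("OXT", "O", ("N", "CA", "C"), 1.34, 113.0, 150.0)
    b.add_int("HXT", "H", ("CA", "C", "OXT"), 0.97, 106.0, 180.0)
    b.add_int("H", "H", ("C", "CA", "N"), 1.01, 109.0, 60.0)
    b.add_int("H2", "H", ("C", "CA", "N"), 1.01, 109.0, 180.0)
    for i, phi in ((1, 60.0), (2, 180.0), (3, -60.0)):
        b.add_int(f"HB{i}", "H", ("N", "CA", "CB"), CH, TET, phi)
    comp = b.component("ALX", "alanine-like amino-acid fixture",
                       comp_class=ComponentClass.AMINO_ACID,
                       smiles="CC(N)C(=O)O")
    atoms = [a for a in comp.atoms if a.name != "X"]
    coords = {k: v for k, v in comp.coords.items() if k != "X"}
    return replace(comp, atoms=atoms, coords=coords)


def _phosphate_like() -> Component:
    """Methyl dihydrogen phosphate: a phosphate mono-ester with two
    acidic P-O-H protons, the archetypal difficult moiety.  The P centre
    is exactly tetrahedral and the three P-O single bonds share one
    length, so every chemical-type class carries a single geometric
    value and a mean-based reference table is exactly consistent."""
    b = _Builder()
    b.add("P1", "P", (0.0, 0.0, 0.0))
    b.add("O1", "O", (1.59, 0.0, 0.0), bond_to="P1")  # ester oxygen
    b.add("X", "C", (-0.5, 1.0, 0.0))
    b.add_int("O2", "O", ("X", "O1", "P1"), 1.48, TET, 0.0,
              order=BondOrder.DOUBLE)
    b.add_int("O3", "O", ("X", "O1", "P1"), 1.59, TET, 120.0)
    b.add_int("O4", "O", ("X", "O1", "P1"), 1.59, TET, -120.0)
    b.add_int("C1", "C", ("X", "P1", "O1"), 1.44, 119.0, 120.0)
    b.add_int("HO3", "H", ("O1", "P1", "O3"), 0.97, 110.0, 180.0)
    b.add_int("HO4", "H", ("O1", "P1", "O4"), 0.97, 110.0, 180.0)
    for i, phi in ((1, 60.0), (2, 180.0), (3, -60.0)):
        b.add_int(f"H1{i}", "H", ("P1", "O1", "C1"), CH, 110.0, phi)
    comp = b.component("MPH", "methyl phosphate fixture",
                       smiles="COP(=O)(O)O")
    atoms = [a for a in comp.atoms if a.name != "X"]
    coords = {k: v for k, v in comp.coords.items() if k != "X"}
    return replace(comp, atoms=atoms, coords=coords)


def make_component(spec: FixtureSpec) -> Component:
    """Build the requested fixture; deterministic, optionally noised."""
    if spec.kind == "alkane_chain":
        comp = _methane() if spec.n == 1 else _chain(spec.n)
    elif spec.kind == "benzene":
        comp = _benzene()
    elif spec.kind == "acetic_acid":
        comp = _acetic_acid(deprotonated=False)
    elif spec.kind == "acetate":
        comp = _acetic_acid(deprotonated=True)
    elif spec.kind == "alanine_like":
        comp = _alanine_like()
    elif spec.kind == "phosphate_like":
        comp = _phosphate_like()
    else:  # pragma: no cover - guarded by FixtureSpec
        raise ValueError(spec.kind)
    if spec.noise_sigma > 0:
        comp = perturb(comp, spec.noise_sigma, spec.seed)
    return comp


def perturb(component: Component, sigma: float, seed: int) -> Component:
    """Add independent Gaussian noise (sigma per Cartesian component) to
    every atom; deterministic for a given seed."""
    if component.coords is None:
        raise ValueError("perturb needs coordinates")
    if sigma == 0:
        return replace(component, coords=dict(component.coords))
    rng = np.random.default_rng(seed)
    names = component.atom_names
    noise = rng.normal(0.0, sigma, size=(len(names), 3))
    coords = {
        n: tuple(np.asarray(component.coords[n]) + noise[i])
        for i, n in enumerate(names)
    }
    return replace(component, coords=coords)


def make_reference_table(
    dictionary: RestraintDictionary,
    graph: MolecularGraph,
    sd_bond: float = 0.01,
    sd_angle: float = 1.0,
    bias: float = 0.0,
    seed: int = 0,
    bias_key: Optional[str] = None,
    sd_overrides: Optional[dict[str, float]] = None,
) -> ReferenceTable:
    """Derive a reference table from a dictionary's own ideals.

    Each distinct type key gets one entry whose ideal is the mean of the
    dictionary ideals sharing that key, shifted by ``bias`` (all keys, or
    only ``bias_key`` when given).  With bias 0 the table is exactly
    consistent with the dictionary.  ``sd_overrides`` pins specific keys
    to a given spread (e.g. 0 to exercise the floor path)."""
    from .validation import type_key

    rng = np.random.default_rng(seed)
    sd_overrides = sd_overrides or {}
    table = ReferenceTable()

    def collect(pairs, kind):
        groups: dict[str, list[float]] = {}
        for atoms, ideal in pairs:
            key = type_key((kind, *atoms), graph)
            groups.setdefault(key, []).append(ideal)
        return groups

    bond_groups = collect(
        (((b.atom1, b.atom2), b.ideal) for b in dictionary.bonds), "bond"
    )
    angle_groups = collect(
        (((a.atom1, a.atom2, a.atom3), a.ideal) for a in dictionary.angles), "angle"
    )

    for groups, entries, sd_default in (
        (bond_groups, table.bond_entries, sd_bond),
        (angle_groups, table.angle_entries, sd_angle),
    ):
        for key, ideals in sorted(groups.items()):
            offset = bias if (bias_key is None or key == bias_key) else 0.0
            sd = sd_overrides.get(key, sd_default)
            entries[key] = ReferenceEntry(
                ideal=float(np.mean(ideals)) + offset,
                sd=float(sd),
                n_obs=int(rng.integers(5, 500)),
            )
    return table
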