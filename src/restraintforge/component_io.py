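"""Reading, writing and filtering of chemical-component descriptions.

Components are the unit everything else operates on: an atom list with
names, elements and formal charges, a bond list with orders, optional
Cartesian coordinates and metadata (SMILES, polymer class, obsolete flag).
The on-disk format is a CCD-style component CIF; MDL molblocks (SDF) are
accepted as a secondary input with generated atom names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator, Optional

import gemmi

__all__ = [
    "Atom",
    "Bond",
    "BondOrder",
    "Component",
    "ComponentClass",
    "FilterDecision",
    "FilterPolicy",
    "FilterReason",
    "read_component_cif",
    "read_components_cif",
    "read_sdf",
    "write_component_cif",
    "filter_component",
]

# IUPAC element symbols accepted in components (subset relevant to organic
# and organometallic chemistry plus all metals, so that exotic elements are
# still *parsed* and left to the filter to reject).
_PERIODIC_TABLE = {
    "H", "D", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb",
    "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn", "Fr", "Ra", "Ac", "Th",
    "Pa", "U", "Np", "Pu",
}

#: Elements that do not trip the metal filter.  Everything outside this set
#: (metals, metalloids we do not handle, and noble gases) is excluded.
DEFAULT_ALLOWED_ELEMENTS = frozenset(
    {"H", "D", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"}
)

#: Standard residues whose restraints are maintained elsewhere.
DEFAULT_STANDARD_RESIDUES = frozenset(
    {
        # amino acids
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
        "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
        "TYR", "VAL",
        # nucleic acids
        "A", "C", "G", "U", "DA", "DC", "DG", "DT", "DU",
    }
)


class BondOrder(str, Enum):
    SINGLE = "single"
    DOUBLE = "double"
    TRIPLE = "triple"
    AROMATIC = "aromatic"


class ComponentClass(str, Enum):
    NON_POLYMER = "non_polymer"
    AMINO_ACID = "amino_acid"
    NUCLEIC_ACID = "nucleic_acid"
    SACCHARIDE = "saccharide"
    OTHER_POLYMER = "other_polymer"


class FilterReason(str, Enum):
    KEPT = "kept"
    SINGLE_ATOM = "single_atom"
    CONTAINS_METAL = "contains_metal"
    OBSOLETE = "obsolete"
    STANDARD_RESIDUE = "standard_residue"
    MANUALLY_CURATED = "manually_curated"


class ComponentError(ValueError):
    """Raised for malformed or inconsistent component descriptions."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    formal_charge: int = 0
    legacy_name: Optional[str] = None

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    def __post_init__(self) -> None:
        if not self.name:
            raise ComponentError("atom name must be nonempty")
        if self.element not in _PERIODIC_TABLE:
            raise ComponentError(f"unknown element symbol {self.element!r}")


@dataclass(frozen=True)
class Bond:
    atom1: str
    atom2: str
    order: BondOrder = BondOrder.SINGLE

    def __post_init__(self) -> None:
        if self.atom1 == self.atom2:
            raise ComponentError(f"bond from atom {self.atom1!r} to itself")

    @property
    def key(self) -> frozenset:
        return frozenset((self.atom1, self.atom2))


@dataclass
class Component:
    """A chemical component: atoms, bonds, optional geometry, metadata."""

    id: str
    atoms: list[Atom]
    bonds: list[Bond]
    name: str = ""
    coords: Optional[dict[str, tuple[float, float, float]]] = None
    smiles: Optional[str] = None
    comp_class: ComponentClass = ComponentClass.NON_POLYMER
    obsolete: bool = False
    coord_source: Optional[str] = None  # "ideal" or "model" when read from CIF

    def __post_init__(self) -> None:
        self.validate()

    @property
    def net_charge(self) -> int:
        return sum(a.formal_charge for a in self.atoms)

    @property
    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(name)

    def validate(self) -> None:
        if not (1 <= len(self.id) <= 5) or not self.id.isalnum():
            raise ComponentError(
                f"component id {self.id!r} must be 1-5 alphanumeric characters"
            )
        names = self.atom_names
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ComponentError(f"duplicate atom names: {dupes}")
        known = set(names)
        seen_pairs = set()
        for b in self.bonds:
            for end in (b.atom1, b.atom2):
                if end not in known:
                    raise ComponentError(
                        f"bond references unknown atom {end!r} in component {self.id}"
                    )
            if b.key in seen_pairs:
                raise ComponentError(f"duplicate bond {b.atom1}-{b.atom2}")
            seen_pairs.add(b.key)
        if self.coords is not None:
            missing = known - set(self.coords)
            if missing:
                raise ComponentError(
                    f"coordinates missing for atoms: {sorted(missing)}"
                )

    def with_coords(self, coords: dict[str, tuple[float, float, float]]) -> "Component":
        c = replace(self, coords=dict(coords))
        c.validate()
        return c


@dataclass(frozen=True)
class FilterDecision:
    component_id: str
    kept: bool
    reason: FilterReason

    def __post_init__(self) -> None:
        assert self.kept == (self.reason is FilterReason.KEPT)


@dataclass(frozen=True)
class FilterPolicy:
    """Which components enter the restraint-generation pipeline.

    Single-atom entries (mostly ions), anything containing an element
    outside ``allowed_elements`` (metals, noble gases), obsolete entries,
    standard residues and entries on a curated skip-list are rejected, in
    that order of precedence after the obsolete check.
    """

    allowed_elements: frozenset = DEFAULT_ALLOWED_ELEMENTS
    standard_residues: frozenset = DEFAULT_STANDARD_RESIDUES
    skip_ids: frozenset = frozenset()

    @classmethod
    def from_json(cls, text: str) -> "FilterPolicy":
        raw = json.loads(text)
        kw = {}
        if "allowed_elements" in raw:
            kw["allowed_elements"] = frozenset(raw["allowed_elements"])
        if "standard_residues" in raw:
            kw["standard_residues"] = frozenset(raw["standard_residues"])
        if "skip_ids" in raw:
            kw["skip_ids"] = frozenset(raw["skip_ids"])
        return cls(**kw)


def filter_component(component: Component, policy: FilterPolicy | None = None) -> FilterDecision:
    """Decide whether a component enters the pipeline.

    The first matching rejection reason wins, in fixed precedence:
    obsolete, single_atom, contains_metal, standard_residue,
    manually_curated.
    """
    policy = policy or FilterPolicy()
    cid = component.id
    if component.obsolete:
        return FilterDecision(cid, False, FilterReason.OBSOLETE)
    if len(component.atoms) < 2:
        return FilterDecision(cid, False, FilterReason.SINGLE_ATOM)
    if any(a.element not in policy.allowed_elements for a in component.atoms):
        return FilterDecision(cid, False, FilterReason.CONTAINS_METAL)
    if cid.upper() in policy.standard_residues:
        return FilterDecision(cid, False, FilterReason.STANDARD_RESIDUE)
    if cid.upper() in {s.upper() for s in policy.skip_ids}:
        return FilterDecision(cid, False, FilterReason.MANUALLY_CURATED)
    return FilterDecision(cid, True, FilterReason.KEPT)


# ---------------------------------------------------------------------------
# CIF reading

_ORDER_FROM_CIF = {
    "SING": BondOrder.SINGLE, "SINGLE": BondOrder.SINGLE, "1": BondOrder.SINGLE,
    "DOUB": BondOrder.DOUBLE, "DOUBLE": BondOrder.DOUBLE, "2": BondOrder.DOUBLE,
    "TRIP": BondOrder.TRIPLE, "TRIPLE": BondOrder.TRIPLE, "3": BondOrder.TRIPLE,
    "AROM": BondOrder.AROMATIC, "AROMATIC": BondOrder.AROMATIC,
}
_ORDER_TO_CIF = {
    BondOrder.SINGLE: "SING",
    BondOrder.DOUBLE: "DOUB",
    BondOrder.TRIPLE: "TRIP",
    BondOrder.AROMATIC: "AROM",
}


def _comp_class_from_type(type_str: str) -> ComponentClass:
    t = type_str.lower()
    if "peptide" in t:
        return ComponentClass.AMINO_ACID
    if "dna" in t or "rna" in t:
        return ComponentClass.NUCLEIC_ACID
    if "saccharide" in t:
        return ComponentClass.SACCHARIDE
    if "non-polymer" in t or "non_polymer" in t:
        return ComponentClass.NON_POLYMER
    if "linking" in t:
        return ComponentClass.OTHER_POLYMER
    return ComponentClass.NON_POLYMER


_CLASS_TO_TYPE = {
    ComponentClass.NON_POLYMER: "non-polymer",
    ComponentClass.AMINO_ACID: "L-peptide linking",
    ComponentClass.NUCLEIC_ACID: "RNA linking",
    ComponentClass.SACCHARIDE: "saccharide",
    ComponentClass.OTHER_POLYMER: "other linking",
}


def _is_value(v: Optional[str]) -> bool:
    return v is not None and v not in (".", "?", "")


def _read_component_block(block: gemmi.cif.Block) -> Component:
    cs = gemmi.cif.as_string

    def meta(tag: str) -> Optional[str]:
        v = block.find_value("_chem_comp." + tag)
        return cs(v) if _is_value(v) else None

    comp_id = meta("id")
    atom_table = block.find(
        "_chem_comp_atom.",
        ["atom_id", "type_symbol", "?charge", "?alt_atom_id",
         "?pdbx_model_Cartn_x_ideal", "?pdbx_model_Cartn_y_ideal",
         "?pdbx_model_Cartn_z_ideal",
         "?model_Cartn_x", "?model_Cartn_y", "?model_Cartn_z"],
    )
    if len(atom_table) == 0:
        raise ComponentError(
            f"no _chem_comp_atom category found in block {block.name!r}"
        )
    if comp_id is None:
        # fall back to the data block name, tolerating a comp_ prefix
        comp_id = block.name.removeprefix("comp_")

    atoms: list[Atom] = []
    ideal: dict[str, tuple[float, float, float]] = {}
    model: dict[str, tuple[float, float, float]] = {}
    # column positions follow the query order above
    for row in atom_table:
        name = cs(row[0])
        element = cs(row[1]).capitalize()
        charge = 0
        if atom_table.has_column(2) and _is_value(row[2]):
            charge = int(float(row[2]))
        legacy = None
        if atom_table.has_column(3) and _is_value(row[3]):
            alt = cs(row[3])
            if alt != name:
                legacy = alt
        atoms.append(Atom(name, element, charge, legacy))
        try:
            if atom_table.has_column(4) and _is_value(row[4]):
                ideal[name] = (float(row[4]), float(row[5]), float(row[6]))
            if atom_table.has_column(7) and _is_value(row[7]):
                model[name] = (float(row[7]), float(row[8]), float(row[9]))
        except ValueError as exc:
            raise ComponentError(f"bad coordinate for atom {name!r}: {exc}") from exc

    bonds: list[Bond] = []
    bond_table = block.find(
        "_chem_comp_bond.", ["atom_id_1", "atom_id_2", "?value_order"]
    )
    for row in bond_table:
        order = BondOrder.SINGLE
        if bond_table.has_column(2) and _is_value(row[2]):
            raw = cs(row[2]).upper()
            if raw not in _ORDER_FROM_CIF:
                raise ComponentError(f"unknown bond order {raw!r}")
            order = _ORDER_FROM_CIF[raw]
        bonds.append(Bond(cs(row[0]), cs(row[1]), order))

    smiles = None
    desc = block.find("_pdbx_chem_comp_descriptor.", ["type", "descriptor"])
    for row in desc:
        if cs(row[0]).upper().startswith("SMILES"):
            smiles = cs(row[1])
            if cs(row[0]).upper() == "SMILES_CANONICAL":
                break

    coords: Optional[dict] = None
    source = None
    if ideal and len(ideal) == len(atoms):
        coords, source = ideal, "ideal"
    elif model and len(model) == len(atoms):
        coords, source = model, "model"

    status = meta("pdbx_release_status") or ""
    comp = Component(
        id=comp_id,
        atoms=atoms,
        bonds=bonds,
        name=meta("name") or "",
        coords=coords,
        smiles=smiles,
        comp_class=_comp_class_from_type(meta("type") or ""),
        obsolete=status.upper() == "OBS",
        coord_source=source,
    )
    return comp


def read_component_cif(text: str) -> Component:
    """Parse a single-component CIF into a :class:`Component`.

    Both loop_ and single-row key-value forms of the atom/bond categories
    are accepted.  When both ideal and model coordinate sets are present,
    the ideal set is preferred and recorded in ``coord_source``.
    """
    try:
        doc = gemmi.cif.read_string(text)
    except (ValueError, RuntimeError) as exc:
        raise ComponentError(f"malformed CIF: {exc}") from exc
    if len(doc) == 0:
        raise ComponentError("CIF contains no data block")
    return _read_component_block(doc[0])


def read_components_cif(text: str) -> Iterator[Component]:
    """Iterate the components of a concatenated multi-block CIF stream."""
    try:
        doc = gemmi.cif.read_string(text)
    except (ValueError, RuntimeError) as exc:
        raise ComponentError(f"malformed CIF: {exc}") from exc
    for block in doc:
        yield _read_component_block(block)


def write_component_cif(component: Component) -> str:
    """Serialize a component as a CCD-style CIF (loop form always).

    ``read_component_cif`` inverts this exactly.
    """
    component.validate()
    q = gemmi.cif.quote
    doc = gemmi.cif.Document()
    block = doc.add_new_block(f"comp_{component.id}")
    block.set_pair("_chem_comp.id", q(component.id))
    block.set_pair("_chem_comp.name", q(component.name or "?"))
    block.set_pair("_chem_comp.type", q(_CLASS_TO_TYPE[component.comp_class]))
    block.set_pair(
        "_chem_comp.pdbx_release_status", "OBS" if component.obsolete else "REL"
    )

    tags = ["atom_id", "type_symbol", "charge", "alt_atom_id"]
    has_coords = component.coords is not None
    if has_coords:
        tags += [
            "pdbx_model_Cartn_x_ideal",
            "pdbx_model_Cartn_y_ideal",
            "pdbx_model_Cartn_z_ideal",
        ]
    loop = block.init_loop("_chem_comp_atom.", tags)
    for a in component.atoms:
        row = [q(a.name), a.element, str(a.formal_charge),
               q(a.legacy_name) if a.legacy_name else "."]
        if has_coords:
            row += ["%.6f" % x for x in component.coords[a.name]]
        loop.add_row(row)

    loop = block.init_loop("_chem_comp_bond.", ["atom_id_1", "atom_id_2", "value_order"])
    for b in component.bonds:
        loop.add_row([q(b.atom1), q(b.atom2), _ORDER_TO_CIF[b.order]])

    if component.smiles:
        loop = block.init_loop("_pdbx_chem_comp_descriptor.", ["type", "descriptor"])
        loop.add_row(["SMILES_CANONICAL", q(component.smiles)])
    return doc.as_string()


# ---------------------------------------------------------------------------
# SDF / molblock reading

_RDKIT_ORDER = {
    "SINGLE": BondOrder.SINGLE,
    "DOUBLE": BondOrder.DOUBLE,
    "TRIPLE": BondOrder.TRIPLE,
    "AROMATIC": BondOrder.AROMATIC,
}


def read_sdf(text: str, component_id: str = "LIG") -> Component:
    """Parse an MDL V2000/V3000 molblock.

    Molblocks carry no atom names, so names are generated as element
    symbol plus a 1-based per-element serial (C1, C2, H1, ...); restraints
    are keyed by these names.  Formal charges from the ``M  CHG`` property
    block are propagated.
    """
    from rdkit import Chem

    mol = Chem.MolFromMolBlock(text, sanitize=False, removeHs=False)
    if mol is None:
        raise ComponentError("unparsable molblock")
    conf = mol.GetConformer() if mol.GetNumConformers() else None
    counters: dict[str, int] = {}
    atoms: list[Atom] = []
    names: list[str] = []
    coords: dict[str, tuple[float, float, float]] = {}
    for at in mol.GetAtoms():
        el = at.GetSymbol()
        counters[el] = counters.get(el, 0) + 1
        name = f"{el}{counters[el]}"
        names.append(name)
        atoms.append(Atom(name, el, at.GetFormalCharge()))
        if conf is not None:
            p = conf.GetAtomPosition(at.GetIdx())
            coords[name] = (p.x, p.y, p.z)
    bonds = [
        Bond(
            names[b.GetBeginAtomIdx()],
            names[b.GetEndAtomIdx()],
            _RDKIT_ORDER.get(str(b.GetBondType()), BondOrder.SINGLE),
        )
        for b in mol.GetBonds()
    ]
    return Component(
        id=component_id,
        atoms=atoms,
        bonds=bonds,
        coords=coords or None,
        coord_source="model" if coords else None,
    )
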