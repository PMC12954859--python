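"""Molecular-graph perception: connectivity, rings, aromaticity,
hybridization, protonation variants and polymer-terminus trimming.

Hybridization drives torsion-restraint periodicity and the typing keys
used for validation, so the assignment here is deliberately simple and
rule-based: triple bonds or cumulated double bonds make an atom sp,
aromaticity or a single double bond makes it sp2, everything else heavy
is sp3 and hydrogens are terminal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import networkx as nx

from .component_io import (
    Atom,
    Bond,
    BondOrder,
    Component,
    ComponentClass,
    ComponentError,
)

__all__ = [
    "Hybridization",
    "MolecularGraph",
    "ProtonationVariant",
    "VariantLabel",
    "build_graph",
    "assign_hybridization",
    "enumerate_protonation_variants",
    "trim_polymer_termini",
    "BACKBONE_ATOM_NAMES",
    "TERMINUS_ATOM_NAMES",
]

log = logging.getLogger(__name__)

#: Amino-acid backbone atom names used for the side-chain/backbone split.
BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O", "OXT", "H", "H2", "HA", "HXT"})

#: Terminus atoms removed when preparing a polymerizable amino acid.
TERMINUS_ATOM_NAMES = ("H2", "OXT", "HXT")


class Hybridization(str, Enum):
    SP = "sp"
    SP2 = "sp2"
    SP3 = "sp3"
    TERMINAL = "terminal"
    OTHER = "other"


class VariantLabel(str, Enum):
    IN_SITU = "in_situ"
    IN_NOTITIA = "in_notitia"


@dataclass
class MolecularGraph:
    component_id: str
    adjacency: dict[str, set[str]]
    bond_orders: dict[frozenset, BondOrder]
    elements: dict[str, str] = field(default_factory=dict)
    hybridization: dict[str, Hybridization] = field(default_factory=dict)
    aromatic_atoms: set[str] = field(default_factory=set)
    ring_memberships: list[frozenset] = field(default_factory=list)

    def neighbors(self, name: str) -> list[str]:
        return sorted(self.adjacency[name])

    def order(self, a: str, b: str) -> BondOrder:
        return self.bond_orders[frozenset((a, b))]

    def in_ring(self, name: str) -> bool:
        return any(name in ring for ring in self.ring_memberships)

    def bond_in_ring(self, a: str, b: str) -> bool:
        return any(a in ring and b in ring for ring in self.ring_memberships)


def _sssr(g: nx.Graph) -> list[frozenset]:
    """Smallest set of smallest rings via minimum cycle basis, with ties
    broken by sorted atom-name order for determinism."""
    rings = nx.minimum_cycle_basis(g)
    return sorted(
        (frozenset(r) for r in rings), key=lambda r: (len(r), tuple(sorted(r)))
    )


def build_graph(component: Component) -> MolecularGraph:
    """Perceive adjacency, rings and aromatic atoms from the bond list.

    Aromaticity trusts explicit aromatic bond flags; additionally, 6-rings
    of alternating single/double bonds (Kekulé benzenoids) are marked
    aromatic.  No electron counting is attempted.
    """
    adjacency: dict[str, set[str]] = {a.name: set() for a in component.atoms}
    bond_orders: dict[frozenset, BondOrder] = {}
    for b in component.bonds:
        adjacency[b.atom1].add(b.atom2)
        adjacency[b.atom2].add(b.atom1)
        bond_orders[b.key] = b.order
    for a in component.atoms:
        if a.is_hydrogen and len(adjacency[a.name]) == 0 and len(component.atoms) > 1:
            raise ComponentError(f"hydrogen {a.name!r} has no bonds")

    g = nx.Graph()
    g.add_nodes_from(adjacency)
    g.add_edges_from((b.atom1, b.atom2) for b in component.bonds)
    rings = _sssr(g)

    aromatic: set[str] = set()
    for key, order in bond_orders.items():
        if order is BondOrder.AROMATIC:
            aromatic.update(key)
    for ring in rings:
        if len(ring) != 6:
            continue
        cycle = _ring_cycle(ring, adjacency)
        if cycle is None:
            continue
        orders = [
            bond_orders[frozenset((cycle[i], cycle[(i + 1) % 6]))] for i in range(6)
        ]
        if all(o in (BondOrder.SINGLE, BondOrder.DOUBLE) for o in orders):
            if all(orders[i] != orders[(i + 1) % 6] for i in range(6)):
                aromatic.update(ring)
    # an aromatic atom must lie in a ring; drop flags that do not
    ring_atoms = set().union(*rings) if rings else set()
    aromatic &= ring_atoms if rings else set()

    return MolecularGraph(
        component_id=component.id,
        adjacency=adjacency,
        bond_orders=bond_orders,
        elements={a.name: a.element for a in component.atoms},
        aromatic_atoms=aromatic,
        ring_memberships=rings,
    )


def _ring_cycle(ring: frozenset, adjacency: dict[str, set[str]]) -> Optional[list[str]]:
    """Order ring atoms into a cycle; None if the set is not a simple cycle."""
    start = min(ring)
    cycle = [start]
    prev = None
    while True:
        nxt = sorted(n for n in adjacency[cycle[-1]] if n in ring and n != prev)
        nxt = [n for n in nxt if n != start or len(cycle) == len(ring)]
        if not nxt:
            return None
        prev = cycle[-1]
        if nxt[0] == start:
            return cycle if len(cycle) == len(ring) else None
        cycle.append(nxt[0])
        if len(cycle) > len(ring):
            return None


def assign_hybridization(graph: MolecularGraph, component: Component) -> MolecularGraph:
    """Label each atom sp / sp2 / sp3 / terminal by its bond pattern."""
    hyb: dict[str, Hybridization] = {}
    for a in component.atoms:
        name = a.name
        if a.is_hydrogen:
            hyb[name] = Hybridization.TERMINAL
            continue
        orders = [graph.order(name, n) for n in graph.adjacency[name]]
        degree = len(orders)
        n_triple = sum(o is BondOrder.TRIPLE for o in orders)
        n_double = sum(o is BondOrder.DOUBLE for o in orders)
        # hypervalent centres (phosphates, sulfones: 4 sigma partners)
        # stay tetrahedral regardless of formal double bonds
        if degree >= 4:
            hyb[name] = Hybridization.SP3
        elif n_triple >= 1 or (n_double >= 2 and degree == 2):
            hyb[name] = Hybridization.SP
        elif name in graph.aromatic_atoms or n_double >= 1 or any(
            o is BondOrder.AROMATIC for o in orders
        ):
            hyb[name] = Hybridization.SP2
        else:
            hyb[name] = Hybridization.SP3
    graph.hybridization = hyb
    return graph


# ---------------------------------------------------------------------------
# Protonation variants

@dataclass(frozen=True)
class ProtonationVariant:
    """One protonation state of a component.

    ``in_notitia`` is the state as recorded in the component dictionary
    (acids typically protonated); ``in_situ`` is the state expected in a
    protein model at physiological pH (acids deprotonated).
    """

    label: VariantLabel
    component: Component
    removed_atoms: tuple[str, ...] = ()
    delta_charge: int = 0


def _acidic_hydrogens(component: Component, graph: MolecularGraph) -> list[str]:
    """H atoms on O bound to C(=O), S(>=2 S=O) or P(>=1 P=O)."""
    acidic: list[str] = []
    elements = {a.name: a.element for a in component.atoms}
    for a in component.atoms:
        if not a.is_hydrogen:
            continue
        neigh = list(graph.adjacency[a.name])
        if len(neigh) != 1 or elements[neigh[0]] != "O":
            continue
        oxy = neigh[0]
        for heavy in graph.adjacency[oxy]:
            if heavy == a.name:
                continue
            if graph.order(oxy, heavy) is not BondOrder.SINGLE:
                continue
            el = elements[heavy]
            n_dbl_o = sum(
                1
                for x in graph.adjacency[heavy]
                if elements[x] == "O" and graph.order(heavy, x) is BondOrder.DOUBLE
            )
            if (el == "C" and n_dbl_o >= 1) or (el == "S" and n_dbl_o >= 2) or (
                el == "P" and n_dbl_o >= 1
            ):
                acidic.append(a.name)
                break
    return sorted(acidic)


def remove_atoms(component: Component, names: set[str],
                 charge_shift: Optional[dict[str, int]] = None) -> Component:
    """Return a copy of the component without the named atoms (and any
    bonds touching them), optionally shifting formal charges."""
    charge_shift = charge_shift or {}
    atoms = [
        replace(a, formal_charge=a.formal_charge + charge_shift.get(a.name, 0))
        for a in component.atoms
        if a.name not in names
    ]
    bonds = [b for b in component.bonds if b.atom1 not in names and b.atom2 not in names]
    coords = None
    if component.coords is not None:
        coords = {k: v for k, v in component.coords.items() if k not in names}
    return replace(component, atoms=atoms, bonds=bonds, coords=coords)


def enumerate_protonation_variants(
    component: Component, graph: Optional[MolecularGraph] = None
) -> list[ProtonationVariant]:
    """Enumerate the in-situ and in-notitia protonation states.

    The in-situ variant removes every acidic proton (carboxylic, sulfonic,
    phosphate-like OH) and puts the resulting negative charge on the bare
    oxygen.  Components without acidic protons yield a single variant.
    The in-situ variant is listed first: it is the one validated first
    downstream.
    """
    if graph is None:
        graph = build_graph(component)
    acidic = _acidic_hydrogens(component, graph)
    if not acidic:
        return [ProtonationVariant(VariantLabel.IN_SITU, component)]
    shifts: dict[str, int] = {}
    for h in acidic:
        (oxy,) = graph.adjacency[h]
        shifts[oxy] = shifts.get(oxy, 0) - 1
    deprot = remove_atoms(component, set(acidic), shifts)
    return [
        ProtonationVariant(
            VariantLabel.IN_SITU, deprot, tuple(acidic), -len(acidic)
        ),
        ProtonationVariant(VariantLabel.IN_NOTITIA, component),
    ]


def trim_polymer_termini(component: Component) -> Component:
    """Remove the terminus atoms (H2, OXT, HXT) of a polymerizable amino
    acid so the restraints suit the in-chain form.  Other polymer classes
    pass through unchanged.  Formal charges are left untouched."""
    if component.comp_class is not ComponentClass.AMINO_ACID:
        log.debug("trim_polymer_termini: %s is %s, not trimmed",
                  component.id, component.comp_class.value)
        return component
    present = {n for n in TERMINUS_ATOM_NAMES if n in component.atom_names}
    if not present:
        return component
    return remove_atoms(component, present)
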