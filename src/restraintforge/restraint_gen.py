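"""Measure internal coordinates and build a refinement restraint dictionary.

A dictionary collects bond, angle, torsion, chirality and plane restraints
for one component, each with an ideal value and an estimated standard
deviation (e.s.d.).  Ideal values come from the supplied (minimized)
geometry; e.s.d. values come from a reference table of experimentally
derived spreads, doubled for refinement use and floored against
unrealistically small spreads, or from configurable defaults when the
term's type has no reference entry.

Torsion restraints carry either a periodicity (evenly spaced minima) or a
discrete list of alternative ideal values (period 0) for bonds whose
minima are not evenly spaced.  Every hydrogen is guaranteed a bond, an
angle and — whenever a four-atom path exists — a positioning torsion, so
that riding-hydrogen schemes can place it deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import gemmi
import numpy as np

from .component_io import Component, ComponentError
from .chemgraph import Hybridization, MolecularGraph, VariantLabel

__all__ = [
    "MeasuredGeometry",
    "BondRestraint",
    "AngleRestraint",
    "TorsionRestraint",
    "ChiralitySign",
    "ChiralityRestraint",
    "PlaneRestraint",
    "RestraintDictionary",
    "EsdPolicy",
    "measure_geometry",
    "assign_torsion_restraints",
    "detect_planes",
    "assign_chirality",
    "build_dictionary",
    "write_restraint_cif",
    "read_restraint_cif",
    "wrap_angle",
    "torsion_distance",
]

_ATOMIC_NUMBER = {
    "H": 1, "D": 1, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "Si": 14,
    "P": 15, "S": 16, "Cl": 17, "Se": 34, "Br": 35, "I": 53,
}

#: Signed-volume magnitude below which a nominally tetrahedral centre is
#: treated as having indeterminate handedness.
CHIRAL_VOLUME_THRESHOLD = 0.1  # Angstrom^3


def wrap_angle(deg: float) -> float:
    """Wrap an angle into (-180, 180]."""
    w = math.fmod(deg, 360.0)
    if w <= -180.0:
        w += 360.0
    elif w > 180.0:
        w -= 360.0
    return w


def torsion_distance(a: float, b: float) -> float:
    """Wrap-aware absolute difference between two torsion values."""
    return abs(wrap_angle(a - b))


# ---------------------------------------------------------------------------
# Measured internal coordinates

@dataclass(frozen=True)
class MeasuredBond:
    atom1: str
    atom2: str
    length: float  # Angstrom


@dataclass(frozen=True)
class MeasuredAngle:
    atom1: str
    atom2: str  # vertex
    atom3: str
    degrees: float


@dataclass(frozen=True)
class MeasuredTorsion:
    atom1: str
    atom2: str
    atom3: str
    atom4: str
    degrees: float

    @property
    def central_bond(self) -> frozenset:
        return frozenset((self.atom2, self.atom3))


@dataclass(frozen=True)
class MeasuredChirality:
    center: str
    neighbor1: str
    neighbor2: str
    neighbor3: str
    volume: float  # signed triple product, Angstrom^3


@dataclass(frozen=True)
class MeasuredPlane:
    atoms: frozenset
    rms_deviation: float  # Angstrom, from the best-fit plane


@dataclass
class MeasuredGeometry:
    bonds: list[MeasuredBond]
    angles: list[MeasuredAngle]
    torsions: list[MeasuredTorsion]
    chiral_centers: list[MeasuredChirality]
    plane_groups: list[MeasuredPlane]


def bond_length(x1: np.ndarray, x2: np.ndarray) -> float:
    return float(np.linalg.norm(x2 - x1))


def bond_angle(x1: np.ndarray, x2: np.ndarray, x3: np.ndarray) -> float:
    """Angle at vertex x2, degrees."""
    u, v = x1 - x2, x3 - x2
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def dihedral(x1: np.ndarray, x2: np.ndarray, x3: np.ndarray, x4: np.ndarray) -> float:
    """Signed dihedral about x2-x3 (IUPAC convention), degrees in (-180, 180]."""
    b1, b2, b3 = x2 - x1, x3 - x2, x4 - x3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return wrap_angle(-math.degrees(math.atan2(np.dot(m, n2), np.dot(n1, n2))))


def signed_volume(c: np.ndarray, n1: np.ndarray, n2: np.ndarray, n3: np.ndarray) -> float:
    """Triple product of the three centre-to-neighbour vectors."""
    return float(np.dot(n1 - c, np.cross(n2 - c, n3 - c)))


def best_fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through points: (centroid, unit normal)."""
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid)
    return centroid, vt[-1]


def _ordered_neighbors(graph: MolecularGraph, component: Component, center: str) -> list[str]:
    """Chirality neighbour order: descending atomic number, ties by name."""
    elements = {a.name: a.element for a in component.atoms}
    return sorted(
        graph.adjacency[center],
        key=lambda n: (-_ATOMIC_NUMBER.get(elements[n], 0), n),
    )


def measure_geometry(component: Component, graph: MolecularGraph) -> MeasuredGeometry:
    """Measure every internal coordinate of a component's geometry.

    Bonds follow the bond list; angles take every pair of distinct
    neighbours around each centre (hydrogen-containing triples included —
    riding hydrogens need them); torsions enumerate every four-atom bonded
    path; chiral volumes are computed for sp3 centres with at least three
    heavy neighbours; plane groups come from :func:`detect_planes` with
    their current rms deviations.
    """
    if component.coords is None:
        raise ComponentError(f"component {component.id} has no coordinates")
    xyz = {name: np.asarray(component.coords[name], dtype=float)
           for name in component.atom_names}
    for name in component.atom_names:
        if name not in xyz:
            raise ComponentError(f"missing coordinate for atom {name!r}")
    names = component.atom_names
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if np.linalg.norm(xyz[a] - xyz[b]) < 0.1:
                raise ComponentError(
                    f"degenerate geometry: atoms {a!r} and {b!r} overlap"
                )

    bonds = [
        MeasuredBond(b.atom1, b.atom2, bond_length(xyz[b.atom1], xyz[b.atom2]))
        for b in component.bonds
    ]

    angles: list[MeasuredAngle] = []
    for center in names:
        neigh = sorted(graph.adjacency[center])
        for i in range(len(neigh)):
            for j in range(i + 1, len(neigh)):
                a, c = neigh[i], neigh[j]
                angles.append(
                    MeasuredAngle(a, center, c, bond_angle(xyz[a], xyz[center], xyz[c]))
                )

    torsions: list[MeasuredTorsion] = []
    for b in component.bonds:
        a2, a3 = sorted((b.atom1, b.atom2))
        for a1 in sorted(graph.adjacency[a2] - {a3}):
            for a4 in sorted(graph.adjacency[a3] - {a2, a1}):
                torsions.append(
                    MeasuredTorsion(
                        a1, a2, a3, a4,
                        dihedral(xyz[a1], xyz[a2], xyz[a3], xyz[a4]),
                    )
                )

    hyb = graph.hybridization
    elements = {a.name: a.element for a in component.atoms}
    chirals: list[MeasuredChirality] = []
    for center in names:
        if hyb.get(center) is not Hybridization.SP3:
            continue
        heavy = [n for n in _ordered_neighbors(graph, component, center)
                 if elements[n] not in ("H", "D")]
        if len(heavy) < 3:
            continue
        n1, n2, n3 = heavy[:3]
        chirals.append(
            MeasuredChirality(
                center, n1, n2, n3,
                signed_volume(xyz[center], xyz[n1], xyz[n2], xyz[n3]),
            )
        )

    planes: list[MeasuredPlane] = []
    for pr in detect_planes(graph, component):
        pts = np.array([xyz[n] for n in sorted(pr.atoms)])
        centroid, normal = best_fit_plane(pts)
        dev = (pts - centroid) @ normal
        planes.append(MeasuredPlane(frozenset(pr.atoms), float(np.sqrt(np.mean(dev ** 2)))))

    return MeasuredGeometry(bonds, angles, torsions, chirals, planes)


# ---------------------------------------------------------------------------
# Restraint records

@dataclass(frozen=True)
class BondRestraint:
    atom1: str
    atom2: str
    ideal: float  # Angstrom
    esd: float  # Angstrom

    def __post_init__(self):
        if self.esd <= 0:
            raise ComponentError("bond restraint esd must be positive")


@dataclass(frozen=True)
class AngleRestraint:
    atom1: str
    atom2: str
    atom3: str
    ideal: float  # degrees
    esd: float

    def __post_init__(self):
        if self.esd <= 0:
            raise ComponentError("angle restraint esd must be positive")
        if not 0.0 < self.ideal < 180.0:
            raise ComponentError(f"angle ideal {self.ideal} out of (0, 180)")


@dataclass(frozen=True)
class TorsionRestraint:
    id: str
    atom1: str
    atom2: str
    atom3: str
    atom4: str
    ideal: float  # degrees, (-180, 180]
    esd: float
    period: int
    alt_ideals: Optional[tuple[float, ...]] = None

    def __post_init__(self):
        if self.esd <= 0:
            raise ComponentError("torsion restraint esd must be positive")
        if self.alt_ideals is not None:
            if self.period != 0 or len(self.alt_ideals) == 0:
                raise ComponentError(
                    "alt_ideals requires period 0 and a nonempty value list"
                )
            for v in self.alt_ideals:
                if not -180.0 < v <= 180.0:
                    raise ComponentError(f"alt ideal {v} outside (-180, 180]")
        elif self.period < 1:
            raise ComponentError("torsion period must be >= 1 unless alt_ideals given")


class ChiralitySign(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    BOTH = "both"


@dataclass(frozen=True)
class ChiralityRestraint:
    center: str
    neighbor1: str
    neighbor2: str
    neighbor3: str
    sign: ChiralitySign


@dataclass(frozen=True)
class PlaneRestraint:
    plane_id: str
    atoms: frozenset
    esd: float  # Angstrom

    def __post_init__(self):
        if len(self.atoms) < 4:
            raise ComponentError("plane restraint needs at least 4 atoms")
        if self.esd <= 0:
            raise ComponentError("plane restraint esd must be positive")


@dataclass(frozen=True)
class EsdPolicy:
    """How e.s.d. values are derived from reference spreads.

    Reference s.d. values are first floored (they can legitimately be
    zero when a bond or angle type has a single observation) and then
    multiplied — refinement-practice e.s.d. is twice the reference s.d.
    Terms without a reference entry fall back to the defaults.
    """

    esd_multiplier: float = 2.0
    bond_floor: float = 0.005  # Angstrom
    angle_floor: float = 0.75  # degrees
    default_bond_esd: float = 0.02
    default_angle_esd: float = 1.5
    default_torsion_esd_by_period: dict = field(
        default_factory=lambda: {0: 10.0, 1: 10.0, 2: 20.0, 3: 30.0, 6: 30.0}
    )
    default_plane_esd: float = 0.02

    def __post_init__(self):
        vals = [self.esd_multiplier, self.bond_floor, self.angle_floor,
                self.default_bond_esd, self.default_angle_esd, self.default_plane_esd,
                *self.default_torsion_esd_by_period.values()]
        if any(v <= 0 for v in vals):
            raise ComponentError("all EsdPolicy values must be positive")

    def torsion_esd(self, period: int) -> float:
        return self.default_torsion_esd_by_period.get(period, 20.0)


@dataclass
class RestraintDictionary:
    component_id: str
    variant_label: VariantLabel
    bonds: list[BondRestraint]
    angles: list[AngleRestraint]
    torsions: list[TorsionRestraint]
    chirality: list[ChiralityRestraint]
    planes: list[PlaneRestraint]
    provenance: str = ""

    def restrained_atoms(self) -> set[str]:
        names: set[str] = set()
        for b in self.bonds:
            names.update((b.atom1, b.atom2))
        for a in self.angles:
            names.update((a.atom1, a.atom2, a.atom3))
        for t in self.torsions:
            names.update((t.atom1, t.atom2, t.atom3, t.atom4))
        for c in self.chirality:
            names.update((c.center, c.neighbor1, c.neighbor2, c.neighbor3))
        for p in self.planes:
            names.update(p.atoms)
        return names

    def check_hydrogen_completeness(self, component: Component,
                                    graph: MolecularGraph) -> list[str]:
        """Return the hydrogens missing a bond, angle or (when a 4-atom
        path exists) positioning torsion restraint."""
        offenders: list[str] = []
        bond_atoms = [set((b.atom1, b.atom2)) for b in self.bonds]
        angle_atoms = [set((a.atom1, a.atom2, a.atom3)) for a in self.angles]
        tor_ends = [(t.atom1, t.atom4) for t in self.torsions]
        for a in component.atoms:
            if not a.is_hydrogen:
                continue
            h = a.name
            ok_bond = any(h in s for s in bond_atoms)
            ok_angle = any(h in s for s in angle_atoms)
            ok_tor = any(h in ends for ends in tor_ends)
            if not _has_torsion_path(graph, h):
                ok_tor = True
            if not (ok_bond and ok_angle and ok_tor):
                offenders.append(h)
        return offenders


def _has_torsion_path(graph: MolecularGraph, h: str) -> bool:
    """True if a non-degenerate 4-atom bonded path starts at the hydrogen.

    Paths through sp (linear) centres are excluded: a dihedral about a
    collinear axis is undefined, so such hydrogens cannot be positioned
    by a torsion."""
    hyb = graph.hybridization
    for b in graph.adjacency[h]:
        if hyb.get(b) is Hybridization.SP:
            continue
        for c in graph.adjacency[b] - {h}:
            if hyb.get(c) is Hybridization.SP:
                continue
            if graph.adjacency[c] - {h, b}:
                return True
    return False


# ---------------------------------------------------------------------------
# Restraint assignment

def _torsion_rule(graph: MolecularGraph, a2: str, a3: str) -> Optional[tuple[int, str]]:
    """Period and ideal-policy for the central bond a2-a3, or None when no
    torsion restraint applies.  Policies: "measured" keeps the measured
    value; "snap" snaps to the nearer of 0/180."""
    hyb = graph.hybridization
    h2, h3 = hyb[a2], hyb[a3]
    if Hybridization.SP in (h2, h3):
        return None
    if graph.bond_in_ring(a2, a3):
        if a2 in graph.aromatic_atoms and a3 in graph.aromatic_atoms:
            return None  # covered by the plane restraint
        return (1, "measured")
    sp2 = {Hybridization.SP2}
    if h2 in sp2 and h3 in sp2:
        return (2, "snap")
    if h2 in sp2 or h3 in sp2:
        return (6, "measured")
    return (3, "measured")


def _priority_key(graph: MolecularGraph, name: str) -> tuple:
    """Heaviest element first, ties by lowest atom name."""
    return (-_ATOMIC_NUMBER.get(graph.elements[name], 0), name)


def _snap(ideal: float) -> float:
    return 180.0 if torsion_distance(ideal, 180.0) <= 90.0 else 0.0


def assign_torsion_restraints(
    graph: MolecularGraph,
    measured: MeasuredGeometry,
    policy: Optional[EsdPolicy] = None,
) -> list[TorsionRestraint]:
    """Select torsion restraints from the measured torsion pool.

    One representative torsion per eligible central bond, with periodicity
    from the hybridization of the bond's end atoms (sp3-sp3 threefold,
    sp2-sp2 twofold snapped to 0/180, sp2-sp3 sixfold, non-aromatic ring
    bonds onefold at the measured value); bonds with an sp end or internal
    to an aromatic ring get no representative.  Additional torsions are
    then appended so that every hydrogen with a four-atom path is an end
    atom of at least one torsion.
    """
    policy = policy or EsdPolicy()
    by_bond: dict[frozenset, list[MeasuredTorsion]] = {}
    for t in measured.torsions:
        by_bond.setdefault(t.central_bond, []).append(t)

    restraints: list[TorsionRestraint] = []
    counter = 0

    def emit(t: MeasuredTorsion, period: int, ideal_policy: str) -> TorsionRestraint:
        nonlocal counter
        counter += 1
        ideal = _snap(t.degrees) if ideal_policy == "snap" else t.degrees
        # avoid an exactly -180 representation
        ideal = wrap_angle(ideal)
        return TorsionRestraint(
            f"tor_{counter}", t.atom1, t.atom2, t.atom3, t.atom4,
            ideal, policy.torsion_esd(period), period,
        )

    positioned_h: set[str] = set()
    hydrogens = {
        name for name, h in graph.hybridization.items()
        if h is Hybridization.TERMINAL
    }

    for key in sorted(by_bond, key=lambda k: tuple(sorted(k))):
        a2, a3 = sorted(key)
        rule = _torsion_rule(graph, a2, a3)
        if rule is None:
            continue
        period, ideal_policy = rule
        cands = by_bond[key]

        def rank(t: MeasuredTorsion):
            ends = sorted([t.atom1, t.atom4], key=lambda n: _priority_key(graph, n))
            return tuple(_priority_key(graph, n) for n in ends) + ((t.atom1, t.atom4),)

        best = min(cands, key=rank)
        restraints.append(emit(best, period, ideal_policy))
        positioned_h.update({best.atom1, best.atom4} & hydrogens)

    # H-positioning completeness: every hydrogen that admits a 4-atom path
    # must be the end atom of some torsion, even across aromatic ring
    # bonds where no representative torsion was emitted.
    hyb = graph.hybridization
    for h in sorted(hydrogens - positioned_h):
        cands = [
            t for ts in by_bond.values() for t in ts
            if h in (t.atom1, t.atom4)
            and Hybridization.SP not in (hyb[t.atom2], hyb[t.atom3])
        ]
        if not cands:
            continue
        def h_rank(t: MeasuredTorsion):
            rule = _torsion_rule(graph, *sorted(t.central_bond))
            return (rule is None, t.atom1, t.atom2, t.atom3, t.atom4)
        best = min(cands, key=h_rank)
        rule = _torsion_rule(graph, *sorted(best.central_bond))
        if rule is None:
            period, ideal_policy = 2, "snap"  # aromatic ring bond
        else:
            period, ideal_policy = rule
        restraints.append(emit(best, period, ideal_policy))
        positioned_h.add(h)
    return restraints


def perceive(component: Component) -> MolecularGraph:
    """Convenience: build the graph and assign hybridization."""
    from .chemgraph import assign_hybridization, build_graph

    return assign_hybridization(build_graph(component), component)


def detect_planes(graph: MolecularGraph, component: Component) -> list[PlaneRestraint]:
    """Group atoms into planarity restraints.

    One plane per aromatic ring (ring atoms plus first-shell
    substituents), one per non-ring sp2 centre with its neighbours;
    groups sharing three or more atoms are merged; groups smaller than
    four atoms are dropped.
    """
    policy = EsdPolicy()
    groups: list[set[str]] = []
    for ring in graph.ring_memberships:
        if not ring <= graph.aromatic_atoms:
            continue
        grp = set(ring)
        for a in ring:
            grp |= graph.adjacency[a]
        groups.append(grp)
    for name, h in sorted(graph.hybridization.items()):
        if h is not Hybridization.SP2 or graph.in_ring(name):
            continue
        groups.append({name} | graph.adjacency[name])

    merged = True
    while merged:
        merged = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if len(groups[i] & groups[j]) >= 3:
                    groups[i] |= groups.pop(j)
                    merged = True
                    break
            if merged:
                break

    groups = [g for g in groups if len(g) >= 4]
    groups.sort(key=lambda g: tuple(sorted(g)))
    return [
        PlaneRestraint(f"plane_{i + 1}", frozenset(g), policy.default_plane_esd)
        for i, g in enumerate(groups)
    ]


def assign_chirality(graph: MolecularGraph, component: Component) -> list[ChiralityRestraint]:
    """Chirality restraints for sp3 centres with >= 3 heavy neighbours.

    Neighbours are ordered by descending atomic number then name; the
    sign is that of the triple product of the centre-to-neighbour
    vectors, or ``both`` when the volume is within the degeneracy
    threshold of zero.
    """
    if component.coords is None:
        raise ComponentError("chirality assignment needs coordinates")
    xyz = {n: np.asarray(component.coords[n], float) for n in component.atom_names}
    elements = {a.name: a.element for a in component.atoms}
    out: list[ChiralityRestraint] = []
    for center in component.atom_names:
        if graph.hybridization.get(center) is not Hybridization.SP3:
            continue
        heavy = [n for n in _ordered_neighbors(graph, component, center)
                 if elements[n] not in ("H", "D")]
        if len(heavy) < 3:
            continue
        n1, n2, n3 = heavy[:3]
        vol = signed_volume(xyz[center], xyz[n1], xyz[n2], xyz[n3])
        if vol > CHIRAL_VOLUME_THRESHOLD:
            sign = ChiralitySign.POSITIVE
        elif vol < -CHIRAL_VOLUME_THRESHOLD:
            sign = ChiralitySign.NEGATIVE
        else:
            sign = ChiralitySign.BOTH
        out.append(ChiralityRestraint(center, n1, n2, n3, sign))
    return out


def build_dictionary(
    component: Component,
    measured: MeasuredGeometry,
    policy: Optional[EsdPolicy] = None,
    table=None,
    graph: Optional[MolecularGraph] = None,
    variant_label: VariantLabel = VariantLabel.IN_SITU,
    provenance: str = "",
) -> RestraintDictionary:
    """Assemble the full restraint dictionary for one component.

    Ideal values are the measured ones.  Bond and angle e.s.d. values are
    ``multiplier x max(reference s.d., floor)`` when the term's type key
    has a reference entry, else the policy defaults.  Torsion e.s.d.
    comes from the per-period default mapping.  Raises when any hydrogen
    would be left without complete restraints.
    """
    from .validation import type_key  # late import to avoid a cycle

    policy = policy or EsdPolicy()
    if graph is None:
        graph = perceive(component)

    def bond_esd(b: MeasuredBond) -> float:
        if table is not None:
            entry = table.bond_entries.get(type_key(("bond", b.atom1, b.atom2), graph, component))
            if entry is not None:
                return policy.esd_multiplier * max(entry.sd, policy.bond_floor)
        return policy.default_bond_esd

    def angle_esd(a: MeasuredAngle) -> float:
        if table is not None:
            entry = table.angle_entries.get(
                type_key(("angle", a.atom1, a.atom2, a.atom3), graph, component)
            )
            if entry is not None:
                return policy.esd_multiplier * max(entry.sd, policy.angle_floor)
        return policy.default_angle_esd

    bonds = [BondRestraint(b.atom1, b.atom2, b.length, bond_esd(b)) for b in measured.bonds]
    angles = [
        AngleRestraint(a.atom1, a.atom2, a.atom3, a.degrees, angle_esd(a))
        for a in measured.angles
    ]
    torsions = assign_torsion_restraints(graph, measured, policy)
    chirality = assign_chirality(graph, component)
    planes = detect_planes(graph, component)

    dictionary = RestraintDictionary(
        component_id=component.id,
        variant_label=variant_label,
        bonds=bonds,
        angles=angles,
        torsions=torsions,
        chirality=chirality,
        planes=planes,
        provenance=provenance,
    )
    offenders = dictionary.check_hydrogen_completeness(component, graph)
    if offenders:
        raise ComponentError(
            f"incomplete hydrogen restraints for atoms: {offenders}"
        )
    unknown = dictionary.restrained_atoms() - set(component.atom_names)
    if unknown:
        raise ComponentError(f"restraints name unknown atoms: {sorted(unknown)}")
    return dictionary


# ---------------------------------------------------------------------------
# Restraint CIF serialization (Monomer-Library style)

_SIGN_TO_CIF = {
    ChiralitySign.POSITIVE: "positiv",
    ChiralitySign.NEGATIVE: "negativ",
    ChiralitySign.BOTH: "both",
}
_SIGN_FROM_CIF = {v: k for k, v in _SIGN_TO_CIF.items()}


def write_restraint_cif(dictionary: RestraintDictionary) -> str:
    """Serialize as a monomer-library-style restraint CIF block.

    Discrete-ideal torsions (period 0) are written as one row per
    alternative value sharing the torsion id.  Empty categories are
    omitted.
    """
    q = gemmi.cif.quote
    doc = gemmi.cif.Document()
    block = doc.add_new_block(f"comp_{dictionary.component_id}")
    block.set_pair("_chem_comp.id", q(dictionary.component_id))
    block.set_pair("_chem_comp.variant", dictionary.variant_label.value)
    if dictionary.provenance:
        block.set_pair("_chem_comp.provenance", q(dictionary.provenance))

    if dictionary.bonds:
        loop = block.init_loop(
            "_chem_comp_bond.", ["atom_id_1", "atom_id_2", "value_dist", "value_dist_esd"]
        )
        for b in dictionary.bonds:
            loop.add_row([q(b.atom1), q(b.atom2), "%.4f" % b.ideal, "%.4f" % b.esd])
    if dictionary.angles:
        loop = block.init_loop(
            "_chem_comp_angle.",
            ["atom_id_1", "atom_id_2", "atom_id_3", "value_angle", "value_angle_esd"],
        )
        for a in dictionary.angles:
            loop.add_row(
                [q(a.atom1), q(a.atom2), q(a.atom3), "%.3f" % a.ideal, "%.3f" % a.esd]
            )
    if dictionary.torsions:
        loop = block.init_loop(
            "_chem_comp_tor.",
            ["id", "atom_id_1", "atom_id_2", "atom_id_3", "atom_id_4",
             "value_angle", "value_angle_esd", "period"],
        )
        for t in dictionary.torsions:
            ideals = t.alt_ideals if t.alt_ideals is not None else (t.ideal,)
            for v in ideals:
                loop.add_row(
                    [q(t.id), q(t.atom1), q(t.atom2), q(t.atom3), q(t.atom4),
                     "%.3f" % v, "%.3f" % t.esd, str(t.period)]
                )
    if dictionary.chirality:
        loop = block.init_loop(
            "_chem_comp_chir.",
            ["id", "atom_id_centre", "atom_id_1", "atom_id_2", "atom_id_3",
             "volume_sign"],
        )
        for i, c in enumerate(dictionary.chirality):
            loop.add_row(
                [f"chir_{i + 1}", q(c.center), q(c.neighbor1), q(c.neighbor2),
                 q(c.neighbor3), _SIGN_TO_CIF[c.sign]]
            )
    if dictionary.planes:
        loop = block.init_loop(
            "_chem_comp_plane_atom.", ["plane_id", "atom_id", "dist_esd"]
        )
        for p in dictionary.planes:
            for atom in sorted(p.atoms):
                loop.add_row([q(p.plane_id), q(atom), "%.3f" % p.esd])
    return doc.as_string()


def read_restraint_cif(text: str) -> RestraintDictionary:
    """Inverse of :func:`write_restraint_cif` (tolerant of column order)."""
    cs = gemmi.cif.as_string
    try:
        doc = gemmi.cif.read_string(text)
    except (ValueError, RuntimeError) as exc:
        raise ComponentError(f"malformed restraint CIF: {exc}") from exc
    if len(doc) == 0:
        raise ComponentError("restraint CIF contains no data block")
    block = doc[0]
    comp_id_val = block.find_value("_chem_comp.id")
    comp_id = cs(comp_id_val) if comp_id_val else block.name.removeprefix("comp_")
    variant_val = block.find_value("_chem_comp.variant")
    variant = VariantLabel(cs(variant_val)) if variant_val else VariantLabel.IN_SITU
    prov_val = block.find_value("_chem_comp.provenance")
    provenance = cs(prov_val) if prov_val else ""

    def require(table, col, what):
        if not table.has_column(col):
            raise ComponentError(f"restraint CIF missing mandatory column in {what}")

    bonds = []
    tb = block.find("_chem_comp_bond.",
                    ["atom_id_1", "atom_id_2", "?value_dist", "?value_dist_esd"])
    if len(tb):
        require(tb, 2, "_chem_comp_bond")
        require(tb, 3, "_chem_comp_bond")
    for row in tb:
        bonds.append(
            BondRestraint(cs(row[0]), cs(row[1]), float(row[2]), float(row[3]))
        )

    angles = []
    ta = block.find(
        "_chem_comp_angle.",
        ["atom_id_1", "atom_id_2", "atom_id_3", "?value_angle", "?value_angle_esd"],
    )
    if len(ta):
        require(ta, 3, "_chem_comp_angle")
        require(ta, 4, "_chem_comp_angle")
    for row in ta:
        angles.append(
            AngleRestraint(cs(row[0]), cs(row[1]), cs(row[2]),
                           float(row[3]), float(row[4]))
        )

    torsions: list[TorsionRestraint] = []
    tor_rows: dict[str, list] = {}
    tor_order: list[str] = []
    tt = block.find(
        "_chem_comp_tor.",
        ["id", "atom_id_1", "atom_id_2", "atom_id_3", "atom_id_4",
         "?value_angle", "?value_angle_esd", "?period"],
    )
    if len(tt):
        for col in (5, 6, 7):
            require(tt, col, "_chem_comp_tor")
    for row in tt:
        tid = cs(row[0])
        if tid not in tor_rows:
            tor_order.append(tid)
        tor_rows.setdefault(tid, []).append(
            (cs(row[1]), cs(row[2]), cs(row[3]), cs(row[4]),
             float(row[5]), float(row[6]), int(row[7]))
        )
    for tid in tor_order:
        rows = tor_rows[tid]
        a1, a2, a3, a4, v, esd, period = rows[0]
        if period == 0 or len(rows) > 1:
            torsions.append(
                TorsionRestraint(tid, a1, a2, a3, a4, rows[0][4], esd, 0,
                                 tuple(r[4] for r in rows))
            )
        else:
            torsions.append(TorsionRestraint(tid, a1, a2, a3, a4, v, esd, period))

    chirality = []
    tc = block.find(
        "_chem_comp_chir.",
        ["atom_id_centre", "atom_id_1", "atom_id_2", "atom_id_3", "?volume_sign"],
    )
    if len(tc):
        require(tc, 4, "_chem_comp_chir")
    for row in tc:
        raw = cs(row[4]).lower()
        if raw not in _SIGN_FROM_CIF:
            raise ComponentError(f"unknown chirality volume_sign {raw!r}")
        chirality.append(
            ChiralityRestraint(cs(row[0]), cs(row[1]), cs(row[2]), cs(row[3]),
                               _SIGN_FROM_CIF[raw])
        )

    planes: list[PlaneRestraint] = []
    plane_atoms: dict[str, list[str]] = {}
    plane_esd: dict[str, float] = {}
    plane_order: list[str] = []
    tp = block.find("_chem_comp_plane_atom.", ["plane_id", "atom_id", "?dist_esd"])
    if len(tp):
        require(tp, 2, "_chem_comp_plane_atom")
    for row in tp:
        pid = cs(row[0])
        if pid not in plane_atoms:
            plane_order.append(pid)
        plane_atoms.setdefault(pid, []).append(cs(row[1]))
        plane_esd[pid] = float(row[2])
    for pid in plane_order:
        planes.append(PlaneRestraint(pid, frozenset(plane_atoms[pid]), plane_esd[pid]))

    return RestraintDictionary(
        component_id=comp_id,
        variant_label=variant,
        bonds=bonds,
        angles=angles,
        torsions=torsions,
        chirality=chirality,
        planes=planes,
        provenance=provenance,
    )
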