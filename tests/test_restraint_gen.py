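"""Internal-coordinate measurement, restraint assignment, serialization."""

import math

import numpy as np
import pytest

from restraintforge.component_io import Atom, Bond, Component, ComponentError
from restraintforge.chemgraph import VariantLabel
from restraintforge.restraint_gen import (
    ChiralitySign,
    EsdPolicy,
    TorsionRestraint,
    assign_chirality,
    assign_torsion_restraints,
    build_dictionary,
    detect_planes,
    measure_geometry,
    perceive,
    read_restraint_cif,
    torsion_distance,
    wrap_angle,
    write_restraint_cif,
)
from restraintforge.validation import ReferenceEntry, ReferenceTable, type_key

from conftest import ALL_KINDS, build_fixture, dictionary_for


# --- independent brute-force measurement oracle ----------------------------

def oracle_length(p, q):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def oracle_angle(p, q, r):
    # law of cosines, no vector library
    a = oracle_length(q, r)
    b = oracle_length(p, q)
    c = oracle_length(p, r)
    return math.degrees(math.acos((a * a + b * b - c * c) / (2 * a * b)))


def oracle_dihedral(p1, p2, p3, p4):
    # project p1 and p4 onto the plane normal to p2-p3, measure the
    # signed rotation between the projections
    p1, p2, p3, p4 = (np.asarray(x, float) for x in (p1, p2, p3, p4))
    axis = (p3 - p2) / np.linalg.norm(p3 - p2)
    u = (p1 - p2) - np.dot(p1 - p2, axis) * axis
    v = (p4 - p3) - np.dot(p4 - p3, axis) * axis
    cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    sin = np.dot(np.cross(u, v), axis) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.atan2(sin, cos))


@pytest.mark.parametrize("kind", ALL_KINDS)
def test_measurement_matches_brute_force(kind):
    comp = build_fixture(kind, n=4 if kind == "alkane_chain" else 1)
    graph = perceive(comp)
    measured = measure_geometry(comp, graph)
    xyz = comp.coords
    for b in measured.bonds:
        assert b.length == pytest.approx(
            oracle_length(xyz[b.atom1], xyz[b.atom2]), abs=1e-9
        )
    for a in measured.angles:
        assert a.degrees == pytest.approx(
            oracle_angle(xyz[a.atom1], xyz[a.atom2], xyz[a.atom3]), abs=1e-9
        )
    for t in measured.torsions:
        expected = oracle_dihedral(
            xyz[t.atom1], xyz[t.atom2], xyz[t.atom3], xyz[t.atom4]
        )
        assert torsion_distance(t.degrees, expected) == pytest.approx(0, abs=1e-9)


def test_simple_geometry_values():
    comp = Component(
        id="TRI",
        atoms=[Atom("A1", "C"), Atom("A2", "C"), Atom("A3", "C")],
        bonds=[Bond("A1", "A2"), Bond("A2", "A3")],
        coords={"A1": (0, 0, 0), "A2": (1.5, 0, 0), "A3": (1.5, 1.0, 0)},
    )
    graph = perceive(comp)
    measured = measure_geometry(comp, graph)
    assert measured.bonds[0].length == pytest.approx(1.5)
    (angle,) = measured.angles
    assert angle.degrees == pytest.approx(90.0)


def test_butane_trans_central_torsion():
    comp = build_fixture("alkane_chain", n=4)
    graph = perceive(comp)
    measured = measure_geometry(comp, graph)
    central = [t for t in measured.torsions
               if {t.atom1, t.atom2, t.atom3, t.atom4} == {"C1", "C2", "C3", "C4"}]
    assert central and abs(central[0].degrees) == pytest.approx(180.0, abs=1e-6)


def test_missing_coordinates_error(acetic_acid):
    from dataclasses import replace

    graph = perceive(acetic_acid)
    nocoords = replace(acetic_acid, coords=None)
    with pytest.raises(ComponentError, match="no coordinates"):
        measure_geometry(nocoords, graph)


def test_overlapping_atoms_error():
    comp = Component(
        id="OVR",
        atoms=[Atom("C1", "C"), Atom("C2", "C")],
        bonds=[Bond("C1", "C2")],
        coords={"C1": (0, 0, 0), "C2": (0.01, 0, 0)},
    )
    with pytest.raises(ComponentError, match="overlap"):
        measure_geometry(comp, perceive(comp))


# --- torsion assignment ----------------------------------------------------

def torsions_by_central_bond(torsions):
    by_bond = {}
    for t in torsions:
        by_bond.setdefault(frozenset((t.atom2, t.atom3)), []).append(t)
    return by_bond


def test_ethane_threefold(ethane):
    _, graph, measured = dictionary_for(ethane)
    torsions = assign_torsion_restraints(graph, measured)
    cc = [t for t in torsions if {t.atom2, t.atom3} == {"C1", "C2"}]
    assert cc and all(t.period == 3 for t in cc)
    # staggered conformation: representative ideal ~ +-60 or 180
    rep = cc[0]
    assert min(
        torsion_distance(rep.ideal, v) for v in (60.0, -60.0, 180.0)
    ) == pytest.approx(0, abs=1e-5)


def test_ethene_twofold_snapped():
    comp = Component(
        id="ETE",
        atoms=[Atom("C1", "C"), Atom("C2", "C"),
               Atom("H1", "H"), Atom("H2", "H"), Atom("H3", "H"), Atom("H4", "H")],
        bonds=[Bond("C1", "C2", order=__import__("restraintforge").BondOrder.DOUBLE),
               Bond("C1", "H1"), Bond("C1", "H2"),
               Bond("C2", "H3"), Bond("C2", "H4")],
        coords={
            "C1": (0, 0, 0), "C2": (1.33, 0, 0),
            "H1": (-0.55, 0.94, 0), "H2": (-0.55, -0.94, 0),
            "H3": (1.88, 0.94, 0), "H4": (1.88, -0.94, 0),
        },
    )
    _, graph, measured = dictionary_for(comp)
    torsions = assign_torsion_restraints(graph, measured)
    cc = [t for t in torsions if {t.atom2, t.atom3} == {"C1", "C2"}]
    assert cc and all(t.period == 2 for t in cc)
    assert all(t.ideal in (0.0, 180.0) for t in cc)


def test_benzene_ring_bonds_no_representative_torsion(benzene):
    _, graph, measured = dictionary_for(benzene)
    torsions = assign_torsion_restraints(graph, measured)
    # only hydrogen-positioning torsions are allowed across ring bonds
    for t in torsions:
        assert t.atom1.startswith("H") or t.atom4.startswith("H")
    # and each H is positioned
    hs = {f"H{i}" for i in range(1, 7)}
    positioned = {t.atom1 for t in torsions} | {t.atom4 for t in torsions}
    assert hs <= positioned


def test_one_representative_torsion_per_eligible_bond(phosphate):
    dictionary, graph, measured = dictionary_for(phosphate)
    heavy_torsions = [
        t for t in dictionary.torsions
        if not (graph.elements[t.atom1] in ("H", "D")
                or graph.elements[t.atom4] in ("H", "D"))
    ]
    bonds = [frozenset((t.atom2, t.atom3)) for t in heavy_torsions]
    assert len(bonds) == len(set(bonds))


def test_sp_central_bonds_unrestrained():
    comp = Component(
        id="PRN",  # propyne-like: H3C-C#CH
        atoms=[Atom("C1", "C"), Atom("C2", "C"), Atom("C3", "C"),
               Atom("H1", "H"), Atom("H2", "H"), Atom("H3", "H"), Atom("H4", "H")],
        bonds=[Bond("C1", "C2"),
               Bond("C2", "C3", order=__import__("restraintforge").BondOrder.TRIPLE),
               Bond("C1", "H1"), Bond("C1", "H2"), Bond("C1", "H3"),
               Bond("C3", "H4")],
        coords={
            "C1": (0, 0, 0), "C2": (1.46, 0, 0), "C3": (2.66, 0, 0),
            "H1": (-0.36, 1.03, 0), "H2": (-0.36, -0.51, 0.89),
            "H3": (-0.36, -0.51, -0.89), "H4": (3.72, 0, 0),
        },
    )
    graph = perceive(comp)
    measured = measure_geometry(comp, graph)
    torsions = assign_torsion_restraints(graph, measured)
    assert all({t.atom2, t.atom3} != {"C2", "C3"} for t in torsions)
    assert all({t.atom2, t.atom3} != {"C1", "C2"} for t in torsions)


# --- planes ----------------------------------------------------------------

def test_benzene_single_twelve_atom_plane(benzene):
    graph = perceive(benzene)
    planes = detect_planes(graph, benzene)
    assert len(planes) == 1
    assert len(planes[0].atoms) == 12


def test_methane_no_planes(methane):
    graph = perceive(methane)
    assert detect_planes(graph, methane) == []


def test_acetate_carboxylate_plane(acetate):
    graph = perceive(acetate)
    planes = detect_planes(graph, acetate)
    assert len(planes) == 1
    assert planes[0].atoms == frozenset({"C1", "C2", "O1", "O2"})


# --- chirality -------------------------------------------------------------

def test_alanine_ca_chirality(alanine):
    graph = perceive(alanine)
    restraints = assign_chirality(graph, alanine)
    centers = {c.center: c for c in restraints}
    assert "CA" in centers
    assert centers["CA"].sign in (ChiralitySign.POSITIVE, ChiralitySign.NEGATIVE)


def test_mirror_flips_chirality_sign(alanine):
    graph = perceive(alanine)
    original = assign_chirality(graph, alanine)
    mirrored = alanine.with_coords(
        {n: (-x, y, z) for n, (x, y, z) in alanine.coords.items()}
    )
    flipped = assign_chirality(graph, mirrored)
    assert len(original) == len(flipped) > 0
    flip = {ChiralitySign.POSITIVE: ChiralitySign.NEGATIVE,
            ChiralitySign.NEGATIVE: ChiralitySign.POSITIVE,
            ChiralitySign.BOTH: ChiralitySign.BOTH}
    for o, f in zip(original, flipped):
        assert (o.center, o.neighbor1, o.neighbor2, o.neighbor3) == (
            f.center, f.neighbor1, f.neighbor2, f.neighbor3
        )
        assert f.sign is flip[o.sign]


def test_planar_sp2_carbon_has_no_chirality(benzene, acetate):
    for comp in (benzene, acetate):
        graph = perceive(comp)
        assert assign_chirality(graph, comp) == []


# --- e.s.d. policy ---------------------------------------------------------

def test_esd_doubling_and_floor(ethane):
    graph = perceive(ethane)
    measured = measure_geometry(ethane, graph)
    cc_key = type_key(("bond", "C1", "C2"), graph)
    ch_key = type_key(("bond", "C1", "H1"), graph)
    table = ReferenceTable(
        bond_entries={
            cc_key: ReferenceEntry(1.53, 0.009, 100),
            ch_key: ReferenceEntry(1.09, 0.001, 3),  # below the 0.005 floor
        }
    )
    dictionary = build_dictionary(ethane, measured, EsdPolicy(), table, graph=graph)
    by_pair = {frozenset((b.atom1, b.atom2)): b for b in dictionary.bonds}
    assert by_pair[frozenset(("C1", "C2"))].esd == pytest.approx(0.018)
    # floored to 0.005 then doubled
    assert by_pair[frozenset(("C1", "H1"))].esd == pytest.approx(0.010)


def test_esd_default_when_type_unknown(ethane):
    graph = perceive(ethane)
    measured = measure_geometry(ethane, graph)
    dictionary = build_dictionary(
        ethane, measured, EsdPolicy(), ReferenceTable(), graph=graph
    )
    assert all(b.esd == pytest.approx(0.02) for b in dictionary.bonds)
    assert all(a.esd == pytest.approx(1.5) for a in dictionary.angles)


@pytest.mark.parametrize("kind", ALL_KINDS)
def test_hydrogen_restraint_completeness(kind):
    comp = build_fixture(kind, n=3 if kind == "alkane_chain" else 1)
    dictionary, graph, _ = dictionary_for(comp)
    assert dictionary.check_hydrogen_completeness(comp, graph) == []
    for a in comp.atoms:
        if not a.is_hydrogen:
            continue
        assert any(a.name in (b.atom1, b.atom2) for b in dictionary.bonds)
        assert any(a.name in (x.atom1, x.atom2, x.atom3) for x in dictionary.angles)


# --- serialization ---------------------------------------------------------

def assert_dictionaries_equal(d1, d2, tol=1e-3):
    assert d1.component_id == d2.component_id
    assert d1.variant_label == d2.variant_label
    for b1, b2 in zip(d1.bonds, d2.bonds, strict=True):
        assert (b1.atom1, b1.atom2) == (b2.atom1, b2.atom2)
        assert b1.ideal == pytest.approx(b2.ideal, abs=tol)
        assert b1.esd == pytest.approx(b2.esd, abs=tol)
    for a1, a2 in zip(d1.angles, d2.angles, strict=True):
        assert (a1.atom1, a1.atom2, a1.atom3) == (a2.atom1, a2.atom2, a2.atom3)
        assert a1.ideal == pytest.approx(a2.ideal, abs=tol)
    for t1, t2 in zip(d1.torsions, d2.torsions, strict=True):
        assert (t1.atom1, t1.atom2, t1.atom3, t1.atom4) == (
            t2.atom1, t2.atom2, t2.atom3, t2.atom4)
        assert t1.period == t2.period
        if t1.alt_ideals is None:
            assert t2.alt_ideals is None
            assert t1.ideal == pytest.approx(t2.ideal, abs=tol)
        else:
            assert t2.alt_ideals == pytest.approx(t1.alt_ideals, abs=tol)
    assert [c.center for c in d1.chirality] == [c.center for c in d2.chirality]
    assert [c.sign for c in d1.chirality] == [c.sign for c in d2.chirality]
    for p1, p2 in zip(d1.planes, d2.planes, strict=True):
        assert p1.atoms == p2.atoms


@pytest.mark.parametrize("kind", ALL_KINDS)
def test_restraint_cif_round_trip(kind):
    comp = build_fixture(kind, n=3 if kind == "alkane_chain" else 1)
    dictionary, _, _ = dictionary_for(comp)
    text = write_restraint_cif(dictionary)
    back = read_restraint_cif(text)
    assert_dictionaries_equal(dictionary, back)
    # write . read . write is stable
    assert write_restraint_cif(back) == text


def test_discrete_torsion_round_trip(ethane):
    dictionary, _, _ = dictionary_for(ethane)
    discrete = TorsionRestraint(
        "tor_alt", "H1", "C1", "C2", "H4", -90.0, 10.0, 0,
        alt_ideals=(0.0, 90.0, -90.0),
    )
    dictionary.torsions.append(discrete)
    back = read_restraint_cif(write_restraint_cif(dictionary))
    alt = [t for t in back.torsions if t.alt_ideals is not None]
    assert len(alt) == 1
    assert alt[0].period == 0
    assert alt[0].alt_ideals == pytest.approx((0.0, 90.0, -90.0))


def test_empty_chirality_category_omitted(ethane):
    dictionary, _, _ = dictionary_for(ethane)
    text = write_restraint_cif(dictionary)
    assert "_chem_comp_chir" not in text
    assert read_restraint_cif(text).chirality == []


def test_bond_only_hand_written_file():
    text = """\
data_comp_MIN
_chem_comp.id MIN
loop_
_chem_comp_bond.atom_id_1
_chem_comp_bond.atom_id_2
_chem_comp_bond.value_dist
_chem_comp_bond.value_dist_esd
C1 C2 1.530 0.020
"""
    d = read_restraint_cif(text)
    assert len(d.bonds) == 1 and d.angles == [] and d.torsions == []
    assert d.bonds[0].ideal == pytest.approx(1.53)


def test_nonpositive_esd_rejected():
    text = """\
data_comp_MIN
loop_
_chem_comp_bond.atom_id_1
_chem_comp_bond.atom_id_2
_chem_comp_bond.value_dist
_chem_comp_bond.value_dist_esd
C1 C2 1.530 0.000
"""
    with pytest.raises(ComponentError, match="esd"):
        read_restraint_cif(text)


def test_missing_mandatory_column_rejected():
    text = """\
data_comp_MIN
loop_
_chem_comp_bond.atom_id_1
_chem_comp_bond.atom_id_2
_chem_comp_bond.value_dist
C1 C2 1.530
"""
    with pytest.raises(ComponentError, match="mandatory"):
        read_restraint_cif(text)


def test_wrap_angle_range():
    for deg in (-720.5, -180.0, -179.999, 0.0, 180.0, 180.001, 359.0, 721.0):
        w = wrap_angle(deg)
        assert -180.0 < w <= 180.0
        assert math.isclose(math.cos(math.radians(w)), math.cos(math.radians(deg)),
                            abs_tol=1e-9)
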