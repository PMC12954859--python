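"""Z-scores, s.d. floors, maximum-Z classification, reference tables."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from restraintforge.component_io import ComponentError
from restraintforge.restraint_gen import (
    MeasuredAngle,
    MeasuredBond,
    MeasuredGeometry,
    perceive,
    measure_geometry,
)
from restraintforge.validation import (
    Classification,
    ReferenceEntry,
    ReferenceTable,
    ValidationConfig,
    ValidationFlag,
    apply_sd_floor,
    classify,
    read_reference_table,
    type_key,
    validate_geometry,
    write_reference_table,
    zscore,
)
from restraintforge import fixtures as fx

from conftest import build_fixture, dictionary_for


# --- zscore ----------------------------------------------------------------

def test_zscore_basic_cases():
    assert zscore(1.53, 1.53, 0.01) == 0.0
    assert zscore(1.55, 1.53, 0.01) == pytest.approx(2.0)
    with pytest.raises(ComponentError):
        zscore(1.5, 1.5, 0.0)


def test_phosphoester_bond_outlier_exceeds_satisfactory_band():
    # a P-O bond stretched to 1.681 A against a tight reference
    # (1.623 +- 0.009 A) sits beyond the satisfactory cutoff of 6 ...
    z = zscore(1.681, 1.623, 0.009)
    assert z == pytest.approx(6.4444, abs=1e-3)
    assert z > 6.0
    assert classify(z)[0] is Classification.FAIL


def test_same_bond_against_broad_organometal_reference_passes():
    # ... but against the broader organometal-inclusive spread
    # (1.608 +- 0.043 A) it is well inside the passing range
    z = zscore(1.681, 1.608, 0.043)
    assert z == pytest.approx(1.6977, abs=1e-3)
    assert z < 6.0
    assert classify(z)[0] is Classification.AWESOME


def test_longer_bond_still_fails():
    z = zscore(1.702, 1.623, 0.009)
    assert z == pytest.approx(8.7778, abs=1e-3)
    assert classify(z)[0] is Classification.FAIL


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    observed=st.floats(0.5, 3.0),
    ideal=st.floats(0.5, 3.0),
    sd=st.floats(1e-4, 0.5),
    scale=st.floats(0.1, 10.0),
)
def test_zscore_scale_equivariance(observed, ideal, sd, scale):
    z1 = zscore(observed, ideal, sd)
    z2 = zscore(observed * scale, ideal * scale, sd * scale)
    assert z2 == pytest.approx(z1, rel=1e-9, abs=1e-9)


# --- floors ----------------------------------------------------------------

@pytest.mark.parametrize(
    "sd,kind,expected,floored",
    [
        (0.0, "bond", 0.005, True),
        (0.004, "bond", 0.005, True),
        (0.02, "bond", 0.02, False),
        (0.5, "angle", 0.75, True),
        (0.0, "angle", 0.75, True),
        (1.2, "angle", 1.2, False),
    ],
)
def test_sd_floor(sd, kind, expected, floored):
    got, got_floored = apply_sd_floor(sd, kind)
    assert got == pytest.approx(expected)
    assert got_floored is floored


# --- classification --------------------------------------------------------

@pytest.mark.parametrize(
    "z,expected",
    [
        (0.0, Classification.AWESOME),
        (1.2, Classification.AWESOME),
        (1.999999, Classification.AWESOME),
        (2.0, Classification.SUPERIOR),
        (3.9, Classification.SUPERIOR),
        (4.0, Classification.SATISFACTORY),
        (5.99, Classification.SATISFACTORY),
        (6.0, Classification.FAIL),
        (6.44, Classification.FAIL),
        (100.0, Classification.FAIL),
    ],
)
def test_classification_bands_strict(z, expected):
    cls, flags = classify(z)
    assert cls is expected
    assert flags == frozenset()


def test_floor_pass_overrides_band():
    cls, flags = classify(1.2, used_floor=True)
    assert cls is Classification.SATISFACTORY
    assert flags == frozenset({ValidationFlag.REASONABLE_STD})
    # floors never rescue an outright fail
    cls, flags = classify(7.0, used_floor=True)
    assert cls is Classification.FAIL


def test_side_chain_flag_attached():
    cls, flags = classify(1.0, side_chain=True)
    assert cls is Classification.AWESOME
    assert flags == frozenset({ValidationFlag.SIDE_CHAIN})


def test_threshold_exactness_by_bisection():
    """The classification changes exactly at 2, 4 and 6."""
    for boundary, lower in ((2.0, Classification.AWESOME),
                            (4.0, Classification.SUPERIOR),
                            (6.0, Classification.SATISFACTORY)):
        lo, hi = boundary - 1.0, boundary + 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if classify(mid)[0] is lower:
                lo = mid
            else:
                hi = mid
        assert hi == pytest.approx(boundary, abs=1e-12)
        # boundary itself belongs to the upper class (strict less-than)
        assert classify(boundary)[0] is not lower


# --- type keys -------------------------------------------------------------

def test_type_key_symmetry_and_tokens(ethane, benzene):
    ge = perceive(ethane)
    assert type_key(("bond", "C1", "C2"), ge) == "C.sp3-C.sp3"
    assert type_key(("bond", "C2", "C1"), ge) == "C.sp3-C.sp3"
    gb = perceive(benzene)
    key = type_key(("angle", "C1", "C2", "C3"), gb)
    assert key == "C.sp2.ar|C.sp2.ar|C.sp2.ar"
    assert key == type_key(("angle", "C3", "C2", "C1"), gb)


def test_type_key_distinguishes_hybridization(acetic_acid):
    g = perceive(acetic_acid)
    assert type_key(("bond", "C1", "C2"), g) == "C.sp2-C.sp3"
    assert type_key(("bond", "C2", "O1"), g) != type_key(("bond", "C2", "O2"), g)


# --- validate_geometry -----------------------------------------------------

def make_simple(geom_bonds, geom_angles=()):
    bonds = [MeasuredBond(a, b, v) for a, b, v in geom_bonds]
    angles = [MeasuredAngle(a, b, c, v) for a, b, c, v in geom_angles]
    return MeasuredGeometry(bonds, angles, [], [], [])


def test_exact_geometry_is_awesome(ethane):
    dictionary, graph, measured = dictionary_for(ethane)
    table = fx.make_reference_table(dictionary, graph)
    report = validate_geometry(measured, graph, table)
    assert report.classification is Classification.AWESOME
    assert report.max_abs_z == pytest.approx(0.0)
    assert report.n_unmatched == 0
    assert report.rmsz_bonds == pytest.approx(0.0)


def test_single_outlier_fails_both_passes(ethane):
    dictionary, graph, measured = dictionary_for(ethane)
    table = fx.make_reference_table(dictionary, graph, sd_bond=0.009)
    cc_key = type_key(("bond", "C1", "C2"), graph)
    # displace the reference ideal so the C-C bond scores like a
    # severely stretched bond: |1.53 - ideal| / 0.009 > 6
    table.bond_entries[cc_key] = ReferenceEntry(1.53 - 0.058, 0.009, 50)
    report = validate_geometry(measured, graph, table)
    assert report.classification is Classification.FAIL
    assert report.max_abs_z == pytest.approx(0.058 / 0.009, rel=1e-6)
    # the floors cannot rescue it: 0.009 is above the bond floor
    assert not report.used_floor


def test_broader_sd_passes(ethane):
    dictionary, graph, measured = dictionary_for(ethane)
    table = fx.make_reference_table(dictionary, graph, sd_bond=0.043)
    cc_key = type_key(("bond", "C1", "C2"), graph)
    table.bond_entries[cc_key] = ReferenceEntry(1.53 - 0.073, 0.043, 50)
    report = validate_geometry(measured, graph, table)
    assert report.max_abs_z == pytest.approx(0.073 / 0.043, rel=1e-6)
    assert report.classification is Classification.AWESOME


def test_unmatched_terms_counted_not_failed(ethane):
    dictionary, graph, measured = dictionary_for(ethane)
    table = fx.make_reference_table(dictionary, graph)
    cc_key = type_key(("bond", "C1", "C2"), graph)
    del table.bond_entries[cc_key]
    report = validate_geometry(measured, graph, table)
    assert report.classification is Classification.AWESOME
    assert report.n_unmatched == 1


def test_empty_table_fails(ethane):
    _, graph, measured = dictionary_for(ethane)
    report = validate_geometry(measured, graph, ReferenceTable())
    assert report.classification is Classification.FAIL
    assert report.n_unmatched == len(report.scores)


def test_zero_sd_exercises_floor_and_reasonable_std(ethane):
    dictionary, graph, measured = dictionary_for(ethane)
    cc_key = type_key(("bond", "C1", "C2"), graph)
    table = fx.make_reference_table(dictionary, graph, sd_overrides={cc_key: 0.0})
    report = validate_geometry(measured, graph, table)
    assert report.classification is Classification.SATISFACTORY
    assert ValidationFlag.REASONABLE_STD in report.flags
    assert report.used_floor


def test_pass2_equals_pass1_when_all_sd_above_floor(ethane):
    dictionary, graph, measured = dictionary_for(ethane)
    table = fx.make_reference_table(dictionary, graph, sd_bond=0.02, sd_angle=1.5)
    report = validate_geometry(measured, graph, table)
    assert not report.used_floor
    assert not any(s.floored for s in report.scores)


def test_monotonicity_worse_observation_never_improves(ethane):
    dictionary, graph, measured = dictionary_for(ethane)
    table = fx.make_reference_table(dictionary, graph, sd_bond=0.01)
    ranks = []
    for stretch in (0.0, 0.015, 0.035, 0.055, 0.08):
        bonds = [
            MeasuredBond(b.atom1, b.atom2,
                         b.length + (stretch if (b.atom1, b.atom2) == ("C1", "C2")
                                     else 0.0))
            for b in measured.bonds
        ]
        geom = MeasuredGeometry(bonds, measured.angles, [], [], [])
        ranks.append(validate_geometry(geom, graph, table).classification.rank)
    assert ranks == sorted(ranks)
    assert ranks[0] == Classification.AWESOME.rank
    assert ranks[-1] == Classification.FAIL.rank


def test_rmsz_matches_brute_force(acetic_acid):
    dictionary, graph, measured = dictionary_for(acetic_acid)
    table = fx.make_reference_table(dictionary, graph, bias=0.005)
    report = validate_geometry(measured, graph, table)
    for kind, reported in (("bond", report.rmsz_bonds),
                           ("angle", report.rmsz_angles)):
        zs = [s.z for s in report.scores if s.matched and s.kind == kind]
        assert reported == pytest.approx(
            math.sqrt(sum(z * z for z in zs) / len(zs)), rel=1e-12
        )


def test_side_chain_only_excludes_backbone_terms(alanine):
    comp = alanine
    graph = perceive(comp)
    measured = measure_geometry(comp, graph)
    dictionary, _, _ = dictionary_for(comp)
    table = fx.make_reference_table(dictionary, graph)
    full = validate_geometry(measured, graph, table, side_chain_only=False)
    side = validate_geometry(measured, graph, table, side_chain_only=True)
    assert len(side.scores) < len(full.scores)
    assert ValidationFlag.SIDE_CHAIN in side.flags
    backbone = {"N", "CA", "C", "O", "OXT", "H", "H2", "HA", "HXT"}
    for s in side.scores:
        assert not set(s.atoms) <= backbone


# --- reference table I/O ---------------------------------------------------

def test_read_reference_table_two_rows():
    text = "kind\ttype_key\tideal\tsd\tn_obs\nbond\tC.sp3-C.sp3\t1.53\t0.01\t100\nangle\tA|B|C\t109.5\t1.2\t55\n"
    table = read_reference_table(text)
    assert len(table.bond_entries) == 1 and len(table.angle_entries) == 1
    assert table.bond_entries["C.sp3-C.sp3"].n_obs == 100


def test_read_reference_table_csv_and_zero_sd():
    text = "kind,type_key,ideal,sd,n_obs\nbond,K1,1.5,0.0,1\n"
    table = read_reference_table(text)
    assert table.bond_entries["K1"].sd == 0.0


def test_read_reference_table_empty_and_negative():
    assert len(read_reference_table("")) == 0
    with pytest.raises(ComponentError, match="negative"):
        read_reference_table("kind,type_key,ideal,sd,n_obs\nbond,K1,1.5,-0.1,5\n")


def test_reference_table_round_trip(ethane):
    dictionary, graph, _ = dictionary_for(ethane)
    table = fx.make_reference_table(dictionary, graph)
    back = read_reference_table(write_reference_table(table))
    for key, e in table.bond_entries.items():
        b = back.bond_entries[key]
        assert b.ideal == pytest.approx(e.ideal, abs=1e-6)
        assert b.sd == pytest.approx(e.sd, abs=1e-6)
        assert b.n_obs == e.n_obs
    assert set(back.angle_entries) == set(table.angle_entries)


def test_duplicate_key_last_wins():
    text = ("kind,type_key,ideal,sd,n_obs\n"
            "bond,K1,1.5,0.01,5\n"
            "bond,K1,1.6,0.02,9\n")
    table = read_reference_table(text)
    assert table.bond_entries["K1"].ideal == pytest.approx(1.6)
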