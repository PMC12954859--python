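"""Z-score validation of component geometries against a reference table.

The reference table maps a bond or angle *type key* (element,
hybridization and ring context of the atoms involved) to an ideal value,
a standard deviation and an observation count — the shape of output
produced by small-molecule knowledge bases mined from experimental
crystal structures.  Each measured bond and angle is scored as

    Z = |observed - ideal| / s.d.

and the geometry is classified from the maximum |Z| over all matched
terms: < 2 "awesome", < 4 "superior", < 6 "satisfactory", otherwise
fail.  Reference spreads can be unrealistically small (a single
observation can even give s.d. = 0), so a second scoring pass applies
conservative minimum spreads (0.005 A for bonds, 0.75 deg for angles); a
geometry that only passes with those floors is classified "satisfactory
(reasonable std)" regardless of its Z value.  Side-chain-only scoring,
used for polymerizable components whose backbone ideals are maintained
elsewhere, tags the verdict with a "(side chain)" flag.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from io import StringIO
from typing import Iterable, Literal, Optional

import pandas as pd

from .chemgraph import BACKBONE_ATOM_NAMES, MolecularGraph, VariantLabel
from .component_io import Component, ComponentError
from .restraint_gen import MeasuredAngle, MeasuredBond, MeasuredGeometry

__all__ = [
    "ReferenceEntry",
    "ReferenceTable",
    "TermScore",
    "Classification",
    "ValidationFlag",
    "ZscoreReport",
    "ValidationConfig",
    "type_key",
    "zscore",
    "apply_sd_floor",
    "validate_geometry",
    "classify",
    "read_reference_table",
    "write_reference_table",
]


class Classification(str, Enum):
    AWESOME = "awesome"
    SUPERIOR = "superior"
    SATISFACTORY = "satisfactory"
    FAIL = "fail"

    @property
    def rank(self) -> int:
        return ("awesome", "superior", "satisfactory", "fail").index(self.value)


class ValidationFlag(str, Enum):
    REASONABLE_STD = "reasonable_std"
    SIDE_CHAIN = "side_chain"


@dataclass(frozen=True)
class ReferenceEntry:
    ideal: float
    sd: float
    n_obs: int

    def __post_init__(self):
        if self.sd < 0:
            raise ComponentError("reference s.d. must be >= 0")
        if self.n_obs < 1:
            raise ComponentError("reference n_obs must be >= 1")


@dataclass
class ReferenceTable:
    bond_entries: dict[str, ReferenceEntry] = field(default_factory=dict)
    angle_entries: dict[str, ReferenceEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.bond_entries) + len(self.angle_entries)


@dataclass(frozen=True)
class ValidationConfig:
    z_awesome: float = 2.0
    z_superior: float = 4.0
    z_satisfactory: float = 6.0
    bond_floor: float = 0.005  # Angstrom
    angle_floor: float = 0.75  # degrees
    side_chain_backbone_names: frozenset = BACKBONE_ATOM_NAMES

    def __post_init__(self):
        if not 0 < self.z_awesome < self.z_superior < self.z_satisfactory:
            raise ComponentError("classification thresholds must increase")
        if self.bond_floor <= 0 or self.angle_floor <= 0:
            raise ComponentError("s.d. floors must be positive")


@dataclass(frozen=True)
class TermScore:
    kind: Literal["bond", "angle"]
    atoms: tuple[str, ...]
    observed: float
    ideal: Optional[float]
    sd_used: Optional[float]
    floored: bool
    z: Optional[float]
    matched: bool
    key: str = ""


@dataclass
class ZscoreReport:
    component_id: str
    variant_label: VariantLabel
    scores: list[TermScore]
    max_abs_z: float
    rmsz_bonds: float
    rmsz_angles: float
    n_unmatched: int
    classification: Classification
    flags: frozenset
    used_floor: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "component_id": self.component_id,
                "variant": self.variant_label.value,
                "classification": self.classification.value,
                "flags": sorted(f.value for f in self.flags),
                "max_abs_z": self.max_abs_z,
                "rmsz_bonds": self.rmsz_bonds,
                "rmsz_angles": self.rmsz_angles,
                "n_unmatched": self.n_unmatched,
                "scores": [
                    {
                        "kind": s.kind,
                        "atoms": list(s.atoms),
                        "observed": s.observed,
                        "ideal": s.ideal,
                        "sd_used": s.sd_used,
                        "floored": s.floored,
                        "z": s.z,
                        "matched": s.matched,
                        "key": s.key,
                    }
                    for s in self.scores
                ],
            },
            indent=1,
        )

    def summary_text(self) -> str:
        """Human-readable summary listing every term with |Z| > 2."""
        flags = "".join(f" ({f.value})" for f in sorted(self.flags, key=lambda f: f.value))
        lines = [
            f"{self.component_id} [{self.variant_label.value}]: "
            f"{self.classification.value}{flags}  "
            f"max|Z|={self.max_abs_z:.2f} rmsZ(bonds)={self.rmsz_bonds:.2f} "
            f"rmsZ(angles)={self.rmsz_angles:.2f} unmatched={self.n_unmatched}"
        ]
        for s in self.scores:
            if s.matched and s.z is not None and s.z > 2.0:
                lines.append(
                    f"  {s.kind} {'-'.join(s.atoms)}: observed {s.observed:.4f} "
                    f"ideal {s.ideal:.4f} sd {s.sd_used:.4f} Z={s.z:.2f}"
                )
        return "\n".join(lines)


# ---------------------------------------------------------------------------

def _atom_token(name: str, graph: MolecularGraph) -> str:
    el = graph.elements[name]
    hyb = graph.hybridization.get(name)
    tok = f"{el}.{hyb.value}" if hyb is not None else el
    if name in graph.aromatic_atoms:
        tok += ".ar"
    elif graph.in_ring(name):
        tok += ".ring"
    return tok


def type_key(term: tuple, graph: MolecularGraph,
             component: Optional[Component] = None) -> str:
    """Canonical chemical-type key for a bond or angle term.

    Bonds: the two end tokens sorted, joined with "-".  Angles: the end
    tokens sorted around the fixed central token, joined with "|".  The
    key is invariant under reversal of the term's atom order.
    """
    kind = term[0]
    if kind == "bond":
        _, a, b = term
        t1, t2 = sorted((_atom_token(a, graph), _atom_token(b, graph)))
        return f"{t1}-{t2}"
    if kind == "angle":
        _, a, b, c = term
        t1, t3 = sorted((_atom_token(a, graph), _atom_token(c, graph)))
        return f"{t1}|{_atom_token(b, graph)}|{t3}"
    raise ComponentError(f"unknown term kind {kind!r}")


def zscore(observed: float, ideal: float, sd: float) -> float:
    """Standard-deviation distance of an observation from its ideal."""
    if sd <= 0:
        raise ComponentError("zscore undefined for sd <= 0; apply the floor first")
    return abs(observed - ideal) / sd


def apply_sd_floor(sd: float, kind: Literal["bond", "angle"],
                   config: Optional[ValidationConfig] = None) -> tuple[float, bool]:
    """Raise a reference s.d. to the conservative minimum for its kind."""
    config = config or ValidationConfig()
    if sd < 0:
        raise ComponentError("s.d. must be >= 0")
    floor = config.bond_floor if kind == "bond" else config.angle_floor
    return (max(sd, floor), sd < floor)


def classify(max_abs_z: float, used_floor: bool = False, side_chain: bool = False,
             config: Optional[ValidationConfig] = None
             ) -> tuple[Classification, frozenset]:
    """Map a maximum |Z| to the classification and flags.

    Thresholds are strict: a maximum |Z| of exactly 6.0 fails.  A
    geometry that needed floored s.d. values to pass is downgraded to
    "satisfactory" with the ``reasonable_std`` flag no matter its Z.
    """
    config = config or ValidationConfig()
    if max_abs_z < config.z_awesome:
        cls = Classification.AWESOME
    elif max_abs_z < config.z_superior:
        cls = Classification.SUPERIOR
    elif max_abs_z < config.z_satisfactory:
        cls = Classification.SATISFACTORY
    else:
        cls = Classification.FAIL
    flags = set()
    if used_floor and cls is not Classification.FAIL:
        cls = Classification.SATISFACTORY
        flags.add(ValidationFlag.REASONABLE_STD)
    if side_chain:
        flags.add(ValidationFlag.SIDE_CHAIN)
    return cls, frozenset(flags)


def _score_terms(
    terms: Iterable[tuple],
    graph: MolecularGraph,
    table: ReferenceTable,
    config: ValidationConfig,
    with_floor: bool,
) -> list[TermScore]:
    scores: list[TermScore] = []
    for kind, atoms, observed in terms:
        key = type_key((kind, *atoms), graph)
        entries = table.bond_entries if kind == "bond" else table.angle_entries
        entry = entries.get(key)
        if entry is None:
            scores.append(TermScore(kind, atoms, observed, None, None, False,
                                    None, False, key))
            continue
        sd, floored = entry.sd, False
        if with_floor:
            sd, floored = apply_sd_floor(sd, kind, config)
        if sd <= 0:
            # zero-spread reference with floors off: unmatched on this pass
            scores.append(TermScore(kind, atoms, observed, entry.ideal, None,
                                    False, None, False, key))
            continue
        scores.append(
            TermScore(kind, atoms, observed, entry.ideal, sd, floored,
                      zscore(observed, entry.ideal, sd), True, key)
        )
    return scores


def _rmsz(scores: list[TermScore], kind: str) -> float:
    zs = [s.z for s in scores if s.matched and s.kind == kind]
    if not zs:
        return 0.0
    return math.sqrt(sum(z * z for z in zs) / len(zs))


def validate_geometry(
    measured: MeasuredGeometry,
    graph: MolecularGraph,
    table: ReferenceTable,
    config: Optional[ValidationConfig] = None,
    side_chain_only: bool = False,
    component_id: str = "",
    variant_label: VariantLabel = VariantLabel.IN_SITU,
) -> ZscoreReport:
    """Score every bond and angle of a geometry and classify it.

    Terms without a reference entry are counted as unmatched and do not
    contribute to the verdict.  Scoring is two-pass: the first pass uses
    raw reference s.d. values (zero-s.d. terms unmatched); when that pass
    fails or left zero-s.d. terms unscored, a second pass applies the
    minimum-s.d. floors to every term and decides instead — passing only
    on that pass yields "satisfactory (reasonable std)".  With
    ``side_chain_only``, terms made up entirely of backbone atoms are
    excluded from scoring.
    """
    config = config or ValidationConfig()
    backbone = config.side_chain_backbone_names

    terms: list[tuple] = []
    for b in measured.bonds:
        atoms = (b.atom1, b.atom2)
        if side_chain_only and all(a in backbone for a in atoms):
            continue
        terms.append(("bond", atoms, b.length))
    for a in measured.angles:
        atoms = (a.atom1, a.atom2, a.atom3)
        if side_chain_only and all(x in backbone for x in atoms):
            continue
        terms.append(("angle", atoms, a.degrees))

    def build(scores: list[TermScore], used_floor: bool) -> ZscoreReport:
        matched = [s for s in scores if s.matched]
        max_abs_z = max((s.z for s in matched), default=0.0)
        cls, flags = classify(
            max_abs_z if matched else math.inf,
            used_floor=used_floor, side_chain=side_chain_only, config=config,
        )
        if not matched:
            cls, flags = Classification.FAIL, frozenset(
                {ValidationFlag.SIDE_CHAIN} if side_chain_only else set()
            )
        return ZscoreReport(
            component_id=component_id or graph.component_id,
            variant_label=variant_label,
            scores=scores,
            max_abs_z=max_abs_z if matched else math.inf,
            rmsz_bonds=_rmsz(scores, "bond"),
            rmsz_angles=_rmsz(scores, "angle"),
            n_unmatched=sum(not s.matched for s in scores),
            classification=cls,
            flags=flags,
            used_floor=used_floor,
        )

    pass1 = _score_terms(terms, graph, table, config, with_floor=False)
    had_zero_sd = any(
        s.ideal is not None and not s.matched for s in pass1
    )
    report1 = build(pass1, used_floor=False)
    if report1.classification is not Classification.FAIL and not had_zero_sd:
        return report1

    pass2 = _score_terms(terms, graph, table, config, with_floor=True)
    any_floored = any(s.floored for s in pass2 if s.matched)
    return build(pass2, used_floor=any_floored)


# ---------------------------------------------------------------------------
# Reference-table I/O (TSV/CSV with header kind,type_key,ideal,sd,n_obs)

def read_reference_table(text: str) -> ReferenceTable:
    """Parse a delimited reference table.

    Delimiter is sniffed between tab and comma.  Duplicate keys keep the
    last row.  A zero s.d. is accepted (single-observation types); a
    negative s.d. is a parse error.
    """
    stripped = text.strip()
    if not stripped:
        return ReferenceTable()
    header = stripped.splitlines()[0]
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(StringIO(text), sep=sep)
    required = {"kind", "type_key", "ideal", "sd", "n_obs"}
    missing = required - set(df.columns)
    if missing:
        raise ComponentError(f"reference table missing columns: {sorted(missing)}")
    table = ReferenceTable()
    for row in df.itertuples(index=False):
        if row.sd < 0:
            raise ComponentError(f"negative s.d. for key {row.type_key!r}")
        entry = ReferenceEntry(float(row.ideal), float(row.sd), int(row.n_obs))
        kind = str(row.kind).strip().lower()
        if kind == "bond":
            if not entry.ideal > 0:
                raise ComponentError(f"bond ideal must be positive: {row.type_key!r}")
            table.bond_entries[str(row.type_key)] = entry
        elif kind == "angle":
            if not 0 < entry.ideal < 180:
                raise ComponentError(f"angle ideal out of (0,180): {row.type_key!r}")
            table.angle_entries[str(row.type_key)] = entry
        else:
            raise ComponentError(f"unknown term kind {row.kind!r}")
    return table


def write_reference_table(table: ReferenceTable, sep: str = "\t") -> str:
    lines = [sep.join(("kind", "type_key", "ideal", "sd", "n_obs"))]
    for kind, entries in (("bond", table.bond_entries), ("angle", table.angle_entries)):
        for key in sorted(entries):
            e = entries[key]
            lines.append(sep.join((kind, key, "%.6f" % e.ideal, "%.6f" % e.sd,
                                   str(e.n_obs))))
    return "\n".join(lines) + "\n"
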