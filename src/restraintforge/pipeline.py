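"""End-to-end orchestration: filter, protonation variants, candidate
geometries in method order, restraint generation, validation and the
minimization round-trip, plus cross-tabulated summaries.

Candidate geometries are data, not computations: callers supply an
ordered list of pre-computed coordinate sets per variant (typically the
output of successively more expensive geometry optimizers) and the first
candidate whose validation does not fail is accepted.  The in-notitia
(as-recorded, protonated) variant is only processed once the in-situ
(deprotonated) variant has passed — no resources are spent on a
protonated form whose parent geometry is already known to be bad.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .chemgraph import (
    VariantLabel,
    enumerate_protonation_variants,
    trim_polymer_termini,
)
from .component_io import Component, ComponentClass
from .geomin import EnergyModel, MinimizeConfig, roundtrip_check
from .restraint_gen import (
    EsdPolicy,
    RestraintDictionary,
    build_dictionary,
    measure_geometry,
    perceive,
)
from .validation import (
    Classification,
    ReferenceTable,
    ValidationConfig,
    ValidationFlag,
    ZscoreReport,
    validate_geometry,
)

__all__ = [
    "CandidateGeometry",
    "VariantRecord",
    "ComponentOutcome",
    "SummaryCounts",
    "process_component",
    "summarize",
]

log = logging.getLogger(__name__)

NO_GEOMETRY = "no-geometry"


@dataclass(frozen=True)
class CandidateGeometry:
    """A pre-computed coordinate set; the label names its provenance
    (e.g. "method-1" for the fast optimizer, "method-2" for the
    expensive fallback)."""

    method_label: str
    coords: dict[str, tuple[float, float, float]]


@dataclass
class VariantRecord:
    variant_label: VariantLabel
    accepted_method: Optional[str]
    classification: Classification
    flags: frozenset
    report: Optional[ZscoreReport] = None
    dictionary: Optional[RestraintDictionary] = None
    roundtrip_rmsd: Optional[float] = None
    failure_marker: Optional[str] = None


@dataclass
class ComponentOutcome:
    component_id: str
    records: list[VariantRecord] = field(default_factory=list)
    filter_reason: Optional[str] = None

    def record(self, label: VariantLabel) -> Optional[VariantRecord]:
        for r in self.records:
            if r.variant_label is label:
                return r
        return None


def _validate_candidates(
    component: Component,
    candidates: Sequence[CandidateGeometry],
    table: ReferenceTable,
    vconfig: ValidationConfig,
    side_chain_only: bool,
    variant_label: VariantLabel,
) -> tuple[Optional[CandidateGeometry], Optional[ZscoreReport]]:
    """Return the first candidate whose classification is not fail."""
    last_report = None
    for cand in candidates:
        comp = component.with_coords(cand.coords)
        graph = perceive(comp)
        measured = measure_geometry(comp, graph)
        report = validate_geometry(
            measured, graph, table, vconfig,
            side_chain_only=side_chain_only,
            component_id=component.id, variant_label=variant_label,
        )
        log.info(
            "%s %s %s: %s max|Z|=%.2f",
            component.id, variant_label.value, cand.method_label,
            report.classification.value, report.max_abs_z,
        )
        if report.classification is not Classification.FAIL:
            return cand, report
        last_report = report
    return None, last_report


def _strip_missing(coords: dict, component: Component) -> dict:
    """Restrict a coordinate set to the variant's atoms."""
    names = set(component.atom_names)
    return {k: v for k, v in coords.items() if k in names}


def process_component(
    component: Component,
    geometries: dict[VariantLabel, Sequence[CandidateGeometry]] | Sequence[CandidateGeometry],
    table: ReferenceTable,
    policy: Optional[EsdPolicy] = None,
    vconfig: Optional[ValidationConfig] = None,
    energy_model: Optional[EnergyModel] = None,
    minimize_config: Optional[MinimizeConfig] = None,
) -> ComponentOutcome:
    """Run the per-component procedure.

    ``geometries`` maps variant label to an ordered candidate list; a
    bare sequence is treated as in-notitia-state geometries and reused
    for the in-situ variant with the acidic protons dropped (an
    approximation, logged — callers with per-variant optimized
    geometries should supply both).  Amino acids are validated
    side-chain-only and trimmed of their terminus atoms before the
    dictionary is built.  The in-notitia variant is processed only when
    the in-situ variant was accepted.
    """
    policy = policy or EsdPolicy()
    vconfig = vconfig or ValidationConfig()
    outcome = ComponentOutcome(component_id=component.id)

    variants = {v.label: v for v in enumerate_protonation_variants(component)}
    if not isinstance(geometries, dict):
        geometries = {VariantLabel.IN_NOTITIA: list(geometries)}

    def candidates_for(label: VariantLabel, comp: Component):
        cands = geometries.get(label)
        if cands is None:
            fallback = geometries.get(VariantLabel.IN_NOTITIA) or geometries.get(
                VariantLabel.IN_SITU
            )
            if fallback is None:
                return []
            log.warning(
                "%s: no %s geometries supplied; reusing the other variant's "
                "with protons stripped (approximate)", component.id, label.value,
            )
            cands = [
                CandidateGeometry(c.method_label, _strip_missing(c.coords, comp))
                for c in fallback
            ]
        return [
            c for c in cands
            if set(comp.atom_names) <= set(c.coords)
        ]

    def run_variant(label: VariantLabel) -> VariantRecord:
        comp = variants[label].component
        side_chain_only = comp.comp_class is ComponentClass.AMINO_ACID
        cands = candidates_for(label, comp)
        if not cands:
            return VariantRecord(
                label, None, Classification.FAIL, frozenset(),
                failure_marker=NO_GEOMETRY,
            )
        accepted, report = _validate_candidates(
            comp, cands, table, vconfig, side_chain_only, label
        )
        if accepted is None:
            return VariantRecord(
                label, None, Classification.FAIL,
                report.flags if report else frozenset(), report=report,
            )
        emit_comp = comp.with_coords(_strip_missing(accepted.coords, comp))
        if side_chain_only:
            emit_comp = trim_polymer_termini(emit_comp)
        graph = perceive(emit_comp)
        measured = measure_geometry(emit_comp, graph)
        dictionary = build_dictionary(
            emit_comp, measured, policy, table, graph=graph,
            variant_label=label, provenance=accepted.method_label,
        )
        rt = roundtrip_check(
            dictionary, emit_comp.coords, energy_model, minimize_config,
            elements={a.name: a.element for a in emit_comp.atoms},
        )
        return VariantRecord(
            label, accepted.method_label, report.classification, report.flags,
            report=report, dictionary=dictionary, roundtrip_rmsd=rt.rmsd_to_start,
        )

    in_situ = run_variant(VariantLabel.IN_SITU)
    outcome.records.append(in_situ)
    if VariantLabel.IN_NOTITIA in variants:
        if in_situ.classification is not Classification.FAIL:
            outcome.records.append(run_variant(VariantLabel.IN_NOTITIA))
        else:
            log.info(
                "%s: in_situ failed validation; in_notitia not attempted",
                component.id,
            )
    return outcome


# ---------------------------------------------------------------------------
# Summaries

_ROW_ORDER = (
    "awesome",
    "awesome (side chain)",
    "superior",
    "superior (side chain)",
    "satisfactory",
    "satisfactory (reasonable std)",
    "satisfactory (reasonable std) (side chain)",
    "satisfactory (side chain)",
    "fail",
)


def _row_label(classification: Classification, flags: frozenset) -> str:
    label = classification.value
    if ValidationFlag.REASONABLE_STD in flags:
        label += " (reasonable std)"
    if ValidationFlag.SIDE_CHAIN in flags:
        label += " (side chain)"
    return label


@dataclass
class SummaryCounts:
    """Cross-tabulation of outcomes: rows are classification labels
    (flag-qualified), columns are (method, variant) cells."""

    cells: dict[tuple[str, str], dict[str, int]] = field(default_factory=dict)

    def add(self, column: tuple[str, str], row: str) -> None:
        self.cells.setdefault(column, {}).setdefault(row, 0)
        self.cells[column][row] += 1

    def column_total(self, column: tuple[str, str]) -> int:
        return sum(self.cells.get(column, {}).values())

    @property
    def total(self) -> int:
        return sum(self.column_total(c) for c in self.cells)

    def to_tsv(self) -> str:
        columns = sorted(self.cells)
        header = ["Validation class"] + [f"{m} ({v})" for m, v in columns]
        rows = [header]
        seen_rows = [r for r in _ROW_ORDER
                     if any(r in self.cells[c] for c in columns)]
        for row in seen_rows:
            rows.append(
                [row] + [str(self.cells[c].get(row, 0)) for c in columns]
            )
        rows.append(["Total"] + [str(self.column_total(c)) for c in columns])
        return "\n".join("\t".join(r) for r in rows) + "\n"


def summarize(outcomes: Sequence[ComponentOutcome]) -> SummaryCounts:
    """Tabulate validation classes per (method, variant) column.

    Every processed variant record is counted exactly once: accepted
    records under their accepting method, failed ones under "failed".
    Filtered-out components (no records) are not counted.
    """
    counts = SummaryCounts()
    for outcome in outcomes:
        for rec in outcome.records:
            method = rec.accepted_method or "failed"
            counts.add((method, rec.variant_label.value),
                       _row_label(rec.classification, rec.flags))
    return counts
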