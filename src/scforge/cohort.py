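"""Repertoire-scale analyses: record filtering, CDR-redundancy
deduplication, linker surveys and property histograms."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

from . import numbering, physchem, seqio
from .errors import NotAnAntibodyError, ScforgeError

TARGET_LOCATIONS = (
    "cytoplasmic",
    "extracellular",
    "membrane",
    "viral",
    "bacterial",
    "undefined",
)


@dataclass(frozen=True)
class CohortRecord:
    """One paired-Fv repertoire entry with flat metadata flags."""

    id: str
    vl: str
    vh: str
    target_is_protein: bool | None = None
    target_location: str | None = None
    specificity_arity: str | None = None  # mono | bi | tri
    target_name: str | None = None

    @property
    def fv_charge(self) -> int:
        return physchem.net_charge(self.vl + self.vh)


@dataclass(frozen=True)
class FilterRules:
    """Thresholds and missing-metadata policy for :func:`filter_records`.

    'Unusually long CDR' is not defined by the source; the defaults
    (CDR-H3 > 26, all others > 17) are deliberate, auditable choices.
    """

    max_cdr_h3: int = 26
    max_cdr_other: int = 17
    missing_metadata: str = "exclude"  # "exclude" | "pass"


#: Removal rules in their canonical application order; a record is
#: removed at the FIRST failing rule.
RULE_ORDER = (
    "non_protein_target",
    "bacterial",
    "viral",
    "extracellular",
    "membrane",
    "multispecific",
    "no_defined_target",
    "long_cdr",
    "annotation_failed",
)


@dataclass
class FilterReport:
    total_in: int = 0
    total_kept: int = 0
    removed: dict[str, int] = field(
        default_factory=lambda: {rule: 0 for rule in RULE_ORDER}
    )


@dataclass(frozen=True)
class Histogram:
    """Fixed-width histogram; bins are inclusive-left, exclusive-right."""

    edges: tuple[float, ...]
    counts: tuple[int, ...]

    @property
    def total(self) -> int:
        return sum(self.counts)

    @classmethod
    def from_values(cls, values: Sequence[float], bin_width: float = 1.0) -> "Histogram":
        if not values:
            return cls(edges=(), counts=())
        lo = math.floor(min(values) / bin_width) * bin_width
        hi = math.floor(max(values) / bin_width) * bin_width + bin_width
        n_bins = round((hi - lo) / bin_width)
        edges = tuple(lo + i * bin_width for i in range(n_bins + 1))
        counts = [0] * n_bins
        for v in values:
            i = min(int((v - lo) / bin_width), n_bins - 1)
            counts[i] += 1
        return cls(edges=edges, counts=tuple(counts))


def _annotate(record: CohortRecord):
    vl = numbering.segment_regions(numbering.number_domain(record.vl))
    vh = numbering.segment_regions(numbering.number_domain(record.vh))
    if vl.chain_class != "VL" or vh.chain_class != "VH":
        raise NotAnAntibodyError(
            f"record {record.id!r}: chain typing mismatch "
            f"({vl.chain_class}, {vh.chain_class})"
        )
    return vl, vh


def _cdr_sequences(domain) -> dict[str, str]:
    out = {"CDR1": "", "CDR2": "", "CDR3": ""}
    for residue, region in zip(domain.residues, domain.regions):
        if region in out:
            out[region] += residue.amino_acid
    return out


def _failing_rule(record: CohortRecord, rules: FilterRules) -> str | None:
    missing_fails = rules.missing_metadata == "exclude"

    def missing(value) -> bool:
        return value is None or value == ""

    if missing(record.target_is_protein):
        if missing_fails:
            return "non_protein_target"
    elif not record.target_is_protein:
        return "non_protein_target"

    loc = record.target_location
    if missing(loc):
        if missing_fails:
            return "no_defined_target"
    else:
        if loc == "bacterial":
            return "bacterial"
        if loc == "viral":
            return "viral"
        if loc == "extracellular":
            return "extracellular"
        if loc == "membrane":
            return "membrane"
        if loc == "undefined":
            return "no_defined_target"

    arity = record.specificity_arity
    if missing(arity):
        if missing_fails:
            return "multispecific"
    elif arity in ("bi", "tri"):
        return "multispecific"

    if missing(record.target_name):
        return "no_defined_target"

    try:
        vl, vh = _annotate(record)
    except ScforgeError:
        return "annotation_failed"
    for domain in (vl, vh):
        cdrs = _cdr_sequences(domain)
        h3_limit = rules.max_cdr_h3 if domain.chain_class == "VH" else rules.max_cdr_other
        if len(cdrs["CDR3"]) > h3_limit:
            return "long_cdr"
        if len(cdrs["CDR1"]) > rules.max_cdr_other:
            return "long_cdr"
        if len(cdrs["CDR2"]) > rules.max_cdr_other:
            return "long_cdr"
    return None


def filter_records(
    records: Sequence[CohortRecord], rules: FilterRules = FilterRules()
) -> tuple[list[CohortRecord], FilterReport]:
    """Apply the removal rules in order; each record is charged to the
    first rule it fails. Order-stable and idempotent."""
    report = FilterReport(total_in=len(records))
    kept: list[CohortRecord] = []
    for record in records:
        rule = _failing_rule(record, rules)
        if rule is None:
            kept.append(record)
        else:
            report.removed[rule] += 1
    report.total_kept = len(kept)
    return kept, report


def dedup_by_cdr(
    records: Sequence[CohortRecord],
) -> tuple[list[CohortRecord], list[CohortRecord]]:
    """Collapse records sharing all six CDR sequences, keeping the
    lowest-charge paired Fv (ties broken by id). Records that fail
    annotation go to the rejects list."""
    groups: dict[str, list[CohortRecord]] = {}
    order: list[str] = []
    rejects: list[CohortRecord] = []
    for record in records:
        try:
            vl, vh = _annotate(record)
        except ScforgeError:
            rejects.append(record)
            continue
        cdrs_vl = _cdr_sequences(vl)
        cdrs_vh = _cdr_sequences(vh)
        key = "|".join(
            [cdrs_vl["CDR1"], cdrs_vl["CDR2"], cdrs_vl["CDR3"],
             cdrs_vh["CDR1"], cdrs_vh["CDR2"], cdrs_vh["CDR3"]]
        )
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(record)
    representatives = [
        min(groups[key], key=lambda r: (r.fv_charge, r.id)) for key in order
    ]
    return representatives, rejects


@dataclass
class LinkerSurveyReport:
    accepted: int = 0
    rejected_short_linker: int = 0
    rejected_unparseable: int = 0


def linker_survey(
    scfv_records: Sequence[seqio.SeqRecord],
    tag_library: Sequence = (),
) -> tuple[Histogram, LinkerSurveyReport]:
    """Histogram of interdomain-linker net charge over parseable scFv
    records; linkers of length <= 6 (and unparseable records) are
    rejected and counted."""
    report = LinkerSurveyReport()
    charges: list[int] = []
    for record in scfv_records:
        try:
            # length rule applied here so short linkers are counted as
            # short, not as parse failures
            parts = seqio.parse_scfv(record, tag_library, min_linker_length=0)
        except ScforgeError:
            report.rejected_unparseable += 1
            continue
        if parts.linker is None or len(parts.linker.sequence) <= seqio.MIN_LINKER_LENGTH:
            report.rejected_short_linker += 1
            continue
        charges.append(physchem.net_charge(parts.linker.sequence))
        report.accepted += 1
    return Histogram.from_values(charges, bin_width=1.0), report


_PROPERTY_FUNCS: dict[str, Callable[[str], float]] = {
    "net_charge": physchem.net_charge,
    "pI": physchem.isoelectric_point,
}


def property_histogram(
    records: Sequence[CohortRecord],
    property: str = "net_charge",
    region: str | None = None,
    chain: str | None = None,
) -> Histogram:
    """Histogram of a per-record property over the paired Fv (or one
    chain / one region class). Charge uses integer bins, pI uses 0.1-pH
    bins. ``region`` may be "framework" or "cdr" (requires ``chain``)."""
    values: list[float] = []
    for record in records:
        if region is None:
            if chain == "VL":
                seq = record.vl
            elif chain == "VH":
                seq = record.vh
            else:
                seq = record.vl + record.vh
            values.append(_PROPERTY_FUNCS[property](seq))
        else:
            vl, vh = _annotate(record)
            summary = physchem.region_charges(vl, vh)
            table = {
                ("VL", "framework"): summary.vl_framework_total,
                ("VL", "cdr"): summary.vl_cdr_total,
                ("VH", "framework"): summary.vh_framework_total,
                ("VH", "cdr"): summary.vh_cdr_total,
            }
            if (chain, region) not in table:
                raise ValueError(f"unknown chain/region {(chain, region)!r}")
            values.append(table[(chain, region)])
    width = 0.1 if property == "pI" else 1.0
    return Histogram.from_values(values, bin_width=width)
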