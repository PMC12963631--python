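"""scFv construct assembly: linker/tag libraries, domain-orientation
rule and charge budgeting toward a target solubility."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations

from . import physchem, solubility
from .errors import AssemblyError, ChargeRangeError
from .numbering import NumberedDomain
from .solubility import SolubilityModel, DEFAULT_MODEL


@dataclass(frozen=True)
class LinkerSpec:
    name: str
    sequence: str

    @property
    def net_charge(self) -> int:
        return physchem.net_charge(self.sequence)


@dataclass(frozen=True)
class TagSpec:
    name: str
    sequence: str
    terminus: str  # "N" | "C"

    @property
    def net_charge(self) -> int:
        return physchem.net_charge(self.sequence)


#: The interdomain linker family: (G4S)4 plus six electronegative
#: variants tuning net charge from 0 to -10.
DEFAULT_LINKERS: dict[str, LinkerSpec] = {
    spec.name: spec
    for spec in (
        LinkerSpec("G4S4", "GGGGS" * 4),
        LinkerSpec("G4D4", "GGGGD" * 4),
        LinkerSpec("G4E4", "GGGGE" * 4),
        LinkerSpec("G2D7", "GGD" * 7),
        LinkerSpec("G2E7", "GGE" * 7),
        LinkerSpec("GD10", "GD" * 10),
        LinkerSpec("GE10", "GE" * 10),
    )
}

#: Epitope tags doubling as negative-charge carriers. Default placement:
#: 3xFLAG at the N-terminus, HA at the C-terminus. The myc sequence is
#: the canonical one (the source never spells it out).
DEFAULT_TAGS: dict[str, TagSpec] = {
    spec.name: spec
    for spec in (
        TagSpec("3xFLAG", "DYKDHDGDYKDHDIDYKDDDDK", "N"),
        TagSpec("HA", "YPYDVPDYA", "C"),
        TagSpec("myc", "EQKLISEEDL", "C"),
    )
}


@dataclass(frozen=True)
class ScFvConstruct:
    """An assembled single-chain construct with resolved part layout."""

    orientation: str  # "VLVH" | "VHVL"
    n_tags: tuple[TagSpec, ...]
    vl: NumberedDomain
    vh: NumberedDomain
    linker: LinkerSpec
    c_tags: tuple[TagSpec, ...]
    warnings: tuple[str, ...] = ()

    @property
    def first_domain(self) -> NumberedDomain:
        return self.vl if self.orientation == "VLVH" else self.vh

    @property
    def second_domain(self) -> NumberedDomain:
        return self.vh if self.orientation == "VLVH" else self.vl

    @property
    def full_sequence(self) -> str:
        return "".join(
            [t.sequence for t in self.n_tags]
            + [self.first_domain.sequence, self.linker.sequence,
               self.second_domain.sequence]
            + [t.sequence for t in self.c_tags]
        )

    @property
    def net_charge(self) -> int:
        return physchem.net_charge(self.full_sequence)

    def part_offsets(self) -> dict[str, tuple[int, int]]:
        """0-based half-open index span of each part in full_sequence."""
        spans: dict[str, tuple[int, int]] = {}
        pos = 0
        for t in self.n_tags:
            spans[f"n_tag:{t.name}"] = (pos, pos + len(t.sequence))
            pos += len(t.sequence)
        first = "VL" if self.orientation == "VLVH" else "VH"
        second = "VH" if self.orientation == "VLVH" else "VL"
        spans[first] = (pos, pos + len(self.first_domain.sequence))
        pos += len(self.first_domain.sequence)
        spans["linker"] = (pos, pos + len(self.linker.sequence))
        pos += len(self.linker.sequence)
        spans[second] = (pos, pos + len(self.second_domain.sequence))
        pos += len(self.second_domain.sequence)
        for t in self.c_tags:
            spans[f"c_tag:{t.name}"] = (pos, pos + len(t.sequence))
            pos += len(t.sequence)
        return spans


def choose_orientation(vh_charge: int, requested: str = "auto"):
    """The reliability rule: auto always resolves to VLVH. An explicit
    VHVL request is honoured, with a warning when the VH domain carries
    positive charge."""
    warnings: list[str] = []
    if requested == "auto":
        return "VLVH", warnings
    if requested not in ("VLVH", "VHVL"):
        raise AssemblyError(f"unknown orientation {requested!r}")
    if requested == "VHVL" and vh_charge > 0:
        warnings.append(
            f"VHVL orientation with positively charged VH (+{vh_charge}): "
            "reduced solubility risk; consider VLVH or charge-swap mutations"
        )
    return requested, warnings


def assemble_scfv(
    vl: NumberedDomain,
    vh: NumberedDomain,
    linker: LinkerSpec | str = "G4S4",
    tags: tuple[TagSpec, ...] | list[TagSpec] = (),
    orientation: str = "auto",
) -> ScFvConstruct:
    """Assemble N-tags + domain + linker + domain + C-tags.

    ``tags`` carry their own terminus; duplicate tag names are rejected.
    """
    if isinstance(linker, str):
        linker = DEFAULT_LINKERS[linker]
    if vl.chain_class != "VL" or vh.chain_class != "VH":
        raise AssemblyError(
            f"expected (VL, VH), got ({vl.chain_class}, {vh.chain_class})"
        )
    names = [t.name for t in tags]
    if len(names) != len(set(names)):
        raise AssemblyError(f"duplicate tag placement: {names}")
    vh_charge = physchem.net_charge(vh.sequence)
    resolved, warnings = choose_orientation(vh_charge, orientation)
    n_tags = tuple(t for t in tags if t.terminus == "N")
    c_tags = tuple(t for t in tags if t.terminus == "C")
    return ScFvConstruct(
        orientation=resolved,
        n_tags=n_tags,
        vl=vl,
        vh=vh,
        linker=linker,
        c_tags=c_tags,
        warnings=tuple(warnings),
    )


def from_sequence(record, tag_library=None) -> ScFvConstruct:
    """Rebuild an :class:`ScFvConstruct` from an assembled scFv sequence
    by decomposing it (tags, domains, linker) and renumbering the
    domains. The reconstructed ``full_sequence`` equals the input."""
    from . import seqio
    from .numbering import number_domain

    if tag_library is None:
        tag_library = tuple(DEFAULT_TAGS.values())
    if isinstance(record, str):
        record = seqio.SeqRecord(id="scfv", residues=record)
    parts = seqio.parse_scfv(record, tag_library)
    if parts.domain2 is None:
        raise AssemblyError(f"record {record.id!r} is not a two-domain scFv")
    d1 = number_domain(parts.domain1.sequence)
    d2 = number_domain(parts.domain2.sequence)
    roles = {d1.chain_class, d2.chain_class}
    if roles != {"VL", "VH"}:
        raise AssemblyError(
            f"record {record.id!r}: expected one VL and one VH, got "
            f"({d1.chain_class}, {d2.chain_class})"
        )
    orientation = "VLVH" if d1.chain_class == "VL" else "VHVL"
    vl, vh = (d1, d2) if orientation == "VLVH" else (d2, d1)
    linker_seq = parts.linker.sequence
    linker = next(
        (l for l in DEFAULT_LINKERS.values() if l.sequence == linker_seq),
        LinkerSpec("custom", linker_seq),
    )
    by_seq = {(t.sequence, t.terminus): t for t in tag_library}
    n_tags = tuple(
        by_seq.get((s.sequence, "N"), TagSpec(s.name, s.sequence, "N"))
        for s in parts.n_tags
    )
    c_tags = tuple(
        by_seq.get((s.sequence, "C"), TagSpec(s.name, s.sequence, "C"))
        for s in parts.c_tags
    )
    built = ScFvConstruct(
        orientation=orientation,
        n_tags=n_tags,
        vl=vl,
        vh=vh,
        linker=linker,
        c_tags=c_tags,
    )
    if built.full_sequence != record.residues:
        raise AssemblyError(
            f"record {record.id!r}: reconstruction does not reproduce input"
        )
    return built


#: Preferred library linker per exactly-matched charge target.
_EXACT_LINKER = {0: "G4S4", -4: "G4D4", -7: "G2D7", -10: "GD10"}

COMPOSED_LINKER_LENGTH = 20


def linker_for_charge(target: int) -> LinkerSpec:
    """A linker whose net charge equals ``target`` (within [-10, 0]).

    Library linkers are returned for exact matches; other targets get a
    composed 20-residue G/S/D pattern with evenly spaced aspartates.
    """
    if not -10 <= target <= 0:
        raise ChargeRangeError(f"linker charge target {target} outside [-10, 0]")
    if target in _EXACT_LINKER:
        return DEFAULT_LINKERS[_EXACT_LINKER[target]]
    k = -target
    length = COMPOSED_LINKER_LENGTH
    residues = list("GGGGS" * (length // 5))
    positions = [round((i + 0.5) * length / k - 0.5) for i in range(k)]
    for p in positions:
        residues[p] = "D"
    seq = "".join(residues)
    spec = LinkerSpec(f"composed_D{k}", seq)
    assert spec.net_charge == target
    return spec


@dataclass(frozen=True)
class ChargeBudget:
    """Outcome of inverting the solubility line for a target percent."""

    required_charge: int
    feasible: bool
    linker: LinkerSpec | None = None
    tags: tuple[TagSpec, ...] = ()
    achieved_charge: int | None = None
    residual_gap: int = 0  # charge units still missing when infeasible
    note: str = ""


def _tag_subsets(pool: tuple[TagSpec, ...]):
    return chain.from_iterable(
        combinations(pool, r) for r in range(len(pool) + 1)
    )


def charge_budget(
    fv_charge: int,
    target_percent: float,
    model: SolubilityModel = DEFAULT_MODEL,
    tag_pool: tuple[TagSpec, ...] = (
        DEFAULT_TAGS["3xFLAG"],
        DEFAULT_TAGS["HA"],
    ),
) -> ChargeBudget:
    """Largest integer charge meeting ``target_percent``, plus the
    lowest-modification tag/linker combination that reaches it from
    ``fv_charge`` — or an infeasibility report with the residual gap."""
    import math

    required = math.floor((target_percent - model.intercept) / model.slope)
    if solubility.predict_percent(required, model) < target_percent:
        required -= 1  # guard against floating point at the boundary

    best = None
    for tags in _tag_subsets(tag_pool):
        tag_charge = sum(t.net_charge for t in tags)
        for linker in DEFAULT_LINKERS.values():
            achieved = fv_charge + tag_charge + linker.net_charge
            if achieved > required:
                continue
            cost = (len(tags) + (1 if linker.net_charge != 0 else 0),
                    abs(tag_charge + linker.net_charge))
            if best is None or cost < best[0]:
                best = (cost, tags, linker, achieved)
    if best is not None:
        _, tags, linker, achieved = best
        return ChargeBudget(
            required_charge=required,
            feasible=True,
            linker=linker,
            tags=tuple(tags),
            achieved_charge=achieved,
        )
    min_mod = sum(t.net_charge for t in tag_pool) + min(
        l.net_charge for l in DEFAULT_LINKERS.values()
    )
    reachable = fv_charge + min_mod
    return ChargeBudget(
        required_charge=required,
        feasible=False,
        achieved_charge=reachable,
        residual_gap=reachable - required,
        note=(
            f"tags+linker reach {reachable:+d} but {required:+d} is needed; "
            "framework charge-swap mutations additionally required"
        ),
    )
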