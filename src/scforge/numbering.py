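"""Chothia numbering by template transfer, region segmentation and
position-addressed editing of antibody variable domains.

The engine aligns a query against three embedded Chothia-labelled
templates (VH, VL-kappa, VL-lambda) with a global affine-gap aligner and
transfers the best template's labels column by column. Insertions
relative to the template receive insertion codes; deletions drop labels.
An acceptance threshold on the template-normalised score rejects
sequences that are not variable domains.

Coordinates: ``source_span`` is 0-based half-open into the parent
sequence; Chothia labels are the conventional 1-based scheme.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, replace
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from ._templates import TEMPLATES, Template
from .errors import MutationError, NotAnAntibodyError

#: Minimum template-normalised alignment score to accept a numbering.
#: Calibrated so shuffled templates (same composition, no antibody
#: architecture) fall well below while true domains with fully divergent
#: CDRs stay well above.
ACCEPT_THRESHOLD = 0.45

GAP_OPEN = -10.0
GAP_EXTEND = -1.0

_INSERTION_CODES = string.ascii_lowercase


@dataclass(frozen=True)
class NumberedResidue:
    """One residue with its Chothia label."""

    number: int
    insertion: str  # "" when none
    amino_acid: str

    @property
    def label(self) -> str:
        return f"{self.number}{self.insertion}"


@dataclass(frozen=True)
class RegionMap:
    """Inclusive Chothia CDR ranges per chain class; frameworks fill the
    gaps. The default carries the VL 24-34/50-56/89-97 and
    VH 25-32/52-56/95-102 boundaries."""

    cdr_ranges: dict  # chain class -> {"CDR1": (lo, hi), ...}

    def region_of(self, chain_class: str, number: int) -> str:
        ranges = self.cdr_ranges[chain_class]
        for name, (lo, hi) in ranges.items():
            if lo <= number <= hi:
                return name
        if number < ranges["CDR1"][0]:
            return "FR1"
        if number < ranges["CDR2"][0]:
            return "FR2"
        if number < ranges["CDR3"][0]:
            return "FR3"
        return "FR4"


DEFAULT_REGION_MAP = RegionMap(
    {
        "VL": {"CDR1": (24, 34), "CDR2": (50, 56), "CDR3": (89, 97)},
        "VH": {"CDR1": (25, 32), "CDR2": (52, 56), "CDR3": (95, 102)},
    }
)

#: Conserved framework salt bridges (chain class -> ((basic pos, allowed),
#: (acidic pos, allowed))).
SALT_BRIDGES = {
    "VL": ((61, "KR"), (82, "D")),
    "VH": ((66, "KR"), (86, "D")),
}


@dataclass(frozen=True)
class NumberedDomain:
    """A variable domain with per-residue Chothia labels.

    ``regions`` is populated by :func:`segment_regions` and is a tuple of
    region names parallel to ``residues``.
    """

    chain_type: str  # "VH" | "VL-kappa" | "VL-lambda"
    residues: tuple[NumberedResidue, ...]
    alignment_score: float  # template-normalised, in (0, 1]
    source_span: tuple[int, int]  # 0-based half-open
    regions: tuple[str, ...] | None = None

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    @property
    def chain_class(self) -> str:
        """"VH" or "VL" irrespective of light-chain isotype."""
        return "VH" if self.chain_type == "VH" else "VL"

    def residue_at(self, number: int, insertion: str = "") -> NumberedResidue | None:
        for r in self.residues:
            if r.number == number and r.insertion == insertion:
                return r
        return None

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class BridgeStatus:
    chain_class: str
    basic_position: int
    basic_residue: str | None  # None when position absent
    acidic_position: int
    acidic_residue: str | None
    intact: bool


@dataclass(frozen=True)
class SaltBridgeReport:
    vl: BridgeStatus
    vh: BridgeStatus

    @property
    def all_intact(self) -> bool:
        return self.vl.intact and self.vh.intact


@dataclass(frozen=True)
class Mutation:
    """A position-addressed substitution, e.g. VL K20D."""

    chain: str  # "VL" | "VH"
    wild_type: str
    number: int
    insertion: str
    new_residue: str

    @classmethod
    def parse(cls, text: str) -> "Mutation":
        """Parse 'VL K20D' / 'VH K100aD' style notation."""
        chain, rest = text.split(None, 1)
        chain = chain.upper()
        if chain not in ("VL", "VH"):
            raise MutationError(f"unknown chain {chain!r} in {text!r}")
        wt, new = rest[0].upper(), rest[-1].upper()
        body = rest[1:-1]
        ins = ""
        while body and body[-1].isalpha():
            ins = body[-1].lower() + ins
            body = body[:-1]
        try:
            num = int(body)
        except ValueError as exc:
            raise MutationError(f"cannot parse position in {text!r}") from exc
        return cls(chain, wt, num, ins, new)


@lru_cache(maxsize=4)
def _aligner(mode: str) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = GAP_OPEN
    a.extend_gap_score = GAP_EXTEND
    a.mode = mode
    return a


@lru_cache(maxsize=8)
def _self_score(sequence: str) -> float:
    mat = substitution_matrices.load("BLOSUM62")
    return float(sum(mat[c, c] for c in sequence))


def _transfer(
    template: Template, alignment, query: str, offset: int = 0
) -> NumberedDomain:
    """Transfer template labels onto the aligned query residues."""
    idx = alignment.indices  # rows: template, query; -1 marks gaps
    t_row, q_row = idx[0], idx[1]
    residues: list[NumberedResidue] = []
    last: tuple[int, str] | None = None
    q_positions: list[int] = []
    for t_i, q_i in zip(t_row, q_row):
        if q_i < 0:
            continue
        if t_i >= 0:
            num, ins = template.labels[t_i]
            last = (num, ins)
        else:
            # insertion relative to the template: extend insertion codes
            if last is None:
                num, ins = 0, _next_code("")
            else:
                num, ins = last[0], _next_code(last[1])
            last = (num, ins)
        residues.append(NumberedResidue(num, ins, query[q_i]))
        q_positions.append(int(q_i))
    chain_class = "VH" if template.chain_type == "VH" else "VL"
    residues = _relayout_cdr3(residues, chain_class)
    span = (offset + q_positions[0], offset + q_positions[-1] + 1)
    norm = alignment.score / _self_score(template.sequence)
    return NumberedDomain(
        chain_type=template.chain_type,
        residues=tuple(residues),
        alignment_score=norm,
        source_span=span,
    )


#: CDR3 layout constants per chain class: (first, last, insertion apex).
_CDR3_LAYOUT = {"VH": (95, 102, 100), "VL": (89, 97, 95)}


def _relayout_cdr3(
    residues: list[NumberedResidue], chain_class: str
) -> list[NumberedResidue]:
    """Renumber the CDR3 loop by the Chothia convention.

    Alignment transfer places loop insertions wherever gaps score best;
    the convention instead numbers from both ends toward the apex, with
    insertion codes at position 100 (VH) / 95 (VL). Short loops delete
    just before the two C-terminal slots.
    """
    lo, hi, apex = _CDR3_LAYOUT[chain_class]
    anchor = (lo - 1, "")
    start = None
    end = None
    for i, r in enumerate(residues):
        key = (r.number, r.insertion)
        if key > anchor and r.number <= hi:
            if start is None:
                start = i
            end = i
    if start is None:
        return residues
    loop = residues[start: end + 1]
    n = len(loop)
    if n <= 2:
        labels = [(lo + i, "") for i in range(n)]
    else:
        front_slots = apex - lo + 1
        rem = n - 2
        if rem <= front_slots:
            labels = [(lo + i, "") for i in range(rem)]
        else:
            labels = [(lo + i, "") for i in range(front_slots)]
            labels += [
                (apex, _INSERTION_CODES[k]) for k in range(rem - front_slots)
            ]
        labels += [(hi - 1, ""), (hi, "")]
    relabelled = [
        NumberedResidue(num, ins, r.amino_acid)
        for (num, ins), r in zip(labels, loop)
    ]
    return residues[:start] + relabelled + residues[end + 1:]


def _next_code(code: str) -> str:
    if code == "":
        return "a"
    i = _INSERTION_CODES.index(code[-1])
    if i + 1 >= len(_INSERTION_CODES):
        raise NotAnAntibodyError("insertion run exceeds insertion-code alphabet")
    return code[:-1] + _INSERTION_CODES[i + 1]


def number_domain(seq: str) -> NumberedDomain:
    """Assign Chothia labels to a single variable-domain sequence.

    Raises :class:`NotAnAntibodyError` when the best template-normalised
    score is below :data:`ACCEPT_THRESHOLD`.
    """
    seq = seq.upper()
    if not seq:
        raise NotAnAntibodyError("empty sequence")
    aligner = _aligner("global")
    best: tuple[float, Template, object] | None = None
    for tpl in TEMPLATES:
        aln = aligner.align(tpl.sequence, seq)[0]
        norm = aln.score / _self_score(tpl.sequence)
        if best is None or norm > best[0]:
            best = (norm, tpl, aln)
    norm, tpl, aln = best
    if norm < ACCEPT_THRESHOLD:
        raise NotAnAntibodyError(
            f"best template score {norm:.3f} below threshold {ACCEPT_THRESHOLD}"
        )
    return _transfer(tpl, aln, seq)


def _best_local(seq: str):
    aligner = _aligner("local")
    best = None
    for tpl in TEMPLATES:
        if not seq:
            continue
        aln = aligner.align(tpl.sequence, seq)[0]
        norm = aln.score / _self_score(tpl.sequence)
        if best is None or norm > best[0]:
            best = (norm, tpl, aln)
    return best


def extract_fv(seq: str, *, _offset: int = 0) -> list[NumberedDomain]:
    """Locate every variable domain in ``seq`` (constant regions, tags and
    linkers discarded) and return them in N-to-C order.

    A full-length chain yields one domain; an scFv yields two. Raises
    :class:`NotAnAntibodyError` when nothing scores above threshold.
    """
    seq = seq.upper()
    found = _scan(seq, _offset)
    if not found:
        raise NotAnAntibodyError("no variable domain found")
    return sorted(found, key=lambda d: d.source_span)


def _scan(seq: str, offset: int) -> list[NumberedDomain]:
    if len(seq) < 60:
        return []
    best = _best_local(seq)
    if best is None or best[0] < ACCEPT_THRESHOLD:
        return []
    norm, tpl, aln = best
    dom = _transfer(tpl, aln, seq, offset)
    start, end = dom.source_span[0] - offset, dom.source_span[1] - offset
    out = [dom]
    out.extend(_scan(seq[:start], offset))
    out.extend(_scan(seq[end:], offset + end))
    return out


def segment_regions(
    domain: NumberedDomain, scheme: RegionMap = DEFAULT_REGION_MAP
) -> NumberedDomain:
    """Label every residue with its region; insertion-coded residues
    inherit the region of their base number. Total on numbered domains."""
    regions = tuple(
        scheme.region_of(domain.chain_class, r.number) for r in domain.residues
    )
    return replace(domain, regions=regions)


def apply_mutation(domain: NumberedDomain, mutation: Mutation) -> NumberedDomain:
    """Replace one residue addressed by Chothia position; numbering is
    unchanged. The stated wild-type residue must match."""
    if mutation.chain != domain.chain_class:
        raise MutationError(
            f"mutation addresses {mutation.chain} but domain is {domain.chain_class}"
        )
    target = domain.residue_at(mutation.number, mutation.insertion)
    if target is None:
        raise MutationError(
            f"position {mutation.number}{mutation.insertion} absent from domain"
        )
    if target.amino_acid != mutation.wild_type:
        raise MutationError(
            f"wild-type mismatch at {mutation.number}{mutation.insertion}: "
            f"expected {mutation.wild_type}, found {target.amino_acid}"
        )
    new_residues = tuple(
        replace(r, amino_acid=mutation.new_residue)
        if (r.number, r.insertion) == (mutation.number, mutation.insertion)
        else r
        for r in domain.residues
    )
    return replace(domain, residues=new_residues)


def _bridge_status(domain: NumberedDomain) -> BridgeStatus:
    (b_pos, b_ok), (a_pos, a_need) = SALT_BRIDGES[domain.chain_class]
    basic = domain.residue_at(b_pos)
    acidic = domain.residue_at(a_pos)
    intact = (
        basic is not None
        and acidic is not None
        and basic.amino_acid in b_ok
        and acidic.amino_acid in a_need
    )
    return BridgeStatus(
        chain_class=domain.chain_class,
        basic_position=b_pos,
        basic_residue=basic.amino_acid if basic else None,
        acidic_position=a_pos,
        acidic_residue=acidic.amino_acid if acidic else None,
        intact=intact,
    )


def salt_bridge_check(vl: NumberedDomain, vh: NumberedDomain) -> SaltBridgeReport:
    """Report whether the conserved VL 61-82 and VH 66-86 K/R-D salt
    bridges are intact. Missing positions are reported as absent (and the
    bridge as broken)."""
    if vl.chain_class != "VL" or vh.chain_class != "VH":
        raise ValueError("salt_bridge_check expects (VL, VH) in that order")
    return SaltBridgeReport(vl=_bridge_status(vl), vh=_bridge_status(vh))
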