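"""Sequence and report I/O, plus decomposition of assembled scFv
sequences back into tag / domain / linker parts."""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from . import numbering
from .errors import (
    AmbiguousLinkerError,
    FastaParseError,
    NotAnAntibodyError,
    ResidueError,
)

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
GAP_CHARACTERS = frozenset("-.")

#: Residue alphabet of the interdomain linker family; other linker
#: chemistries must be declared explicitly via ``extra_linker_alphabet``.
LINKER_ALPHABET = frozenset("GSDE")

#: A linker must be strictly longer than this many residues.
MIN_LINKER_LENGTH = 6

FASTA_WRAP = 80


@dataclass(frozen=True)
class ResiduePolicy:
    """How non-canonical letters are handled on input.

    strict (default): any letter outside the 20 canonical residues is an
    error. ``allow_x`` admits 'X' (charge 0, excluded from GRAVY and
    aliphatic denominators downstream). ``strip_gaps`` silently removes
    '-'/'.' instead of rejecting them.
    """

    allow_x: bool = False
    strip_gaps: bool = False

    @property
    def alphabet(self) -> frozenset:
        return CANONICAL_RESIDUES | ({"X"} if self.allow_x else frozenset())


STRICT = ResiduePolicy()


@dataclass(frozen=True)
class SeqRecord:
    """An identified amino-acid sequence; the unit all I/O moves."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Segment:
    """A named contiguous slice of a parent sequence."""

    name: str
    sequence: str
    start: int  # 0-based half-open into the parent
    end: int


@dataclass
class ConstructParts:
    """Decomposition of an scFv (or Fv-only) sequence.

    Invariant: the concatenation of all segments in order reproduces the
    input sequence exactly.
    """

    n_tags: list[Segment] = field(default_factory=list)
    domain1: Segment | None = None
    domain1_role: str | None = None  # "VL" | "VH"
    linker: Segment | None = None
    domain2: Segment | None = None
    domain2_role: str | None = None
    c_tags: list[Segment] = field(default_factory=list)

    def segments(self) -> list[Segment]:
        out = list(self.n_tags)
        if self.domain1 is not None:
            out.append(self.domain1)
        if self.linker is not None:
            out.append(self.linker)
        if self.domain2 is not None:
            out.append(self.domain2)
        out.extend(self.c_tags)
        return out

    def reassembled(self) -> str:
        return "".join(s.sequence for s in self.segments())


def _validate_residues(record_id: str, residues: str, policy: ResiduePolicy) -> str:
    cleaned = []
    for i, ch in enumerate(residues):
        if ch in GAP_CHARACTERS:
            if policy.strip_gaps:
                continue
            raise ResidueError(
                f"record {record_id!r}: gap character {ch!r} at position {i}"
            )
        if ch not in policy.alphabet:
            raise ResidueError(
                f"record {record_id!r}: disallowed residue {ch!r} at position {i}"
            )
        cleaned.append(ch)
    return "".join(cleaned)


def read_fasta(path, policy: ResiduePolicy = STRICT) -> list[SeqRecord]:
    """Read a FASTA file into a list of :class:`SeqRecord`.

    Order is preserved, residues are uppercased, and every record is
    validated against the residue policy. Malformed input raises
    :class:`FastaParseError` naming the offending line.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    with path.open() as handle:
        first = handle.read(1)
        if first and first not in ">;\n":
            raise FastaParseError(f"{path}: line 1 does not start a FASTA entry")
        handle.seek(0)
        seen: set[str] = set()
        for rec in _BioSeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            residues = _validate_residues(rec.id, str(rec.seq).upper(), policy)
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            records.append(SeqRecord(id=rec.id, residues=residues, description=desc))
    return records


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    """Write records as FASTA, wrapped at 80 columns. Round trips with
    :func:`read_fasta`."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with Path(path).open("w") as handle:
        writer = _BioSeqIO.FastaIO.FastaWriter(handle, wrap=FASTA_WRAP)
        writer.write_file(bio)


def write_table(rows: Sequence[dict], path, format: str = "tsv") -> None:
    """Write a list of dict rows with a header and stable column order
    (first-seen order across rows)."""
    path = Path(path)
    columns: list[str] = []
    for row in rows:
        for key in row:
            if key not in columns:
                columns.append(key)
    fmt = format.lower()
    if fmt == "json":
        path.write_text(json.dumps(list(rows), indent=2, ensure_ascii=False) + "\n")
        return
    delim = {"tsv": "\t", "csv": ","}.get(fmt)
    if delim is None:
        raise ValueError(f"unknown table format {format!r}")
    with path.open("w", newline="") as handle:
        writer = csv.DictWriter(handle, fieldnames=columns, delimiter=delim)
        writer.writeheader()
        writer.writerows(rows)


def _strip_tags(sequence: str, tag_library, terminus: str):
    """Peel exact-matching library tags off one terminus, outermost first."""
    found = []
    offset_moved = 0
    changed = True
    while changed:
        changed = False
        for tag in tag_library:
            ts = tag.sequence
            if terminus == "N" and sequence.startswith(ts):
                found.append((tag.name, ts, offset_moved))
                offset_moved += len(ts)
                sequence = sequence[len(ts):]
                changed = True
                break
            if terminus == "C" and sequence.endswith(ts):
                found.append((tag.name, ts))
                sequence = sequence[: -len(ts)]
                changed = True
                break
    return found, sequence


def parse_scfv(
    record: SeqRecord,
    tag_library: Sequence = (),
    *,
    extra_linker_alphabet: str = "",
    min_linker_length: int = MIN_LINKER_LENGTH,
) -> ConstructParts:
    """Decompose a full-length scFv sequence into tags, two variable
    domains and the interdomain linker.

    Tags are identified by exact match against ``tag_library`` at the
    termini. The linker is the run of residues from the {G,S,D,E} family
    (plus any declared extras), strictly longer than ``min_linker_length``,
    lying between the two numbering-positive domain segments. Fv-only
    inputs (a single domain, no linker) are returned with ``linker`` and
    ``domain2`` unset.
    """
    seq = record.residues
    alphabet = LINKER_ALPHABET | set(extra_linker_alphabet.upper())

    n_found, core = _strip_tags(seq, tag_library, "N")
    c_found, core = _strip_tags(core, tag_library, "C")

    try:
        domains = numbering.extract_fv(core)
    except NotAnAntibodyError as exc:
        raise NotAnAntibodyError(f"record {record.id!r}: {exc}") from exc

    parts = ConstructParts()
    cursor = 0
    for name, ts, *_ in n_found:
        parts.n_tags.append(Segment(name, ts, cursor, cursor + len(ts)))
        cursor += len(ts)

    if len(domains) == 1:
        dom = domains[0]
        d_start, d_end = dom.source_span
        if d_start != 0 or d_end != len(core):
            # absorb unclaimed flanking residues into the domain segment so
            # the concatenation invariant holds
            d_start, d_end = 0, len(core)
        parts.domain1 = Segment("domain1", core[d_start:d_end],
                                cursor, cursor + (d_end - d_start))
        parts.domain1_role = dom.chain_class
    elif len(domains) >= 2:
        if len(domains) > 2:
            raise NotAnAntibodyError(
                f"record {record.id!r}: found {len(domains)} domains, expected 2"
            )
        d1, d2 = domains
        gap = core[d1.source_span[1]: d2.source_span[0]]
        gap_start = d1.source_span[1]
        runs = _alphabet_runs(gap, alphabet, min_linker_length)
        if len(runs) > 1:
            raise AmbiguousLinkerError(
                [(gap_start + a, gap_start + b) for a, b in runs]
            )
        if not runs or runs[0] != (0, len(gap)):
            bad = sorted(set(gap) - alphabet)
            raise NotAnAntibodyError(
                f"record {record.id!r}: interdomain region {gap!r} is not a "
                f"linker (length must exceed {min_linker_length}; residues "
                f"outside linker alphabet: {bad})"
            )
        d1_seq = core[: d1.source_span[1]]
        d2_seq = core[d2.source_span[0]:]
        parts.domain1 = Segment("domain1", d1_seq, cursor, cursor + len(d1_seq))
        parts.domain1_role = d1.chain_class
        cursor2 = cursor + len(d1_seq)
        parts.linker = Segment("linker", gap, cursor2, cursor2 + len(gap))
        cursor2 += len(gap)
        parts.domain2 = Segment("domain2", d2_seq, cursor2, cursor2 + len(d2_seq))
        parts.domain2_role = d2.chain_class

    cursor = len(seq) - sum(len(t[1]) for t in c_found)
    for name, ts in reversed(c_found):
        parts.c_tags.append(Segment(name, ts, cursor, cursor + len(ts)))
        cursor += len(ts)

    assert parts.reassembled() == seq, "concatenation invariant violated"
    return parts


def _alphabet_runs(gap: str, alphabet, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of alphabet residues with length > min_len."""
    runs = []
    i = 0
    while i < len(gap):
        if gap[i] in alphabet:
            j = i
            while j < len(gap) and gap[j] in alphabet:
                j += 1
            if j - i > min_len:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs
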