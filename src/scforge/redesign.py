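"""Inverse-folding support: fixed-position masks, candidate validation,
charge-based ranking and ensemble statistics.

Masks address Chothia positions and are resolved to concrete 0-based
indices of the assembled construct. Candidates are same-length sequences
from an external generator; validation enforces fixed positions,
cysteine retention and the conserved framework salt bridges. Ranking is
predicted solubility first, generator rank second, sequence third —
total and deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from . import physchem, solubility
from .construct import ScFvConstruct
from .numbering import SALT_BRIDGES, segment_regions

#: Fixed Chothia ranges (inclusive) per mask mode.
MASK_MODES: dict[str, dict] = {
    "cdr_only": {
        "VL": ((24, 34), (50, 56), (89, 97)),
        "VH": ((25, 32), (52, 56), (95, 102)),
        "fix_linker": False,
    },
    "extended": {
        "VL": ((24, 36), (47, 56), (86, 97)),
        "VH": ((26, 59), (91, 105)),
        "fix_linker": False,
    },
    "production": {
        "VL": ((24, 56), (86, 100)),
        "VH": ((26, 56), (92, 105)),
        "fix_linker": True,
    },
}


@dataclass(frozen=True)
class FixedMask:
    mode: str
    vl_ranges: tuple[tuple[int, int], ...]
    vh_ranges: tuple[tuple[int, int], ...]
    fix_linker: bool

    @classmethod
    def from_mode(cls, mode: str) -> "FixedMask":
        spec = MASK_MODES[mode]
        return cls(
            mode=mode,
            vl_ranges=tuple(spec["VL"]),
            vh_ranges=tuple(spec["VH"]),
            fix_linker=spec["fix_linker"],
        )


@dataclass(frozen=True)
class ResolvedMask:
    """A mask resolved against one construct's concrete indices."""

    mask: FixedMask
    fixed_indices: frozenset[int]
    labels: dict[int, str] = field(repr=False, default_factory=dict)
    warnings: tuple[str, ...] = ()

    def is_fixed(self, index: int) -> bool:
        return index in self.fixed_indices


@dataclass(frozen=True)
class DesignCandidate:
    sequence: str
    model_rank: int
    model_score: float | None
    predicted_percent: float
    violations: tuple[str, ...]

    @property
    def valid(self) -> bool:
        return not self.violations

    @property
    def net_charge(self) -> int:
        return physchem.net_charge(self.sequence)


@dataclass(frozen=True)
class EnsembleSummary:
    conservation: tuple[float, ...]
    consensus: str
    substituted_fraction: dict[str, float]  # per chain, non-fixed positions
    parent_framework_charge: dict[str, int]
    consensus_framework_charge: dict[str, int]
    n_candidates: int


def build_fixed_mask(construct: ScFvConstruct, mode: str) -> ResolvedMask:
    """Resolve a mask mode to construct indices.

    Insertion-coded residues whose base number lies in a fixed range are
    fixed. Range numbers absent from a domain produce a warning, not an
    error.
    """
    mask = FixedMask.from_mode(mode)
    spans = construct.part_offsets()
    fixed: set[int] = set()
    labels: dict[int, str] = {}
    warnings: list[str] = []
    for chain, ranges in (("VL", mask.vl_ranges), ("VH", mask.vh_ranges)):
        domain = construct.vl if chain == "VL" else construct.vh
        start = spans[chain][0]
        present = {r.number for r in domain.residues}
        for lo, hi in ranges:
            for number in range(lo, hi + 1):
                if number not in present:
                    warnings.append(f"{chain} Chothia {number} absent; skipped")
        for i, residue in enumerate(domain.residues):
            if any(lo <= residue.number <= hi for lo, hi in ranges):
                idx = start + i
                fixed.add(idx)
                labels[idx] = f"{chain} {residue.label}"
    if mask.fix_linker:
        lo, hi = spans["linker"]
        for idx in range(lo, hi):
            fixed.add(idx)
            labels[idx] = f"linker {idx - lo + 1}"
    return ResolvedMask(
        mask=mask,
        fixed_indices=frozenset(fixed),
        labels=labels,
        warnings=tuple(warnings),
    )


def _salt_bridge_indices(construct: ScFvConstruct):
    """Global indices of the conserved salt-bridge members present in the
    parent, with their required residue classes."""
    spans = construct.part_offsets()
    out = []
    for chain in ("VL", "VH"):
        domain = construct.vl if chain == "VL" else construct.vh
        start = spans[chain][0]
        (b_pos, b_ok), (a_pos, a_ok) = SALT_BRIDGES[chain]
        for pos, allowed in ((b_pos, b_ok), (a_pos, a_ok)):
            for i, residue in enumerate(domain.residues):
                if residue.number == pos and residue.insertion == "":
                    if residue.amino_acid in allowed:
                        out.append((start + i, allowed, f"{chain} {pos}"))
                    break
    return out


def validate_candidate(
    parent: ScFvConstruct,
    candidate_sequence: str,
    mask: ResolvedMask,
    model_rank: int = 0,
    model_score: float | None = None,
) -> DesignCandidate:
    """Check a same-length candidate against fixed positions, cysteine
    retention and the framework salt bridges."""
    parent_seq = parent.full_sequence
    cand = candidate_sequence.upper()
    if len(cand) != len(parent_seq):
        raise ValueError(
            f"candidate length {len(cand)} != parent length {len(parent_seq)}"
        )
    violations: list[str] = []
    for idx in sorted(mask.fixed_indices):
        if cand[idx] != parent_seq[idx]:
            label = mask.labels.get(idx, str(idx))
            violations.append(
                f"fixed position {label}: {parent_seq[idx]}->{cand[idx]}"
            )
    for idx, aa in enumerate(parent_seq):
        if aa == "C" and cand[idx] != "C":
            violations.append(f"cysteine lost at index {idx}")
    for idx, allowed, label in _salt_bridge_indices(parent):
        if cand[idx] not in allowed:
            violations.append(
                f"salt-bridge residue {label}: {parent_seq[idx]}->{cand[idx]}"
            )
    percent = solubility.predict_percent(physchem.net_charge(cand))
    return DesignCandidate(
        sequence=cand,
        model_rank=model_rank,
        model_score=model_score,
        predicted_percent=percent,
        violations=tuple(violations),
    )


def rank_candidates(
    candidates: list[DesignCandidate], weight: float | None = None
) -> tuple[list[DesignCandidate], list[DesignCandidate]]:
    """Order valid candidates by predicted solubility (descending), ties
    by generator rank (ascending), residual ties lexicographically.

    ``weight`` switches to a blended score
    (percent - weight * model_rank, descending). Returns
    (ranked_valid, excluded_invalid).
    """
    valid = [c for c in candidates if c.valid]
    invalid = [c for c in candidates if not c.valid]
    if weight is None:
        key = lambda c: (-c.predicted_percent, c.model_rank, c.sequence)
    else:
        key = lambda c: (-(c.predicted_percent - weight * c.model_rank), c.sequence)
    return sorted(valid, key=key), invalid


def _chain_index_sets(construct: ScFvConstruct):
    spans = construct.part_offsets()
    return {
        chain: set(range(*spans[chain])) for chain in ("VL", "VH")
    }


def _framework_indices(construct: ScFvConstruct) -> dict[str, list[int]]:
    spans = construct.part_offsets()
    out: dict[str, list[int]] = {}
    for chain in ("VL", "VH"):
        domain = construct.vl if chain == "VL" else construct.vh
        segmented = segment_regions(domain) if domain.regions is None else domain
        start = spans[chain][0]
        out[chain] = [
            start + i
            for i, region in enumerate(segmented.regions)
            if region.startswith("FR")
        ]
    return out


def _charge_at(seq: str, indices: list[int]) -> int:
    sub = "".join(seq[i] for i in indices)
    return physchem.net_charge(sub)


def ensemble_summary(
    parent: ScFvConstruct,
    candidates: list[DesignCandidate],
    mask: ResolvedMask,
) -> EnsembleSummary:
    """Per-position conservation, modal consensus (ties keep the parent
    residue), per-chain substitution fraction over non-fixed positions,
    and the framework net-charge shift from parent to consensus."""
    valid = [c for c in candidates if c.valid]
    if not valid:
        raise ValueError("ensemble_summary needs at least one valid candidate")
    parent_seq = parent.full_sequence
    n = len(valid)
    conservation = []
    consensus_chars = []
    for i, parent_aa in enumerate(parent_seq):
        column = [c.sequence[i] for c in valid]
        counts = Counter(column)
        conservation.append(counts.get(parent_aa, 0) / n)
        top = counts.most_common()
        best_count = top[0][1]
        winners = {aa for aa, k in top if k == best_count}
        consensus_chars.append(parent_aa if parent_aa in winners else top[0][0])
    consensus = "".join(consensus_chars)

    chain_sets = _chain_index_sets(parent)
    substituted = {}
    for chain, indices in chain_sets.items():
        non_fixed = sorted(indices - mask.fixed_indices)
        if not non_fixed:
            substituted[chain] = 0.0
            continue
        changed = sum(1 for i in non_fixed if consensus[i] != parent_seq[i])
        substituted[chain] = changed / len(non_fixed)

    fr = _framework_indices(parent)
    return EnsembleSummary(
        conservation=tuple(conservation),
        consensus=consensus,
        substituted_fraction=substituted,
        parent_framework_charge={c: _charge_at(parent_seq, fr[c]) for c in fr},
        consensus_framework_charge={c: _charge_at(consensus, fr[c]) for c in fr},
        n_candidates=n,
    )


def load_candidates(records) -> list[tuple[str, int, float | None]]:
    """Interpret a multi-FASTA ensemble: ordinal position is the model
    rank unless 'score=<x>' keys are present in descriptions, in which
    case ranks follow ascending score order (generator convention:
    lower score is better)."""
    scores: list[float | None] = []
    for rec in records:
        score = None
        for token in rec.description.split():
            if token.startswith("score="):
                try:
                    score = float(token[len("score="):])
                except ValueError:
                    pass
        scores.append(score)
    if all(s is not None for s in scores) and scores:
        order = sorted(range(len(records)), key=lambda i: scores[i])
        ranks = {i: r + 1 for r, i in enumerate(order)}
    else:
        ranks = {i: i + 1 for i in range(len(records))}
    return [
        (records[i].residues, ranks[i], scores[i]) for i in range(len(records))
    ]
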