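"""Deterministic generators of test inputs: variable-domain pairs with
controllable charge composition, mask-respecting design ensembles and
noisy linear charge-to-solubility datasets.

Every generator is a pure function of its arguments; randomness flows
through a single seeded ``numpy`` generator.
"""

from __future__ import annotations

import numpy as np

from . import numbering, physchem, seqio
from ._templates import template_by_chain
from .construct import ScFvConstruct
from .errors import GenerationError
from .redesign import ResolvedMask, _salt_bridge_indices

#: Chothia positions never touched by the Fv generator: conserved
#: cysteines, the FR2 tryptophan, the framework salt bridge, FR4 anchor,
#: plus the two terminal residues of each domain (terminal substitutions
#: would let downstream linker detection trim the domain boundary).
_PROTECTED_POSITIONS = {
    "VH": {1, 2, 22, 36, 66, 86, 92, 103, 112, 113},
    "VL": {1, 2, 23, 35, 61, 82, 88, 98, 106, 107},
}

_MUTABLE_AA = "ACDEFGHIKLMNPQRSTVWY"


def _adjust_charge(chars, indices, target, rng):
    """Nudge the residues at ``indices`` until their summed counting
    charge equals ``target``; each step changes one residue by one
    charge unit."""
    def charge():
        return physchem.net_charge("".join(chars[i] for i in indices))

    guard = 0
    while charge() != target:
        delta = target - charge()
        if delta > 0:
            up = [i for i in indices if chars[i] in "DE"]
            neutral = [i for i in indices if chars[i] not in "DEKR"]
            pool = up or neutral
            if not pool:
                raise GenerationError("charge target unreachable (no raisable site)")
            i = pool[rng.integers(len(pool))]
            chars[i] = "G" if chars[i] in "DE" else "K"
        else:
            down = [i for i in indices if chars[i] in "KR"]
            neutral = [i for i in indices if chars[i] not in "DEKR"]
            pool = down or neutral
            if not pool:
                raise GenerationError("charge target unreachable (no lowerable site)")
            i = pool[rng.integers(len(pool))]
            chars[i] = "G" if chars[i] in "KR" else "D"
        guard += 1
        if guard > 10 * len(chars) + 100:
            raise GenerationError("charge adjustment did not converge")


from functools import lru_cache


@lru_cache(maxsize=4)
def _template_domain(chain_type: str):
    tpl = template_by_chain(chain_type)
    domain = numbering.segment_regions(numbering.number_domain(tpl.sequence))
    return domain


def generate_fv(
    seed: int = 0,
    target_charge: int | None = None,
    region_charges: dict[str, int] | None = None,
    light_chain: str = "VL-kappa",
    id_prefix: str = "synthfv",
) -> tuple[seqio.SeqRecord, seqio.SeqRecord]:
    """A paired VL/VH with controllable charge composition.

    ``target_charge`` fixes the combined (VL+VH) counting charge;
    ``region_charges`` maps keys among {"vl_framework", "vl_cdr",
    "vh_framework", "vh_cdr"} to exact per-region-class charges (applied
    before any overall target). Outputs start from the embedded templates
    and always renumber with identity region boundaries.
    """
    rng = np.random.default_rng(seed)
    domains = {"VL": _template_domain(light_chain), "VH": _template_domain("VH")}
    chars: dict[str, list[str]] = {
        c: list(d.sequence) for c, d in domains.items()
    }
    mutable: dict[str, dict[str, list[int]]] = {}
    region_all: dict[str, dict[str, list[int]]] = {}
    for chain, domain in domains.items():
        protected = _PROTECTED_POSITIONS[chain]
        fr, cdr = [], []
        fr_all, cdr_all = [], []
        for i, (residue, region) in enumerate(zip(domain.residues, domain.regions)):
            (cdr_all if region.startswith("CDR") else fr_all).append(i)
            if residue.number in protected and residue.insertion == "":
                continue
            (cdr if region.startswith("CDR") else fr).append(i)
        mutable[chain] = {"framework": fr, "cdr": cdr}
        region_all[chain] = {"framework": fr_all, "cdr": cdr_all}

    if region_charges:
        for key, target in region_charges.items():
            chain, kind = key.split("_")
            chain = chain.upper()
            # the target addresses the whole region class; immutable
            # residues contribute a fixed offset
            immutable = [
                i for i in region_all[chain][kind]
                if i not in set(mutable[chain][kind])
            ]
            fixed_part = physchem.net_charge(
                "".join(chars[chain][i] for i in immutable)
            )
            _adjust_charge(
                chars[chain], mutable[chain][kind], target - fixed_part, rng
            )

    if target_charge is not None:
        fixed_sets = set()
        if region_charges:
            for key in region_charges:
                chain, kind = key.split("_")
                fixed_sets.add((chain.upper(), kind))
        free = [
            (chain, i)
            for chain in ("VL", "VH")
            for kind in ("framework", "cdr")
            if (chain, kind) not in fixed_sets
            for i in mutable[chain][kind]
        ]
        if not free and physchem.net_charge(
            "".join(chars["VL"]) + "".join(chars["VH"])
        ) != target_charge:
            raise GenerationError("target charge conflicts with region targets")
        # operate on the concatenation through a combined index space
        combined = chars["VL"] + chars["VH"]
        offset = len(chars["VL"])
        idx = [i if c == "VL" else offset + i for c, i in free]
        _adjust_charge(combined, idx, target_charge - _charge_outside(combined, idx), rng)
        chars["VL"] = combined[:offset]
        chars["VH"] = combined[offset:]

    vl_seq = "".join(chars["VL"])
    vh_seq = "".join(chars["VH"])
    meta = f"seed={seed} target_charge={target_charge} region_charges={region_charges}"
    return (
        seqio.SeqRecord(id=f"{id_prefix}_VL", residues=vl_seq, description=meta),
        seqio.SeqRecord(id=f"{id_prefix}_VH", residues=vh_seq, description=meta),
    )


def _charge_outside(chars, indices) -> int:
    inside = set(indices)
    return physchem.net_charge(
        "".join(c for i, c in enumerate(chars) if i not in inside)
    )


def generate_ensemble(
    parent: ScFvConstruct,
    mask: ResolvedMask,
    n: int = 10,
    substitution_rate: float = 0.1,
    charge_bias: float = 0.0,
    seed: int = 0,
) -> list[str]:
    """``n`` candidate sequences substituting only at non-fixed
    positions; cysteines and salt-bridge residues are never touched, so
    every output passes validation.

    ``charge_bias`` in [-1, 0] is the probability that a substitution at
    a K/R site specifically installs D/E (emulating solubility-directed
    redesign); 0 draws uniformly."""
    rng = np.random.default_rng(seed)
    parent_seq = parent.full_sequence
    protected = set(mask.fixed_indices)
    protected.update(i for i, aa in enumerate(parent_seq) if aa == "C")
    protected.update(idx for idx, _, _ in _salt_bridge_indices(parent))
    candidates: list[str] = []
    alphabet = [aa for aa in _MUTABLE_AA if aa != "C"]
    for _ in range(n):
        chars = list(parent_seq)
        for i, aa in enumerate(parent_seq):
            if i in protected or rng.random() >= substitution_rate:
                continue
            if charge_bias < 0 and aa in "KR" and rng.random() < -charge_bias:
                chars[i] = "D" if rng.random() < 0.5 else "E"
            else:
                options = [c for c in alphabet if c != aa]
                chars[i] = options[rng.integers(len(options))]
        candidates.append("".join(chars))
    return candidates


def generate_solubility_dataset(
    n: int = 45,
    slope: float = -4.6237,
    intercept: float = 8.2469,
    noise_sd: float = 10.0,
    charge_range: tuple[int, int] = (-20, 3),
    seed: int = 0,
) -> list[tuple[int, float]]:
    """(charge, percent) pairs from the linear model plus Gaussian noise,
    truncated to [0, 100]."""
    if n < 3:
        raise GenerationError("dataset needs n >= 3")
    rng = np.random.default_rng(seed)
    lo, hi = charge_range
    charges = rng.integers(lo, hi + 1, size=n)
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    out = []
    for c, e in zip(charges, noise):
        y = slope * int(c) + intercept + float(e)
        out.append((int(c), min(100.0, max(0.0, y))))
    return out
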