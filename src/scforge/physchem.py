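"""Sequence physicochemical properties.

Net charge is the integer counting formula (K+R)-(D+E); the pH 5.5
variant adds histidines: (K+R+H)-(D+E). The isoelectric point is solved
by bisection of the Henderson-Hasselbalch total charge for each
configured pKa table and averaged across tables. GRAVY is the mean
Kyte-Doolittle hydropathy, and the aliphatic index is the unweighted
mole percent of A/V/I/L (deliberately not the classical Ikai weighted
form; ``weighted=True`` gives the Ikai variant).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ResidueError, UndefinedPIError

_POSITIVE = "KR"
_NEGATIVE = "DE"

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Average residue masses (Da) of amino acids within a peptide chain.
_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
_WATER_MASS = 18.0153

#: Two published pKa scales; the reported pI is their mean. Keys: "Nterm",
#: "Cterm" and the ionizable side chains.
PKA_TABLES: dict[str, dict[str, float]] = {
    # Bjellqvist-style scale (as used by common web calculators)
    "bjellqvist": {
        "Nterm": 7.50, "Cterm": 3.55,
        "K": 10.00, "R": 12.00, "H": 5.98,
        "D": 4.05, "E": 4.45, "C": 9.00, "Y": 10.00,
    },
    # IPC protein-optimised scale
    "ipc_protein": {
        "Nterm": 9.094, "Cterm": 2.869,
        "K": 9.052, "R": 11.84, "H": 5.637,
        "D": 3.872, "E": 4.412, "C": 7.555, "Y": 10.85,
    },
}


@dataclass(frozen=True)
class PhyschemProfile:
    """The per-sequence property bundle emitted by :func:`profile`."""

    length: int
    net_charge: int
    charge_ph55: int
    pI: float
    gravy: float
    aliphatic_index: float
    mass: float


@dataclass(frozen=True)
class RegionChargeSummary:
    """Integer net charge per region for a VL/VH pair.

    Invariant: framework_total + cdr_total equals the summed domain net
    charge for each chain.
    """

    vl: dict[str, int]
    vh: dict[str, int]
    vl_framework_total: int
    vl_cdr_total: int
    vh_framework_total: int
    vh_cdr_total: int


def _check(seq: str) -> str:
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in KYTE_DOOLITTLE and ch != "X":
            raise ResidueError(f"disallowed residue {ch!r} at position {i}")
    return seq


def net_charge(seq: str) -> int:
    """(K+R)-(D+E): the counting net charge at physiological pH."""
    seq = _check(seq)
    return sum(seq.count(c) for c in _POSITIVE) - sum(seq.count(c) for c in _NEGATIVE)


def charge_ph55(seq: str) -> int:
    """(K+R+H)-(D+E): counting charge at pH 5.5 (histidines protonated)."""
    return net_charge(seq) + _check(seq).count("H")


def _hh_charge(seq: str, pH: float, pka: dict[str, float], free_termini: bool) -> float:
    pos = 0.0
    neg = 0.0
    if free_termini:
        pos += 1.0 / (1.0 + 10 ** (pH - pka["Nterm"]))
        neg += 1.0 / (1.0 + 10 ** (pka["Cterm"] - pH))
    for aa in "KRH":
        pos += seq.count(aa) / (1.0 + 10 ** (pH - pka[aa]))
    for aa in "DECY":
        neg += seq.count(aa) / (1.0 + 10 ** (pka[aa] - pH))
    return pos - neg


def henderson_hasselbalch_charge(
    seq: str, pH: float, table: str = "bjellqvist", free_termini: bool = True
) -> float:
    """Fractional net charge at a given pH under one pKa table."""
    return _hh_charge(_check(seq), pH, PKA_TABLES[table], free_termini)


def _bisect_pi(seq: str, pka: dict[str, float], free_termini: bool) -> float:
    lo, hi = 0.0, 14.0
    f_lo = _hh_charge(seq, lo, pka, free_termini)
    f_hi = _hh_charge(seq, hi, pka, free_termini)
    if f_lo <= 0.0:
        return lo
    if f_hi >= 0.0:
        return hi
    # converge on interval width, not on |charge|: titration curves can be
    # nearly flat around the root, where an |charge| < 1e-4 stop would land
    # far from the actual zero crossing
    while (hi - lo) > 1e-8:
        mid = 0.5 * (lo + hi)
        if _hh_charge(seq, mid, pka, free_termini) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def isoelectric_point(
    seq: str,
    pka_tables: dict[str, dict[str, float]] | None = None,
    free_termini: bool = True,
) -> float:
    """pH at which the modelled net charge is zero, averaged across the
    configured pKa tables."""
    seq = _check(seq)
    tables = pka_tables if pka_tables is not None else PKA_TABLES
    has_ionizable = free_termini or any(c in "KRHDECY" for c in seq)
    if not has_ionizable:
        raise UndefinedPIError("no ionizable groups and termini are blocked")
    values = [_bisect_pi(seq, pka, free_termini) for pka in tables.values()]
    return sum(values) / len(values)


def gravy(seq: str) -> float:
    """Mean Kyte-Doolittle hydropathy per residue ('X' excluded)."""
    seq = _check(seq)
    counted = [KYTE_DOOLITTLE[c] for c in seq if c != "X"]
    if not counted:
        raise ValueError("gravy undefined on empty sequence")
    return sum(counted) / len(counted)


def aliphatic_index(seq: str, weighted: bool = False) -> float:
    """Mole percent of A, V, I and L ('X' excluded from the denominator).

    ``weighted=True`` switches to the classical Ikai index
    (A + 2.9 V + 3.9 (I+L), as mole-percent weights).
    """
    seq = _check(seq)
    n = sum(1 for c in seq if c != "X")
    if n == 0:
        raise ValueError("aliphatic index undefined on empty sequence")
    if weighted:
        value = (
            seq.count("A")
            + 2.9 * seq.count("V")
            + 3.9 * (seq.count("I") + seq.count("L"))
        )
    else:
        value = seq.count("A") + seq.count("V") + seq.count("I") + seq.count("L")
    return 100.0 * value / n


def mass(seq: str) -> float:
    """Average molecular mass in Da ('X' contributes nothing)."""
    seq = _check(seq)
    return sum(_RESIDUE_MASS.get(c, 0.0) for c in seq) + _WATER_MASS


def profile(seq: str) -> PhyschemProfile:
    seq = _check(seq)
    return PhyschemProfile(
        length=len(seq),
        net_charge=net_charge(seq),
        charge_ph55=charge_ph55(seq),
        pI=isoelectric_point(seq),
        gravy=gravy(seq),
        aliphatic_index=aliphatic_index(seq),
        mass=mass(seq),
    )


_REGIONS = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")


def _per_region(domain) -> dict[str, int]:
    if domain.regions is None:
        raise ValueError("domain must be segmented (see numbering.segment_regions)")
    charges = {r: 0 for r in _REGIONS}
    for residue, region in zip(domain.residues, domain.regions):
        aa = residue.amino_acid
        if aa in _POSITIVE:
            charges[region] += 1
        elif aa in _NEGATIVE:
            charges[region] -= 1
    return charges


def region_charges(vl, vh) -> RegionChargeSummary:
    """Per-region integer net charges for a segmented VL/VH pair."""
    vl_c = _per_region(vl)
    vh_c = _per_region(vh)

    def fr(c):
        return c["FR1"] + c["FR2"] + c["FR3"] + c["FR4"]

    def cdr(c):
        return c["CDR1"] + c["CDR2"] + c["CDR3"]

    return RegionChargeSummary(
        vl=vl_c,
        vh=vh_c,
        vl_framework_total=fr(vl_c),
        vl_cdr_total=cdr(vl_c),
        vh_framework_total=fr(vh_c),
        vh_cdr_total=cdr(vh_c),
    )
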