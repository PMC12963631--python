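"""Embedded Chothia-labelled variable-domain templates.

Each template is a human-germline-derived consensus with an explicit
per-residue Chothia label (number + insertion code). Labels are data, not
computed: the numbering engine transfers them onto query sequences by
global or local alignment. Anchor residues (Cys22/23, Trp35/36, the
framework salt-bridge K/R and D positions, Cys88/92) sit at their
canonical Chothia numbers in every template.
"""

from __future__ import annotations

from dataclasses import dataclass


def _span(lo: int, hi: int) -> list[tuple[int, str]]:
    return [(n, "") for n in range(lo, hi + 1)]


@dataclass(frozen=True)
class Template:
    name: str
    chain_type: str  # "VH" | "VL-kappa" | "VL-lambda"
    sequence: str
    labels: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.labels):
            raise ValueError(
                f"template {self.name}: {len(self.sequence)} residues vs "
                f"{len(self.labels)} labels"
            )


# VH: VH3-family framework, 8-residue CDR3, JH4 FR4. Insertions at 52a and
# 82a-c as in the overwhelming majority of human heavy domains.
_VH_SEQ = (
    "EVQLLESGGGLVQPGGSLRLSCAA"  # FR1 1-24
    "SGFTFSSY"                  # CDR1 25-32
    "AMSWVRQAPGKGLEWVSAI"       # FR2 33-51
    "SGSGGS"                    # CDR2 52,52a,53-56
    "TYYADSVKG"                 # 57-65
    "RFTISRDNSKNTLYLQM"         # 66-82
    "NSL"                       # 82a-82c
    "RAEDTAVYYCAK"              # 83-94
    "DRGYSFDY"                  # CDR3 95-102
    "WGQGTLVTVSS"               # FR4 103-113
)
_VH_LABELS = (
    _span(1, 52)
    + [(52, "a")]
    + _span(53, 82)
    + [(82, "a"), (82, "b"), (82, "c")]
    + _span(83, 113)
)

# VL kappa: VK1 framework (O12-like), 11-residue CDR1, JK FR4; no insertions.
_VK_SEQ = (
    "DIQMTQSPSSLSASVGDRVTITC"  # FR1 1-23
    "RASQSISSYLN"              # CDR1 24-34
    "WYQQKPGKAPKLLIY"          # FR2 35-49
    "AASSLQS"                  # CDR2 50-56
    "GVPSRFSGSGSGTDFTLTISSLQPEDFATYYC"  # FR3 57-88
    "QQSYSTPLT"                # CDR3 89-97
    "FGQGTKVEIK"               # FR4 98-107
)
_VK_LABELS = _span(1, 107)

# VL lambda: VL1 framework; conventional gap at position 10, insertions
# 30a-c in the 14-residue CDR1 and 95a in the 10-residue CDR3.
_VLAM_SEQ = (
    "QSVLTQPPS"          # 1-9 (no residue at 10)
    "VSGAPGQRVTISC"      # 11-23
    "TGSSSNI" "GAG" "YDVH"  # CDR1: 24-30, 30a-c, 31-34
    "WYQQLPGTAPKLLIY"    # FR2 35-49
    "GNSNRPS"            # CDR2 50-56
    "GVPDRFSGSKSGTSASLAITGLQAEDEADYYC"  # FR3 57-88
    "QSYDSSL" "S" "GV"   # CDR3: 89-95, 95a, 96-97
    "FGGGTKLTVL"         # FR4 98-107
)
_VLAM_LABELS = (
    _span(1, 9)
    + _span(11, 30)
    + [(30, "a"), (30, "b"), (30, "c")]
    + _span(31, 95)
    + [(95, "a")]
    + _span(96, 107)
)

TEMPLATES: tuple[Template, ...] = (
    Template("vh3_consensus", "VH", _VH_SEQ, tuple(_VH_LABELS)),
    Template("vk1_consensus", "VL-kappa", _VK_SEQ, tuple(_VK_LABELS)),
    Template("vl1_consensus", "VL-lambda", _VLAM_SEQ, tuple(_VLAM_LABELS)),
)


def template_by_chain(chain_type: str) -> Template:
    for t in TEMPLATES:
        if t.chain_type == chain_type:
            return t
    raise KeyError(chain_type)
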