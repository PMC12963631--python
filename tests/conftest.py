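import pytest

from scforge import construct, numbering, redesign, synthetic
from scforge._templates import template_by_chain

# Trastuzumab VH with its published Chothia labels (insertions at 52a,
# 82a-c and 100a-c) — the external-numbering cross-check fixture.
TRASTUZUMAB_VH = (
    "EVQLVESGGGLVQPGGSLRLSCAASGFNIKDTYIHWVRQAPGKGLEWVARIYPTNGYTRYADSVKG"
    "RFTISADTSKNTAYLQMNSLRAEDTAVYYCSRWGGDGFYAMDYWGQGTLVTVSS"
)


def _span(lo, hi):
    return [(n, "") for n in range(lo, hi + 1)]


TRASTUZUMAB_VH_CHOTHIA = (
    _span(1, 52) + [(52, "a")] + _span(53, 82)
    + [(82, "a"), (82, "b"), (82, "c")]
    + _span(83, 100) + [(100, "a"), (100, "b"), (100, "c")]
    + _span(101, 113)
)

# Human IgG1 CH1 domain: an Ig fold that is not a variable domain.
IGG1_CH1 = (
    "ASTKGPSVFPLAPSSKSTSGGTAALGCLVKDYFPEPVTVSWNSGALTSGVHTFPAVLQSSGLYSLS"
    "SVVTVPSSSLGTQTYICNVNHKPSNTKVDKKV"
)


@pytest.fixture(scope="session")
def vh_template():
    return template_by_chain("VH")


@pytest.fixture(scope="session")
def vk_template():
    return template_by_chain("VL-kappa")


@pytest.fixture(scope="session")
def vl_domain(vk_template):
    return numbering.segment_regions(numbering.number_domain(vk_template.sequence))


@pytest.fixture(scope="session")
def vh_domain(vh_template):
    return numbering.segment_regions(numbering.number_domain(vh_template.sequence))


@pytest.fixture(scope="session")
def vh_domain_no52a(vh_template):
    """VH template with the 52a residue deleted: no insertion codes in
    the mask ranges (82a-c remain, outside every mask range)."""
    i = vh_template.labels.index((52, "a"))
    seq = vh_template.sequence[:i] + vh_template.sequence[i + 1:]
    return numbering.segment_regions(numbering.number_domain(seq))


@pytest.fixture(scope="session")
def fv_pair():
    """Deterministic synthetic VL/VH pair with combined charge +2."""
    vl, vh = synthetic.generate_fv(seed=1, target_charge=2)
    return (
        numbering.number_domain(vl.residues),
        numbering.number_domain(vh.residues),
    )


@pytest.fixture(scope="session")
def scfv(fv_pair):
    vl, vh = fv_pair
    return construct.assemble_scfv(
        vl,
        vh,
        linker="G4D4",
        tags=[construct.DEFAULT_TAGS["3xFLAG"], construct.DEFAULT_TAGS["HA"]],
    )


@pytest.fixture(scope="session")
def production_mask(scfv):
    return redesign.build_fixed_mask(scfv, "production")
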