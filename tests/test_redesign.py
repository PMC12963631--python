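import random

import pytest

from scforge import construct, physchem, redesign, solubility, synthetic
from scforge.redesign import (
    DesignCandidate,
    build_fixed_mask,
    ensemble_summary,
    load_candidates,
    rank_candidates,
    validate_candidate,
)
from scforge.seqio import SeqRecord


@pytest.fixture(scope="module")
def clean_scfv(vh_domain_no52a):
    """Construct whose domains carry no insertion codes inside any mask
    range: mask cardinalities match the pure range arithmetic."""
    from scforge import numbering
    from scforge._templates import template_by_chain

    vl = numbering.number_domain(template_by_chain("VL-kappa").sequence)
    return construct.assemble_scfv(
        vl, vh_domain_no52a, linker="G4D4",
        tags=[construct.DEFAULT_TAGS["3xFLAG"], construct.DEFAULT_TAGS["HA"]],
    )


class TestBuildFixedMask:
    def test_production_counts(self, clean_scfv):
        mask = build_fixed_mask(clean_scfv, "production")
        by_chain = {"VL": 0, "VH": 0, "linker": 0}
        for label in mask.labels.values():
            by_chain[label.split()[0]] += 1
        # VL 24-56 and 86-100 -> 33 + 15; VH 26-56 and 92-105 -> 31 + 14
        assert by_chain["VL"] == 48
        assert by_chain["VH"] == 45
        assert by_chain["linker"] == len(clean_scfv.linker.sequence)
        assert not mask.warnings

    def test_cdr_only_leaves_linker_free(self, clean_scfv):
        mask = build_fixed_mask(clean_scfv, "cdr_only")
        linker_span = clean_scfv.part_offsets()["linker"]
        assert not any(linker_span[0] <= i < linker_span[1]
                       for i in mask.fixed_indices)

    def test_production_fixes_linker(self, clean_scfv):
        mask = build_fixed_mask(clean_scfv, "production")
        linker_span = clean_scfv.part_offsets()["linker"]
        assert all(i in mask.fixed_indices
                   for i in range(linker_span[0], linker_span[1]))

    def test_indices_subset_of_sequence(self, scfv, production_mask):
        assert all(0 <= i < len(scfv.full_sequence)
                   for i in production_mask.fixed_indices)

    def test_insertion_coded_residue_fixed(self, scfv):
        # the VH template carries 52a, inside the production 26-56 range
        mask = build_fixed_mask(scfv, "production")
        assert "VH 52a" in mask.labels.values()

    def test_absent_range_number_warns(self, scfv):
        mask = build_fixed_mask(scfv, "extended")
        # extended VH range reaches 59; template VH has 57-59, VL lacks none;
        # warnings only appear when a range number is missing
        assert isinstance(mask.warnings, tuple)


class TestValidateCandidate:
    def test_identical_is_valid(self, scfv, production_mask):
        cand = validate_candidate(scfv, scfv.full_sequence, production_mask)
        assert cand.valid and cand.violations == ()

    def test_fixed_cdr_substitution_named(self, scfv, production_mask):
        spans = scfv.part_offsets()
        vh_start = spans["VH"][0]
        idx = next(
            vh_start + i for i, r in enumerate(scfv.vh.residues) if r.number == 95
        )
        seq = list(scfv.full_sequence)
        seq[idx] = "W" if seq[idx] != "W" else "F"
        cand = validate_candidate(scfv, "".join(seq), production_mask)
        assert not cand.valid
        assert any("VH 95" in v for v in cand.violations)

    def test_salt_bridge_violation(self, scfv, production_mask):
        spans = scfv.part_offsets()
        vh_start = spans["VH"][0]
        idx = next(
            vh_start + i for i, r in enumerate(scfv.vh.residues)
            if (r.number, r.insertion) == (86, "")
        )
        assert scfv.full_sequence[idx] == "D"
        seq = list(scfv.full_sequence)
        seq[idx] = "N"
        cand = validate_candidate(scfv, "".join(seq), production_mask)
        assert any("salt-bridge" in v and "VH 86" in v for v in cand.violations)

    def test_cysteine_loss(self, scfv, production_mask):
        idx = scfv.full_sequence.index("C")
        seq = list(scfv.full_sequence)
        seq[idx] = "S"
        cand = validate_candidate(scfv, "".join(seq), production_mask)
        assert any("cysteine" in v for v in cand.violations)

    def test_length_mismatch_hard_error(self, scfv, production_mask):
        with pytest.raises(ValueError, match="length"):
            validate_candidate(scfv, scfv.full_sequence + "G", production_mask)

    def test_predicted_percent_matches_asis_prediction(self, scfv, production_mask):
        cand = validate_candidate(scfv, scfv.full_sequence, production_mask)
        expected = solubility.predict_for_sequence(scfv.full_sequence, mode="as-is")
        assert cand.predicted_percent == pytest.approx(expected.percent)


def _candidate(seq: str, rank: int, percent: float | None = None) -> DesignCandidate:
    if percent is None:
        percent = solubility.predict_percent(physchem.net_charge(seq))
    return DesignCandidate(
        sequence=seq, model_rank=rank, model_score=None,
        predicted_percent=percent, violations=(),
    )


class TestRankCandidates:
    def test_charge_order(self):
        seqs = {"D" * 16: -16, "D" * 4 + "G" * 12: -4, "D" * 10 + "G" * 6: -10}
        cands = [_candidate(s, i + 1) for i, s in enumerate(seqs)]
        ranked, _ = rank_candidates(cands)
        assert [physchem.net_charge(c.sequence) for c in ranked] == [-16, -10, -4]

    def test_model_rank_breaks_ties(self):
        a = _candidate("GGDD", 7)
        b = _candidate("DDGG", 2)
        ranked, _ = rank_candidates([a, b])
        assert ranked[0].model_rank == 2

    def test_empty(self):
        assert rank_candidates([]) == ([], [])

    def test_invalid_excluded(self):
        good = _candidate("GGGG", 1)
        bad = DesignCandidate("GGGG", 2, None, 8.2, ("fixed position VH 95",))
        ranked, excluded = rank_candidates([good, bad])
        assert len(ranked) == 1 and len(excluded) == 1

    def test_deterministic_under_shuffle(self):
        rng = random.Random(0)
        base = [
            _candidate("".join(rng.choice("GDEKRS") for _ in range(12)), i + 1)
            for i in range(30)
        ]
        reference = rank_candidates(list(base))[0]
        for seed in range(5):
            shuffled = list(base)
            random.Random(seed).shuffle(shuffled)
            assert rank_candidates(shuffled)[0] == reference

    def test_blended_weight_mode(self):
        a = _candidate("DDGG", 10)   # -2 charge, bad model rank
        b = _candidate("GGGG", 1)    # 0 charge, best model rank
        lexicographic, _ = rank_candidates([a, b])
        assert lexicographic[0] is a
        blended, _ = rank_candidates([a, b], weight=5.0)
        assert blended[0] is b


class TestEnsembleSummary:
    def test_copies_of_parent(self, scfv, production_mask):
        cands = [
            validate_candidate(scfv, scfv.full_sequence, production_mask, i)
            for i in range(5)
        ]
        summary = ensemble_summary(scfv, cands, production_mask)
        assert all(c == 1.0 for c in summary.conservation)
        assert summary.consensus == scfv.full_sequence
        assert summary.substituted_fraction == {"VL": 0.0, "VH": 0.0}

    def test_half_substituted_position(self, scfv, production_mask):
        spans = scfv.part_offsets()
        vh_start = spans["VH"][0]
        # a non-fixed FR3 lysine-free position: Chothia VH 75 (K in template)
        idx = next(
            vh_start + i for i, r in enumerate(scfv.vh.residues)
            if (r.number, r.insertion) == (75, "")
        )
        assert idx not in production_mask.fixed_indices
        mutant = list(scfv.full_sequence)
        mutant[idx] = "D" if mutant[idx] != "D" else "E"
        mutant = "".join(mutant)
        cands = [
            validate_candidate(scfv, s, production_mask, i)
            for i, s in enumerate([scfv.full_sequence] * 5 + [mutant] * 5)
        ]
        summary = ensemble_summary(scfv, cands, production_mask)
        assert summary.conservation[idx] == pytest.approx(0.5)
        # exact tie: consensus keeps the parent residue
        assert summary.consensus[idx] == scfv.full_sequence[idx]

    def test_charge_bias_lowers_consensus_framework_charge(self, scfv, production_mask):
        seqs = synthetic.generate_ensemble(
            scfv, production_mask, n=30, substitution_rate=0.8,
            charge_bias=-0.95, seed=5,
        )
        cands = [
            validate_candidate(scfv, s, production_mask, i)
            for i, s in enumerate(seqs)
        ]
        assert all(c.valid for c in cands)
        summary = ensemble_summary(scfv, cands, production_mask)
        assert (
            summary.consensus_framework_charge["VH"]
            < summary.parent_framework_charge["VH"]
        )

    def test_conservation_one_at_fixed_positions(self, scfv, production_mask):
        seqs = synthetic.generate_ensemble(
            scfv, production_mask, n=20, substitution_rate=0.5, seed=9
        )
        cands = [
            validate_candidate(scfv, s, production_mask, i)
            for i, s in enumerate(seqs)
        ]
        summary = ensemble_summary(scfv, cands, production_mask)
        for idx in production_mask.fixed_indices:
            assert summary.conservation[idx] == 1.0

    def test_needs_valid_candidate(self, scfv, production_mask):
        with pytest.raises(ValueError):
            ensemble_summary(scfv, [], production_mask)


class TestLoadCandidates:
    def test_ordinal_ranks(self):
        records = [SeqRecord(id=f"d{i}", residues="GGGG") for i in range(3)]
        loaded = load_candidates(records)
        assert [r for _, r, _ in loaded] == [1, 2, 3]

    def test_scores_override_ordinals(self):
        records = [
            SeqRecord(id="a", residues="GGGG", description="score=1.2"),
            SeqRecord(id="b", residues="CCCC", description="score=0.3"),
        ]
        loaded = load_candidates(records)
        assert loaded[0] == ("GGGG", 2, 1.2)
        assert loaded[1] == ("CCCC", 1, 0.3)
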