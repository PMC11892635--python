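import itertools

import numpy as np
import pytest

from bicistroscan import construct_audit as ca
from bicistroscan import kozak_model as km

from conftest import make_zero_entropy_pwm, random_pwm

CONSENSUS = "GCCACATGGCGCC"


@pytest.fixture
def refs():
    rng = np.random.default_rng(0)
    return ca.ReferenceDistributions(
        utr_lengths=rng.integers(50, 400, 500).astype(float),
        mono_scores=rng.uniform(1.0, 2.0, 500),
    )


def build_construct(utr, orf1, inter, orf2):
    seq = utr + orf1 + inter + orf2
    s1 = len(utr)
    s2 = s1 + len(orf1) + len(inter)
    return seq, (s1, s1 + len(orf1)), (s2, s2 + len(orf2))


class TestAuditConstruct:
    def test_clean_weak_orf1_construct(self, refs):
        pwm = make_zero_entropy_pwm(CONSENSUS)
        # AUG-free upstream except the ORF1 start; ORF1 context fully off-consensus
        seq, iv1, iv2 = build_construct(
            "TTTTT", "ATGTTTTTTTGA", "CCGCC", "ATGGCGCCCTAA")
        report = ca.audit_construct(seq, iv1, iv2, pwm, refs)
        assert "R3_upstream_aug_present" not in report.flags
        assert "R2_orf1_not_suboptimal" not in report.flags
        assert report.upstream_aug_inventory == []

    def test_extra_inter_orf_aug_flagged(self, refs):
        pwm = make_zero_entropy_pwm(CONSENSUS)
        seq, iv1, iv2 = build_construct(
            "TTTTT", "ATGTTTTTTTGA", "ATGCC", "ATGGCGCCCTAA")
        report = ca.audit_construct(seq, iv1, iv2, pwm, refs)
        assert len(report.upstream_aug_inventory) == 1
        pos, region, _frame, _score = report.upstream_aug_inventory[0]
        assert region == "inter_orf"
        assert "R3_upstream_aug_present" in report.flags

    def test_consensus_orf1_percentile_100(self, refs):
        pwm = make_zero_entropy_pwm(CONSENSUS)
        # ORF1 flank == PWM consensus -> score 2.0, above every reference score
        seq, iv1, iv2 = build_construct(
            "TGCCAC", "ATGGCGCCTTGA", "TTTTT", "ATGTTTCCCTAA")
        report = ca.audit_construct(seq, iv1, iv2, pwm, refs)
        assert report.orf1_score == pytest.approx(2.0)
        assert report.orf1_percentile == pytest.approx(100.0)
        assert "R2_orf1_not_suboptimal" in report.flags
        # brute-force percentile oracle
        frac = np.mean(refs.mono_scores < 2.0) * 100
        assert report.orf1_percentile == pytest.approx(frac)

    def test_overlapping_orfs_error(self, refs):
        pwm = make_zero_entropy_pwm(CONSENSUS)
        with pytest.raises(ValueError):
            ca.audit_construct("ATGATGATGATG", (0, 9), (6, 12), pwm, refs)


class TestTuneKozak:
    def test_consensus_strengthen_empty(self):
        rng = np.random.default_rng(1)
        pwm = random_pwm(rng)
        res = ca.tune_kozak(pwm.consensus(), pwm, "strengthen",
                            mutable_positions=km.FLANK_INDICES, max_edits=2)
        assert res.variants == []
        assert res.note is not None

    def test_zero_entropy_single_edit_drop(self):
        pwm = make_zero_entropy_pwm(CONSENSUS)
        res = ca.tune_kozak(CONSENSUS, pwm, "weaken",
                            mutable_positions=(0,), max_edits=1)
        # column height is 1.0 * 2 bits; one mismatch drops exactly 2/10
        assert len(res.variants) == 3
        for _v, score in res.variants:
            assert score == pytest.approx(2.0 - 0.2)

    def test_weaken_postcondition(self):
        rng = np.random.default_rng(2)
        pwm = random_pwm(rng)
        site = pwm.sample_sites(1, rng)[0]
        base = km.bit_score(site, pwm)
        res = ca.tune_kozak(site, pwm, "weaken", max_edits=2)
        assert res.variants
        for v, score in res.variants:
            assert score < base
            assert km.bit_score(v, pwm) == pytest.approx(score)

    def test_upstream_only_default(self):
        rng = np.random.default_rng(3)
        pwm = random_pwm(rng)
        site = pwm.sample_sites(1, rng)[0]
        res = ca.tune_kozak(site, pwm, "weaken", max_edits=1)
        for v, _s in res.variants:
            assert v[5:] == site[5:]  # downstream half untouched

    def test_bad_direction(self):
        pwm = make_zero_entropy_pwm(CONSENSUS)
        with pytest.raises(ValueError):
            ca.tune_kozak(CONSENSUS, pwm, "sideways")


def oracle_synonymous(codon):
    from Bio.Seq import Seq
    aa = str(Seq(codon).translate())
    return sorted(
        "".join(c) for c in itertools.product("ACGT", repeat=3)
        if "".join(c) != codon and str(Seq("".join(c)).translate()) == aa
    )


class TestSuggestAugRemoval:
    def test_in_frame_met_to_leu(self):
        orf = "ATGAAAATGCCCTAA"   # internal Met codon at index 2
        (sug,) = ca.suggest_aug_removal(orf)
        assert sug.consequence == "nonsynonymous"
        assert sug.edit == ("ATG", "CTG")
        assert sug.sequence == "ATGAAACTGCCCTAA"

    def test_out_of_frame_synonymous(self):
        orf = "ATGGATGCATAA"      # ATG spanning codons GAT|GCA (frame 1)
        (sug,) = ca.suggest_aug_removal(orf)
        assert sug.consequence == "synonymous"
        old, new = sug.edit
        assert new in oracle_synonymous(old)
        assert ca.count_aug(sug.sequence) < ca.count_aug(orf)

    def test_clean_orf_empty(self):
        assert ca.suggest_aug_removal("ATGCCCAAATAA") == []

    def test_length_validation(self):
        with pytest.raises(ValueError):
            ca.suggest_aug_removal("ATGAA")

    def test_fewer_augs_property(self):
        rng = np.random.default_rng(4)
        lut = np.array(list("ACGT"))
        for _ in range(50):
            body = "".join(lut[rng.integers(0, 4, 60)])
            orf = "ATG" + body + "TAA"
            n0 = ca.count_aug(orf)
            for sug in ca.suggest_aug_removal(orf):
                if sug.sequence is not None:
                    assert ca.count_aug(sug.sequence) < n0


class TestClosure:
    """Every suggested fix, re-audited, clears the flag it was raised for."""

    def test_r3_closure_via_aug_removal(self, refs):
        pwm = make_zero_entropy_pwm(CONSENSUS)
        orf1 = "ATGTTTATGTTTTGA"   # internal in-frame ATG -> R3
        seq, iv1, iv2 = build_construct("TTTTT", orf1, "CCCCC", "ATGGCGCCCTAA")
        report = ca.audit_construct(seq, iv1, iv2, pwm, refs)
        assert "R3_upstream_aug_present" in report.flags
        fixed_orf1 = orf1
        for sug in ca.suggest_aug_removal(fixed_orf1):
            if sug.sequence is not None:
                fixed_orf1 = sug.sequence
                break
        seq2, iv1b, iv2b = build_construct("TTTTT", fixed_orf1, "CCCCC",
                                           "ATGGCGCCCTAA")
        report2 = ca.audit_construct(seq2, iv1b, iv2b, pwm, refs)
        assert "R3_upstream_aug_present" not in report2.flags

    def test_r2_closure_via_weaken(self, refs):
        pwm = make_zero_entropy_pwm(CONSENSUS)
        seq, iv1, iv2 = build_construct("TGCCAC", "ATGGCGCCTTGA", "TTTTT",
                                        "ATGTTTCCCTAA")
        report = ca.audit_construct(seq, iv1, iv2, pwm, refs)
        assert "R2_orf1_not_suboptimal" in report.flags
        s1 = iv1[0]
        window = km.start_site_window(seq, s1)
        res = ca.tune_kozak(window, pwm, "weaken", max_edits=3)
        fixed = None
        thresholds = ca.RuleThresholds()
        for v, score in res.variants:
            pct = np.mean(refs.mono_scores < score) * 100
            if pct <= thresholds.orf1_max_percentile:
                fixed = v
                break
        assert fixed is not None
        # splice the new upstream flank back into the construct
        new_seq = seq[: s1 - 5] + fixed[:5] + seq[s1:]
        report2 = ca.audit_construct(new_seq, iv1, iv2, pwm, refs)
        assert "R2_orf1_not_suboptimal" not in report2.flags
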