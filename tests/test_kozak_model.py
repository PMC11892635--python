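import itertools
import math

import numpy as np
import pytest

from bicistroscan import kozak_model as km
from bicistroscan import transcript_io as tio

from conftest import make_uniform_pwm, make_zero_entropy_pwm, random_pwm


def oracle_bit_score(site, pwm):
    """Independent re-statement: renormalized mean of p*R over scorable flanks."""
    total, n = 0.0, 0
    for i in km.FLANK_INDICES:
        if site[i] in "ACGT":
            total += pwm.probs[i, "ACGT".index(site[i])] * pwm.info[i]
            n += 1
    if (10 - n) > 3:
        return None
    return total / n


class TestBuildPwm:
    def test_zero_entropy_limit(self):
        sites = ["GCCACATGGCGCC"] * 50
        pwm = km.build_pwm(sites, pseudocount=1e-12)
        for i in km.FLANK_INDICES:
            assert pwm.info[i] == pytest.approx(2.0, abs=1e-6)

    def test_uniform_position_zero_info(self):
        sites = [b + "CCAC" + "ATG" + "GCGCC" for b in "ACGT"]
        pwm = km.build_pwm(sites, pseudocount=0.0)
        assert pwm.info[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_entropy_example(self):
        # frequencies (0.5, 0.25, 0.25, 0) at position 0: H=1.5, R=0.5
        sites = [b + "CCAC" + "ATG" + "GCGCC" for b in "AACG"]
        pwm = km.build_pwm(sites, pseudocount=0.0)
        assert pwm.probs[0].tolist() == [0.5, 0.25, 0.25, 0.0]
        assert pwm.info[0] == pytest.approx(0.5)

    def test_probability_normalization(self):
        rng = np.random.default_rng(0)
        sites = random_pwm(rng).sample_sites(200, rng)
        pwm = km.build_pwm(sites, pseudocount=0.5)
        assert np.allclose(pwm.probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(pwm.info >= -1e-12) and np.all(pwm.info <= 2 + 1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            km.build_pwm([])

    def test_malformed_site_names_index(self):
        good = "GCCACATGGCGCC"
        with pytest.raises(ValueError, match="site 1"):
            km.build_pwm([good, "GCCACTTGGCGCC"])
        with pytest.raises(ValueError, match="site 0"):
            km.build_pwm(["GCNACATGGCGCC"])


class TestBitScore:
    def test_uniform_pwm_scores_zero(self):
        pwm = make_uniform_pwm()
        assert km.bit_score("GCCACATGGCGCC", pwm) == pytest.approx(0.0)

    def test_range_endpoints(self):
        pwm = make_zero_entropy_pwm("GCCACATGGCGCC")
        assert km.bit_score("GCCACATGGCGCC", pwm) == pytest.approx(2.0)
        assert km.bit_score("ATTGAATGATATT", pwm) == pytest.approx(0.0)

    def test_single_informative_position(self):
        # one flank with probs (0.5,0.25,0.25,0), all others uniform:
        # site carrying the 0.5-base scores (0.5*0.5)/10 = 0.025
        pwm = make_uniform_pwm()
        pwm.probs[0] = [0.5, 0.25, 0.25, 0.0]
        pwm.info[0] = 0.5
        assert km.bit_score("ACCACATGGCGCC", pwm) == pytest.approx(0.025)
        # brute force over the 4 possible bases at that position
        for b in "ACGT":
            site = b + "CCACATGGCGCC"
            assert km.bit_score(site, pwm) == pytest.approx(oracle_bit_score(site, pwm))

    def test_n_handling(self):
        rng = np.random.default_rng(1)
        pwm = random_pwm(rng)
        site = "NNNACATGGCGCC"   # 3 unscorable flanks: renormalized
        assert km.bit_score(site, pwm) == pytest.approx(oracle_bit_score(site, pwm))
        assert km.bit_score("NNNNCATGGCGCC", pwm) is None  # 4 -> missing

    def test_length_error(self):
        with pytest.raises(ValueError):
            km.bit_score("ATG", make_uniform_pwm())

    def test_exhaustive_oracle_small_k(self):
        rng = np.random.default_rng(7)
        pwm = random_pwm(rng)
        base = pwm.consensus()
        vary = (0, 2, 4, 8, 11)
        for combo in itertools.product("ACGT", repeat=len(vary)):
            chars = list(base)
            for pos, b in zip(vary, combo):
                chars[pos] = b
            site = "".join(chars)
            assert km.bit_score(site, pwm) == pytest.approx(
                oracle_bit_score(site, pwm), abs=1e-12)


class TestConsensusMaximality:
    def test_consensus_is_argmax(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            pwm = random_pwm(rng)
            cmax = pwm.max_score()
            for site in pwm.sample_sites(50, rng):
                assert km.bit_score(site, pwm) <= cmax + 1e-12


class TestPwmRecovery:
    def test_probs_recovered_within_002(self):
        rng = np.random.default_rng(11)
        truth = random_pwm(rng, concentration=2.0)
        sites = truth.sample_sites(10_000, rng)
        rebuilt = km.build_pwm(sites, pseudocount=0.5)
        for i in km.FLANK_INDICES:
            assert np.all(np.abs(rebuilt.probs[i] - truth.probs[i]) <= 0.02)


class TestLocusProfile:
    def make_regions(self, utr, orf1, inter, orf2, utr3="TT"):
        R = tio.Region
        a = len(utr)
        b = a + len(orf1)
        c = b + len(inter)
        d = c + len(orf2)
        return tio.RegionSet(
            "t", R(0, a, utr), R(a, b, orf1), R(b, c, inter),
            R(c, d, orf2), R(d, d + len(utr3), utr3))

    def test_no_internal_atg(self):
        pwm = make_uniform_pwm()
        rs = self.make_regions("CCCCCCC", "ATGGGGTGA", "CCCCC", "ATGCCCTAA")
        prof = km.locus_kozak_profile(rs, pwm)
        assert prof.internal_sites == []

    def test_one_internal_atg_with_frame(self):
        pwm = make_uniform_pwm()
        # extra ATG inside ORF1 at offset +3 from the ORF1 start (frame 0)
        rs = self.make_regions("CCCCCCC", "ATGATGGGGTGA", "CCCCC", "ATGCCCTAA")
        prof = km.locus_kozak_profile(rs, pwm)
        assert len(prof.internal_sites) == 1
        pos, frame, _score = prof.internal_sites[0]
        assert pos == 10 and frame == 0
        # exhaustive 3-mer scan oracle
        mrna = rs.mrna
        s2 = rs.orf2.start
        expected = [p for p in range(s2 - 2)
                    if mrna[p:p + 3] == "ATG" and p != rs.orf1.start]
        assert [p for p, _f, _s in prof.internal_sites] == expected

    def test_equal_scores_ratio_one(self):
        # both start sites carry the full consensus window -> ratio exactly 1
        pwm = make_zero_entropy_pwm("GCCACATGGCGCC")
        rs = self.make_regions("GCCAC", "ATGGCGCCTTGA", "GCCAC", "ATGGCGCCTTAA")
        prof = km.locus_kozak_profile(rs, pwm)
        assert prof.orf1_score == pytest.approx(2.0)
        assert prof.orf2_score == pytest.approx(2.0)
        assert prof.ratio == pytest.approx(1.0)

    def test_monocistronic_rejected(self):
        R = tio.Region
        rs = tio.RegionSet("t", R(0, 3, "CCC"), R(3, 9, "ATGTAA"),
                           None, None, R(9, 9, ""))
        with pytest.raises(ValueError, match="not bicistronic"):
            km.locus_kozak_profile(rs, make_uniform_pwm())


class TestSplitTrainEval:
    def test_even_split_deterministic(self):
        ids = [f"g{i}" for i in range(10)]
        t1, e1 = km.split_train_eval(ids, seed=1)
        t2, e2 = km.split_train_eval(ids, seed=1)
        assert (t1, e1) == (t2, e2)
        assert len(t1) == len(e1) == 5
        assert set(t1) | set(e1) == set(ids)
        assert set(t1) & set(e1) == set()

    def test_odd_split_extra_to_eval(self):
        t, e = km.split_train_eval([f"g{i}" for i in range(11)], seed=0)
        assert len(t) == 5 and len(e) == 6

    def test_different_seeds_differ(self):
        ids = [f"g{i}" for i in range(100)]
        splits = {tuple(km.split_train_eval(ids, seed=s)[0]) for s in range(5)}
        assert len(splits) == 5

    def test_too_few_errors(self):
        with pytest.raises(ValueError):
            km.split_train_eval(["only"], seed=0)


class TestSerialization:
    def test_json_roundtrip(self):
        rng = np.random.default_rng(9)
        pwm = random_pwm(rng)
        back = km.KozakPWM.from_json(pwm.to_json())
        assert np.allclose(back.probs, pwm.probs)
        assert np.allclose(back.info, pwm.info)
        assert back.window_offsets == pwm.window_offsets


class TestPlantedRatioSeparation:
    def test_bicistrons_vs_colinear_controls(self, trained_pwm_world):
        from bicistroscan import bicistron_detect as bd
        from bicistroscan.stats_core import wilcoxon_rank_sum

        world, pwm, _ev = trained_pwm_world
        by_tid = {m.transcript_id: m for m in world.models}
        ratios = []
        for rec in world.truth.itertuples():
            if rec.locus_class != "bicistronic_exclusive":
                continue
            rs = tio.extract_regions(by_tid[rec.transcript_id], world.genome)
            ratios.append(km.locus_kozak_profile(rs, pwm).ratio)
        mono_models = [by_tid[r.transcript_id] for r in world.truth.itertuples()
                       if r.locus_class == "monocistronic"]
        pairs = bd.colinear_mono_pairs(mono_models, 5000)
        rng = np.random.default_rng(2)
        controls = []
        for i in rng.choice(len(pairs), size=40, replace=False):
            up, down, _gap = pairs[i]
            su = km.start_site_score(tio.extract_regions(up, world.genome), pwm)
            sd = km.start_site_score(tio.extract_regions(down, world.genome), pwm)
            if su is not None and sd is not None and sd > 0:
                controls.append(su / sd)
        ratios = ratios[:40]
        assert np.median(ratios) < 1.0
        assert 0.9 <= np.median(controls) <= 1.1
        assert wilcoxon_rank_sum(ratios, controls).p_value < 0.05
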