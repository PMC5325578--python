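import random

import pytest

from oracles import oracle_candidates, oracle_revcomp, oracle_score
from paredeg.target_scoring import (GU, MISMATCH, WC, DuplexAlignment,
                                    find_candidates, format_duplex,
                                    scan_best_hits, score_duplex)

L = 21


def states_with(**overrides):
    states = [WC] * L
    for pos, st in overrides.get("at", {}).items():
        states[pos - 1] = st
    return states


class TestScoreDuplex:
    def test_perfect_duplex_scores_zero(self):
        assert score_duplex([WC] * L) == 0.0

    def test_wobble_outside_core_region(self):
        states = states_with(at={15: GU})
        assert oracle_score(states) == 0.5
        assert score_duplex(states) == 0.5

    def test_mismatch_inside_core_region_doubled(self):
        states = states_with(at={5: MISMATCH})
        assert oracle_score(states) == 2.0
        assert score_duplex(states) == 2.0

    def test_bulge_charges_position_weight(self):
        assert score_duplex([WC] * L, bulges=(15,)) == 1.0
        assert score_duplex([WC] * L, bulges=(5,)) == 2.0

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError):
            score_duplex(["??"] + [WC] * (L - 1))

    def test_matches_oracle_on_random_states(self):
        rng = random.Random(5)
        pool = [WC, GU, MISMATCH, "gap_target"]
        for _ in range(200):
            states = [rng.choice(pool) for _ in range(L)]
            bulges = tuple(rng.sample(range(1, L), rng.randint(0, 1)))
            assert score_duplex(states, bulges) == oracle_score(states, bulges)


class TestFindCandidates:
    def test_planted_perfect_site_scores_zero(self, rng):
        from conftest import random_seq
        mirna = random_seq(rng, L)
        window = oracle_revcomp(mirna)
        transcript = random_seq(rng, 80) + window + random_seq(rng, 80)
        hits = find_candidates("m", mirna, "t", transcript)
        perfect = [h for h in hits if h.score == 0.0]
        assert len(perfect) == 1
        h = perfect[0]
        assert (h.start, h.end) == (81, 81 + L - 1)
        assert h.site == 81 + L - 10  # base paired with miRNA position 10
        assert all(s == WC for s in h.pair_states)

    def test_all_candidates_respect_cutoff_and_slicing_site(self, rng):
        from conftest import random_seq
        mirna = random_seq(rng, L)
        transcript = random_seq(rng, 400)
        for h in find_candidates("m", mirna, "t", transcript, max_score=7.0):
            assert h.score <= 7.0
            assert h.pair_states[9] == WC and h.pair_states[10] == WC
            assert 10 not in h.bulges

    def test_mutated_slicing_site_not_called(self, rng):
        from conftest import random_seq
        mirna = random_seq(rng, L)
        window = list(oracle_revcomp(mirna))
        # corrupt the base paired with miRNA position 10 (window offset L-10)
        # with one that neither Watson-Crick pairs nor wobbles with it
        m10 = mirna[9]
        allowed = {"A": "T", "T": "AG", "C": "G", "G": "CT"}[m10]
        window[L - 10] = next(b for b in "ACGT" if b not in allowed)
        transcript = "ACGT" * 20 + "".join(window) + "ACGT" * 20
        site = 81 + L - 10
        ungapped = [h for h in find_candidates("m", mirna, "t", transcript)
                    if h.site == site and not h.bulges
                    and "gap_target" not in h.pair_states]
        assert ungapped == []

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError):
            find_candidates("m", "ACGTACGTAC", "t", "A" * 100)

    def test_lowering_cutoff_never_adds_candidates(self, rng):
        from conftest import random_seq
        mirna = random_seq(rng, L)
        transcript = random_seq(rng, 300)
        loose = {(h.start, h.end, h.site, h.score, h.pair_states, h.bulges)
                 for h in find_candidates("m", mirna, "t", transcript, 7.0)}
        tight = {(h.start, h.end, h.site, h.score, h.pair_states, h.bulges)
                 for h in find_candidates("m", mirna, "t", transcript, 3.0)}
        assert tight <= loose

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_exhaustive_enumeration(self, seed):
        rng = random.Random(seed)
        from conftest import random_seq
        mirna = random_seq(rng, L)
        transcript = random_seq(rng, 60) + oracle_revcomp(mirna) + \
            random_seq(rng, 60)  # <= 200 nt, guaranteed at least one hit
        got = {(h.start, h.end, h.site, h.score, h.pair_states, h.bulges)
               for h in find_candidates("m", mirna, "t", transcript, 7.0)}
        expected = oracle_candidates(mirna, transcript, 7.0)
        assert got == expected
        assert got  # the planted window guarantees a non-empty space

    def test_u_and_t_alphabets_equivalent(self, rng):
        from conftest import random_seq
        mirna = random_seq(rng, L)
        transcript = random_seq(rng, 70) + oracle_revcomp(mirna) + \
            random_seq(rng, 30)
        a = find_candidates("m", mirna, "t", transcript)
        b = find_candidates("m", mirna.replace("T", "U"), "t", transcript)
        assert [(h.site, h.score) for h in a] == [(h.site, h.score) for h in b]


class TestGaplessScan:
    def test_agrees_with_ungapped_enumeration(self, rng):
        from conftest import random_seq
        mirna = random_seq(rng, L)
        transcript = random_seq(rng, 50) + oracle_revcomp(mirna) + \
            random_seq(rng, 50)
        hits = scan_best_hits(mirna, transcript, max_score=7.0)
        expected = {}
        for s, e, site, score, states, bulges in oracle_candidates(
                mirna, transcript, 7.0, allow_gaps=False):
            expected[site] = min(expected.get(site, 99.0), score)
        assert hits == expected


def test_format_duplex_notation(rng):
    from conftest import random_seq
    mirna = random_seq(rng, L)
    window = oracle_revcomp(mirna)
    aln = DuplexAlignment("m", mirna, "t", 1, L, tuple([WC] * L), (), 0.0,
                          L - 9)
    text = format_duplex(aln, window)
    lines = text.splitlines()
    assert lines[1].strip() == ":" * L  # all Watson-Crick pairs
    assert window in lines[0]
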