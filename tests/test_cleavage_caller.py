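import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import oracle_categorize, oracle_revcomp
from paredeg.cleavage_caller import (DegradomeProfile, build_profile,
                                     build_profiles, call_targets,
                                     categorize, empirical_pvalue,
                                     pvalue_from_counts, site_location)
from paredeg.target_scoring import WC, DuplexAlignment, find_candidates


def profile(counts, tid="tx", total=10**6):
    return DegradomeProfile(tid, dict(counts), total)


class TestCategorize:
    @pytest.mark.parametrize("counts,site,expected", [
        ({100: 5, 200: 2}, 100, 0),                    # unique maximum
        ({100: 5, 200: 5, 300: 1}, 100, 1),            # tied maximum
        ({100: 3, 200: 5, 300: 1, 400: 1}, 100, 2),    # above median 2
        ({100: 1, 200: 7}, 100, 4),                    # single tag
        ({100: 2, 200: 7, 300: 2, 400: 2}, 100, 3),    # at median 2
    ])
    def test_printed_ladder(self, counts, site, expected):
        assert categorize(profile(counts), site) == expected

    def test_unsupported_site_rejected(self):
        with pytest.raises(ValueError):
            categorize(profile({10: 3}), 99)

    def test_matches_brute_force_on_random_profiles(self):
        rng = random.Random(99)
        for _ in range(400):
            n = rng.randint(1, 12)
            counts = {rng.randint(1, 500): rng.randint(1, 20)
                      for _ in range(n)}
            site = rng.choice(list(counts))
            assert categorize(profile(counts), site) == \
                oracle_categorize(counts, site)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.dictionaries(st.integers(1, 100), st.integers(1, 30),
                           min_size=1, max_size=10),
           st.integers(0, 9))
    def test_ladder_total_and_exclusive(self, counts, pick):
        site = sorted(counts)[pick % len(counts)]
        cat = categorize(profile(counts), site)
        assert cat in (0, 1, 2, 3, 4)
        assert cat == oracle_categorize(counts, site)

    def test_raising_count_never_worsens_category(self):
        rng = random.Random(7)
        for _ in range(100):
            counts = {rng.randint(1, 99): rng.randint(1, 15)
                      for _ in range(rng.randint(2, 8))}
            site = rng.choice(list(counts))
            if counts[site] < 2:
                counts[site] = 2
            before = categorize(profile(counts), site)
            bumped = dict(counts)
            bumped[site] += rng.randint(1, 10)
            assert categorize(profile(bumped), site) <= before


class TestProfiles:
    def test_counts_sum_by_position(self):
        prof = build_profile([("s1", 100, 3), ("s2", 100, 2),
                              ("s3", 200, 1)], "tx", 1000)
        assert prof.counts == {100: 5, 200: 1}

    def test_no_hits_empty_profile(self):
        assert build_profile([], "tx", 1000).counts == {}

    def test_grouped_by_transcript(self):
        profs = build_profiles([("s", "a", 10, 2), ("s", "b", 10, 4)], 100)
        assert profs["a"].counts == {10: 2} and profs["b"].counts == {10: 4}


class TestCallTargets:
    def _candidate(self, tid, site, score=0.0, mirna="m1"):
        return DuplexAlignment(mirna, "A" * 21, tid, site - 11, site + 9,
                               tuple([WC] * 21), (), score, site)

    def test_supported_candidate_called_with_category(self):
        profs = {"tx": profile({50: 5, 80: 2})}
        recs = call_targets([self._candidate("tx", 50)], profs)
        assert len(recs) == 1
        r = recs[0]
        assert (r.site, r.category, r.location) == (50, 0, "CDS")
        assert r.tp100m == pytest.approx(5 / 10**6 * 1e8)

    def test_unsupported_candidate_dropped(self):
        profs = {"tx": profile({50: 5})}
        assert call_targets([self._candidate("tx", 60)], profs) == []

    def test_same_site_keeps_best_score(self):
        profs = {"tx": profile({50: 5})}
        recs = call_targets([self._candidate("tx", 50, 3.0),
                             self._candidate("tx", 50, 1.0)], profs)
        assert [r.score for r in recs] == [1.0]

    def test_utr_locations_from_sidecar(self):
        profs = {"tx": profile({5: 3, 50: 3, 95: 3})}
        cands = [self._candidate("tx", s) for s in (5, 50, 95)]
        recs = call_targets(cands, profs, {"tx": (10, 90)})
        assert [r.location for r in recs] == ["5UTR", "CDS", "3UTR"]

    def test_location_rule(self):
        assert site_location(5, (10, 90)) == "5UTR"
        assert site_location(90, (10, 90)) == "CDS"
        assert site_location(91, (10, 90)) == "3UTR"
        assert site_location(1, None) == "CDS"


class TestEmpiricalPvalue:
    def test_add_one_estimator(self):
        assert pvalue_from_counts(0, 99) == pytest.approx(0.01)
        assert pvalue_from_counts(99, 99) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            pvalue_from_counts(0, 0)

    def test_planted_perfect_site_is_significant(self, rng):
        from conftest import random_seq
        mirna = random_seq(rng, 21)
        transcripts = {f"t{i}": random_seq(rng, 300) for i in range(8)}
        window = oracle_revcomp(mirna)
        transcripts["t0"] = transcripts["t0"][:100] + window + \
            transcripts["t0"][100 + len(window):]
        site = 101 + 21 - 10
        profiles = {"t0": profile({site: 10, 30: 1}, "t0")}
        cands = find_candidates("m", mirna, "t0", transcripts["t0"])
        recs = call_targets(cands, profiles)
        rec = next(r for r in recs if r.site == site)
        p = empirical_pvalue(rec, mirna, transcripts, profiles,
                             shuffles=50, seed=4)
        assert p < 0.1

    def test_pvalue_within_unit_interval(self, rng):
        from conftest import random_seq
        mirna = random_seq(rng, 21)
        transcripts = {"t0": random_seq(rng, 200)}
        profiles = {"t0": profile({50: 4}, "t0")}
        from paredeg.cleavage_caller import TargetRecord
        rec = TargetRecord("m", "t0", 50, "CDS", 7.0, 4, 1.0)
        p = empirical_pvalue(rec, mirna, transcripts, profiles,
                             shuffles=20, seed=1)
        assert 0.0 < p <= 1.0
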