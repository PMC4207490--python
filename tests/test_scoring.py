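"""Similarity scoring: weights, pairwise score, and the brute-force oracle."""

import itertools
import random

import pytest

from bmclocus import (
    CorpusPfamStats,
    ScoringParams,
    cooccurrence_weight,
    distance_weight,
    identifying_weight,
    pairwise_score,
    rare_weight,
    score_all_pairs,
)

from conftest import make_profile


def naive_score(profile_i, profile_j, corpus_sets, params):
    """Independent evaluation of the composed score on explicit sets.

    corpus_sets: locus_id -> set of pfams (the scoring corpus).
    Distance weight: 1 - 0.1*min(d, 4); rarity R(p) = fraction of corpus loci
    lacking p (floored at params.rare_floor on the positive side);
    identifying boost for configured pfams; disjoint pfams damped by
    (1 - F(p|C)) with F the frequency of p among loci containing C.
    """
    n = len(corpus_sets)
    set_i, set_j = set(profile_i.distances), set(profile_j.distances)
    common = set_i & set_j

    def wd(d):
        return 1.0 - 0.1 * min(d, 4)

    def rare(p):
        return 1.0 - sum(p in s for s in corpus_sets.values()) / n

    def wid(p):
        return params.identifying_boost if p in params.identifying_pfams else 1.0

    pos = 0.0
    for p in common:
        pos += (
            wid(p)
            * max(rare(p), params.rare_floor)
            * 0.5 * (wd(profile_i.distances[p]) + wd(profile_j.distances[p]))
        )
    neg = 0.0
    for private, prof in ((set_i - set_j, profile_i), (set_j - set_i, profile_j)):
        for p in private:
            supersets = [s for s in corpus_sets.values() if common <= s]
            f = sum(p in s for s in supersets) / len(supersets) if supersets else 0.0
            neg += wid(p) * rare(p) * wd(prof.distances[p]) * (1.0 - f)
    return pos - params.k * neg


def random_corpus(rng, n_loci=None, n_pfams=None):
    n_loci = n_loci or rng.randint(3, 8)
    n_pfams = n_pfams or rng.randint(4, 12)
    pfams = [f"PF{i:05d}" for i in range(n_pfams)]
    profiles = []
    for i in range(n_loci):
        chosen = rng.sample(pfams, rng.randint(1, n_pfams))
        profiles.append(
            make_profile(f"L{i:02d}", {p: rng.randint(0, 6) for p in chosen})
        )
    return profiles


class TestDistanceWeight:
    @pytest.mark.parametrize(
        "d,expected",
        [(0, 1.0), (1, 0.9), (2, 0.8), (3, 0.7), (4, 0.6), (9, 0.6)],
    )
    def test_linear_decay_with_floor(self, d, expected):
        assert distance_weight(d) == pytest.approx(expected)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            distance_weight(-1)


class TestRareWeight:
    def test_ubiquitous_pfam_weight_is_zero(self):
        profiles = [make_profile(f"L{i}", {"PFX": 0}) for i in range(50)]
        stats = CorpusPfamStats.from_profiles(profiles)
        assert rare_weight("PFX", stats) == 0.0

    def test_one_of_ten(self):
        profiles = [make_profile("L0", {"PFX": 0})] + [
            make_profile(f"L{i}", {"PFY": 0}) for i in range(1, 10)
        ]
        stats = CorpusPfamStats.from_profiles(profiles)
        assert rare_weight("PFX", stats) == pytest.approx(0.9)

    def test_strictly_below_one_for_any_corpus_pfam(self):
        rng = random.Random(5)
        for _ in range(20):
            profiles = random_corpus(rng)
            stats = CorpusPfamStats.from_profiles(profiles)
            for p in stats.pfam_counts:
                assert 0.0 <= rare_weight(p, stats) < 1.0

    def test_unknown_pfam_treated_as_singleton_with_warning(self, caplog):
        profiles = [make_profile(f"L{i}", {"PFX": 0}) for i in range(10)]
        stats = CorpusPfamStats.from_profiles(profiles)
        with caplog.at_level("WARNING", logger="bmclocus"):
            assert rare_weight("PFNEW", stats) == pytest.approx(0.9)
        assert "PFNEW" in caplog.text


class TestIdentifyingWeight:
    def test_boost_for_identifying_pfam(self):
        assert identifying_weight("PF00596", ScoringParams()) == 2.0

    def test_neutral_for_ordinary_pfam(self):
        assert identifying_weight("PF99999", ScoringParams()) == 1.0

    def test_boost_of_one_disables(self):
        params = ScoringParams(identifying_boost=1.0)
        assert identifying_weight("PF00596", params) == 1.0


class TestCooccurrenceWeight:
    def _stats(self, sets):
        profiles = [
            make_profile(f"L{i}", {p: 0 for p in s}) for i, s in enumerate(sets)
        ]
        return CorpusPfamStats.from_profiles(profiles)

    def test_always_cooccurring_gives_full_downweight(self):
        stats = self._stats([{"a", "b", "x"}, {"a", "b", "x"}, {"a", "b", "x"}])
        assert cooccurrence_weight("x", frozenset({"a", "b"}), stats) == 1.0

    def test_one_of_five_superset_loci(self):
        sets = [{"a", "x"}, {"a"}, {"a"}, {"a"}, {"a"}]
        stats = self._stats(sets)
        assert cooccurrence_weight("x", frozenset({"a"}), stats) == pytest.approx(0.2)

    def test_empty_common_gives_overall_frequency(self):
        sets = [{"x"}, {"y"}, {"y"}, {"x", "y"}]
        stats = self._stats(sets)
        assert cooccurrence_weight("x", frozenset(), stats) == pytest.approx(0.5)


class TestPairwiseScore:
    def test_identical_profiles_have_no_negative(self):
        profiles = [
            make_profile("A", {"p1": 0, "p2": 1}),
            make_profile("B", {"p1": 0, "p2": 1}),
            make_profile("C", {"p3": 0}),
        ]
        stats = CorpusPfamStats.from_profiles(profiles)
        b = pairwise_score(profiles[0], profiles[1], stats)
        assert b.negative == 0.0
        assert b.score == b.positive >= 0.0

    def test_disjoint_profiles_never_positive(self):
        profiles = [
            make_profile("A", {"p1": 0}),
            make_profile("B", {"p2": 0}),
            make_profile("C", {"p1": 0, "p2": 0}),
        ]
        stats = CorpusPfamStats.from_profiles(profiles)
        b = pairwise_score(profiles[0], profiles[1], stats)
        assert b.positive == 0.0
        assert b.score <= 0.0

    def test_matches_brute_force_oracle_on_random_corpora(self):
        rng = random.Random(17)
        params = ScoringParams()
        for _ in range(60):
            profiles = random_corpus(rng)
            stats = CorpusPfamStats.from_profiles(profiles)
            corpus_sets = {p.locus_id: set(p.distances) for p in profiles}
            for a, b in itertools.combinations(profiles, 2):
                got = pairwise_score(a, b, stats, params).score
                expected = naive_score(a, b, corpus_sets, params)
                assert got == pytest.approx(expected, abs=1e-9)

    def test_symmetry_is_exact(self):
        rng = random.Random(23)
        for _ in range(20):
            profiles = random_corpus(rng)
            stats = CorpusPfamStats.from_profiles(profiles)
            for a, b in itertools.combinations(profiles, 2):
                assert (
                    pairwise_score(a, b, stats).score
                    == pairwise_score(b, a, stats).score
                )

    def test_shared_pfam_never_decreases_score(self):
        rng = random.Random(31)
        for _ in range(20):
            profiles = random_corpus(rng, n_pfams=8)
            stats = CorpusPfamStats.from_profiles(profiles)
            a, b = profiles[0], profiles[1]
            base = pairwise_score(a, b, stats).score
            a2 = make_profile(a.locus_id, {**a.distances, "PFNEW_SH": 0})
            b2 = make_profile(b.locus_id, {**b.distances, "PFNEW_SH": 0})
            stats2 = CorpusPfamStats.from_profiles([a2, b2] + profiles[2:])
            # corpus stats held fixed except the two loci gaining the pfam
            assert pairwise_score(a2, b2, stats2).score >= base - 1e-12

    def test_private_pfam_never_increases_score(self):
        rng = random.Random(37)
        for _ in range(20):
            profiles = random_corpus(rng, n_pfams=8)
            stats = CorpusPfamStats.from_profiles(profiles)
            a, b = profiles[0], profiles[1]
            base = pairwise_score(a, b, stats).score
            a2 = make_profile(a.locus_id, {**a.distances, "PFNEW_PRIV": 0})
            stats2 = CorpusPfamStats.from_profiles([a2] + profiles[1:])
            assert pairwise_score(a2, b, stats2).score <= base + 1e-12

    def test_k_zero_makes_all_scores_nonnegative(self):
        rng = random.Random(41)
        profiles = random_corpus(rng, n_loci=8)
        params = ScoringParams(k=0.0)
        for b in score_all_pairs(profiles, params=params):
            assert b.score >= 0.0

    def test_component_sets_partition_the_union(self):
        rng = random.Random(43)
        profiles = random_corpus(rng)
        for b in score_all_pairs(profiles):
            union = b.common | b.only_i | b.only_j
            assert not (b.common & b.only_i)
            assert not (b.common & b.only_j)
            assert not (b.only_i & b.only_j)
            assert union == b.common | b.only_i | b.only_j


class TestScoreAllPairs:
    def test_pair_count(self):
        rng = random.Random(47)
        profiles = random_corpus(rng, n_loci=4)
        assert len(score_all_pairs(profiles)) == 6

    def test_permutation_invariance(self):
        rng = random.Random(53)
        profiles = random_corpus(rng, n_loci=6)
        baseline = {
            (b.locus_i, b.locus_j): b.score for b in score_all_pairs(profiles)
        }
        shuffled = profiles[:]
        rng.shuffle(shuffled)
        assert {
            (b.locus_i, b.locus_j): b.score for b in score_all_pairs(shuffled)
        } == baseline

    def test_requires_two_profiles(self):
        with pytest.raises(ValueError):
            score_all_pairs([make_profile("A", {"p": 0})])
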