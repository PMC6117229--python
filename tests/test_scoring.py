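"""Additive candidate scoring: scaling, combination, grouping, ranking."""

import random

import pytest

from msready.scoring import (
    CandidateScore,
    ScoringConfig,
    combined_score,
    group_candidates,
    rank,
    scale_metadata,
    score_candidates,
)

BLOCKS = [
    "AAAAAAAAAAAAAA", "BBBBBBBBBBBBBB", "CCCCCCCCCCCCCC",
    "DDDDDDDDDDDDDD", "EEEEEEEEEEEEEE",
]


def _key(block):
    return f"{block}-UHFFFAOYSA-N"


def _candidate(ident, block=None, **kw):
    return CandidateScore(ident, inchikey=_key(block or BLOCKS[0]), **kw)


class TestScaleMetadata:
    def test_divide_by_max_worked_values(self):
        cands = [
            _candidate("A", metadata={"ds": 3880}),
            _candidate("B", metadata={"ds": 1560}),
            _candidate("C", metadata={"ds": 182}),
        ]
        cfg = ScoringConfig(metadata_categories=("ds",))
        scaled = scale_metadata(cands, "ds", cfg)
        assert scaled["A"] == pytest.approx(1.0)
        assert scaled["B"] == pytest.approx(1560 / 3880)
        assert scaled["C"] == pytest.approx(182 / 3880)

    def test_missing_values_score_zero(self):
        cands = [
            _candidate("A", metadata={"ds": 10}),
            _candidate("B", metadata={}),
        ]
        cfg = ScoringConfig(metadata_categories=("ds",))
        assert scale_metadata(cands, "ds", cfg)["B"] == 0.0

    def test_all_missing_category_scores_all_zero(self):
        cands = [_candidate("A"), _candidate("B")]
        cfg = ScoringConfig(metadata_categories=("ds",))
        assert set(scale_metadata(cands, "ds", cfg).values()) == {0.0}

    def test_single_candidate_scores_one(self):
        cands = [_candidate("A", metadata={"ds": 7})]
        cfg = ScoringConfig(metadata_categories=("ds",))
        assert scale_metadata(cands, "ds", cfg)["A"] == 1.0

    def test_constant_nonzero_category_scores_one_under_divide_by_max(self):
        cands = [_candidate("A", metadata={"ds": 5}), _candidate("B", metadata={"ds": 5})]
        cfg = ScoringConfig(metadata_categories=("ds",))
        assert set(scale_metadata(cands, "ds", cfg).values()) == {1.0}

    def test_min_max_option(self):
        cands = [
            _candidate("A", metadata={"ds": 30}),
            _candidate("B", metadata={"ds": 20}),
            _candidate("C", metadata={"ds": 10}),
        ]
        cfg = ScoringConfig(metadata_categories=("ds",), scaling="min-max")
        scaled = scale_metadata(cands, "ds", cfg)
        assert scaled == {"A": 1.0, "B": 0.5, "C": 0.0}

    def test_negative_values_rejected(self):
        cands = [_candidate("A", metadata={"ds": -3})]
        cfg = ScoringConfig(metadata_categories=("ds",))
        with pytest.raises(ValueError, match="negative"):
            scale_metadata(cands, "ds", cfg)

    def test_inactive_category_rejected(self):
        cfg = ScoringConfig(metadata_categories=("ds",))
        with pytest.raises(ValueError):
            scale_metadata([_candidate("A")], "other", cfg)


class TestCombinedScore:
    def test_maximum_with_five_categories_is_seven(self):
        cfg = ScoringConfig(metadata_categories=("a", "b", "c", "d", "e"))
        assert cfg.max_score == 7.0
        cand = _candidate(
            "X", fragmenter=1.0, spectral_similarity=1.0,
            metadata={c: 42 for c in "abcde"},
        )
        score_candidates([cand], cfg)
        assert cand.combined == pytest.approx(7.0)

    def test_core_only_bound_is_two(self):
        cfg = ScoringConfig()
        cand = _candidate("X", fragmenter=1.0, spectral_similarity=1.0)
        assert combined_score(cand, cfg) == pytest.approx(2.0)
        assert cfg.max_score == 2.0

    def test_hand_summed_example(self):
        cfg = ScoringConfig(metadata_categories=("m1", "m2", "m3"))
        cand = _candidate("X", fragmenter=0.8, spectral_similarity=0.5774)
        cand.scaled = {"m1": 1.0, "m2": 0.0, "m3": 0.5}
        assert combined_score(cand, cfg) == pytest.approx(2.8774)

    def test_weight_for_inactive_category_rejected(self):
        with pytest.raises(ValueError):
            ScoringConfig(weights={"nope": 2.0})

    def test_bound_property_random_configs(self):
        rng = random.Random(7)
        for _ in range(50):
            cats = tuple(f"c{i}" for i in range(rng.randint(0, 5)))
            weights = {c: rng.uniform(0, 3) for c in cats}
            cfg = ScoringConfig(metadata_categories=cats, weights=weights)
            cands = [
                _candidate(
                    f"X{j}",
                    fragmenter=rng.random(),
                    spectral_similarity=rng.random(),
                    metadata={c: rng.choice([None, rng.uniform(0, 100)]) for c in cats},
                )
                for j in range(rng.randint(1, 6))
            ]
            score_candidates(cands, cfg)
            for c in cands:
                assert 0.0 <= c.combined <= cfg.max_score + 1e-9

    def test_raising_non_max_value_never_decreases_score(self):
        cfg = ScoringConfig(metadata_categories=("ds",))
        base = [
            _candidate("A", metadata={"ds": 100}),
            _candidate("B", metadata={"ds": 40}),
        ]
        score_candidates(base, cfg)
        before = base[1].combined
        bumped = [
            _candidate("A", metadata={"ds": 100}),
            _candidate("B", metadata={"ds": 70}),
        ]
        score_candidates(bumped, cfg)
        assert bumped[1].combined >= before


class TestGrouping:
    def test_salt_forms_collapse_into_one_group(self):
        # 11 of 21 candidates share a skeleton (the simazine scenario scale)
        cands = [
            _candidate(f"S{i:02d}", block=BLOCKS[0], fragmenter=0.1 * (i % 5))
            for i in range(11)
        ] + [
            _candidate(f"U{i:02d}", block=BLOCKS[1 + i % 4], fragmenter=0.5)
            for i in range(10)
        ]
        cfg = ScoringConfig()
        score_candidates(cands, cfg)
        groups = group_candidates(cands)
        sizes = sorted((len(g.members) for g in groups), reverse=True)
        assert sizes[0] == 11
        assert sum(sizes) == 21

    def test_all_distinct_blocks_give_singleton_groups(self):
        cands = [_candidate(f"X{i}", block=BLOCKS[i]) for i in range(5)]
        groups = group_candidates(cands)
        assert all(len(g.members) == 1 for g in groups)

    def test_tie_breaks_toward_smaller_identifier(self):
        a = _candidate("AAA", fragmenter=0.5)
        b = _candidate("BBB", fragmenter=0.5)
        cfg = ScoringConfig()
        score_candidates([a, b], cfg)
        group = group_candidates([b, a])[0]
        assert group.representative.identifier == "AAA"

    def test_representative_invariant_under_member_permutation(self):
        cands = [
            _candidate(f"X{i}", fragmenter=0.2 * i) for i in range(5)
        ]
        cfg = ScoringConfig()
        score_candidates(cands, cfg)
        rep1 = group_candidates(cands)[0].representative.identifier
        rep2 = group_candidates(list(reversed(cands)))[0].representative.identifier
        assert rep1 == rep2

    def test_group_retains_all_identifiers(self):
        cands = [_candidate(f"X{i}") for i in range(4)]
        group = group_candidates(cands)[0]
        assert sorted(group.identifiers) == ["X0", "X1", "X2", "X3"]

    def test_missing_inchikey_names_candidate(self):
        with pytest.raises(ValueError, match="NOKEY"):
            group_candidates([CandidateScore("NOKEY")])


class TestRank:
    def test_candidate_with_full_metadata_outranks_sparse_one(self):
        cfg = ScoringConfig(metadata_categories=("ds", "norman", "toxcast"))
        full = _candidate(
            "terbutylazine", block=BLOCKS[0],
            fragmenter=1.0, spectral_similarity=1.0,
            metadata={"ds": 3880, "norman": 1, "toxcast": 31},
        )
        sparse = _candidate(
            "sebutylazine", block=BLOCKS[1],
            fragmenter=0.97, spectral_similarity=0.95,
            metadata={"ds": 182, "norman": None, "toxcast": None},
        )
        ordered = rank(score_candidates([sparse, full], cfg))
        assert ordered[0].identifier == "terbutylazine"

    def test_single_candidate_ranks_itself(self):
        cfg = ScoringConfig()
        c = _candidate("only", fragmenter=0.4)
        assert rank(score_candidates([c], cfg)) == [c]

    def test_zero_weight_removes_category_influence(self):
        cats = ("ds",)
        heavy = ScoringConfig(metadata_categories=cats)
        none = ScoringConfig(metadata_categories=cats, weights={"ds": 0.0})
        a = lambda: _candidate("A", block=BLOCKS[0], fragmenter=0.3,
                               metadata={"ds": 1000})
        b = lambda: _candidate("B", block=BLOCKS[1], fragmenter=0.5,
                               metadata={"ds": 10})
        with_meta = rank(score_candidates([a(), b()], heavy))
        without = rank(score_candidates([a(), b()], none))
        assert with_meta[0].identifier == "A"
        assert without[0].identifier == "B"

    def test_grouped_ranking_uses_representatives(self):
        cfg = ScoringConfig(grouping=True)
        cands = [
            _candidate("A1", block=BLOCKS[0], fragmenter=0.9),
            _candidate("A2", block=BLOCKS[0], fragmenter=0.2),
            _candidate("B1", block=BLOCKS[1], fragmenter=0.5),
        ]
        score_candidates(cands, cfg)
        ordered = rank(cands, cfg)
        assert [c.identifier for c in ordered] == ["A1", "B1"]
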