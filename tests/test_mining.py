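"""Constrained sequence miner vs. brute-force enumeration."""

import numpy as np
import pytest

from patternsurv.mining import (MiningParams, TemporalPattern, contains_pattern,
                                enumerate_patterns_bruteforce, mine_patterns,
                                pattern_support, read_patterns_jsonl,
                                write_patterns_jsonl)
from conftest import make_visit, random_sequence_db


def _db_tuples(db):
    return {pid: seq for pid, seq in db.items()}


class TestContainsPattern:
    def test_single_element_anywhere(self):
        seq = [make_visit("p", 0, "a=1"), make_visit("p", 30, "b=1")]
        assert contains_pattern(seq, TemporalPattern.from_items("b=1"), 60)

    def test_gap_violated_by_one_day(self):
        seq = [make_visit("p", 0, "a=1"), make_visit("p", 61, "b=1")]
        pattern = TemporalPattern.from_items("a=1", "b=1")
        assert not contains_pattern(seq, pattern, 60)
        assert contains_pattern(seq, pattern, 61)

    def test_intervening_unmatched_visits_allowed(self):
        seq = [make_visit("p", 0, "a=1"), make_visit("p", 30, "c=1"),
               make_visit("p", 55, "b=1")]
        assert contains_pattern(seq, TemporalPattern.from_items("a=1", "b=1"), 60)

    def test_example_triple_neuro_then_rate(self):
        """A visit with moderate symptoms and unchanged overall status followed
        within 60 days by a mid-decile volume rate change."""
        pattern = TemporalPattern.from_items(
            ["neurologic_function=2", "overall_neuro_status=0"],
            "volume_rate=[122,371)",
        )
        seq = [
            make_visit("p", 10, "neurologic_function=2", "overall_neuro_status=0"),
            make_visit("p", 65, "volume_rate=[122,371)"),
        ]
        assert contains_pattern(seq, pattern, 60)
        far = [
            make_visit("p", 10, "neurologic_function=2", "overall_neuro_status=0"),
            make_visit("p", 75, "volume_rate=[122,371)"),
        ]
        assert not contains_pattern(far, pattern, 60)

    def test_itemset_must_cooccur_at_one_visit(self):
        seq = [make_visit("p", 0, "a=1"), make_visit("p", 10, "b=1")]
        assert not contains_pattern(
            seq, TemporalPattern.from_items(["a=1", "b=1"]), 60)


class TestPatternSupport:
    def test_toy_counts(self):
        db = {
            "p0": [make_visit("p0", 0, "a=1")],
            "p1": [make_visit("p1", 0, "b=1")],
            "p2": [make_visit("p2", 0, "b=1"), make_visit("p2", 20, "b=1")],
        }
        pattern = TemporalPattern.from_items("a=1")
        assert pattern_support(pattern, db, 60) == pytest.approx(1 / 3)
        # multiple occurrences within one patient count once
        assert pattern_support(TemporalPattern.from_items("b=1"), db, 60) == \
            pytest.approx(2 / 3)

    def test_universal_pattern(self):
        db = {f"p{i}": [make_visit(f"p{i}", 0, "a=1")] for i in range(5)}
        assert pattern_support(TemporalPattern.from_items("a=1"), db, 60) == 1.0

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            pattern_support(TemporalPattern.from_items("a=1"), {}, 60)


class TestMinePatterns:
    def test_no_universal_item_at_full_support(self):
        db = {
            "p0": [make_visit("p0", 0, "a=1")],
            "p1": [make_visit("p1", 0, "b=1")],
        }
        assert mine_patterns(db, MiningParams(1.0, 60, 3, 3)) == []

    def test_single_patient_itemset_subsets(self):
        db = {"p0": [make_visit("p0", 0, "a=1", "b=1")]}
        mined = mine_patterns(db, MiningParams(1.0, 60, 1, 2))
        found = {p.key() for p in mined}
        assert found == {
            ((("a", "1"),),),
            ((("b", "1"),),),
            ((("a", "1"), ("b", "1")),),
        }
        assert all(p.support == 1.0 for p in mined)

    def test_support_threshold_monotonicity(self, rng):
        db = random_sequence_db(np.random.default_rng(5), max_patients=5)
        low = mine_patterns(db, MiningParams(0.25, 60, 3, 2))
        high = mine_patterns(db, MiningParams(0.30, 60, 3, 2))
        assert {p.key() for p in high} <= {p.key() for p in low}

    def test_determinism(self):
        db = random_sequence_db(np.random.default_rng(11))
        params = MiningParams(0.3, 45, 3, 2)
        assert mine_patterns(db, params) == mine_patterns(db, params)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MiningParams(0.0, 60, 3, 3)
        with pytest.raises(ValueError):
            MiningParams(0.3, 60, 0, 3)


class TestBruteForceOracle:
    def test_empty_database(self):
        assert enumerate_patterns_bruteforce({}, MiningParams()) == []

    def test_hand_enumeration_one_visit(self):
        db = {"p0": [make_visit("p0", 0, "a=1", "b=1")]}
        pats = enumerate_patterns_bruteforce(db, MiningParams(1.0, 60, 3, 2))
        assert {p.key() for p in pats} == {
            ((("a", "1"),),),
            ((("b", "1"),),),
            ((("a", "1"), ("b", "1")),),
        }

    def test_size_guard(self):
        db = {f"p{i}": [make_visit(f"p{i}", 0, "a=1")] for i in range(11)}
        with pytest.raises(ValueError):
            enumerate_patterns_bruteforce(db, MiningParams())

    def test_structural_constraints_respected(self):
        db = random_sequence_db(np.random.default_rng(3))
        params = MiningParams(0.2, 40, 2, 2)
        for p in enumerate_patterns_bruteforce(db, params):
            assert p.length <= 2 and p.size <= 2


def test_miner_equals_oracle_on_random_databases():
    """Exact set-and-support agreement with exhaustive enumeration over many
    seeded random databases with all four constraints active."""
    rng = np.random.default_rng(2024)
    for _ in range(60):
        db = random_sequence_db(rng)
        params = MiningParams(
            min_support=float(rng.choice([0.2, 0.34, 0.5, 0.67])),
            max_gap_days=int(rng.choice([25, 40, 60])),
            max_length=int(rng.integers(1, 4)),
            max_size=int(rng.integers(1, 4)),
        )
        mined = mine_patterns(db, params)
        oracle = enumerate_patterns_bruteforce(db, params)
        assert [(p.key(), p.support) for p in mined] == \
            [(p.key(), p.support) for p in oracle], (db, params)


def test_prefix_and_subset_antimonotonicity():
    """Support of any prefix, and of any pattern with a reduced final itemset,
    is at least the support of the full pattern."""
    rng = np.random.default_rng(77)
    for _ in range(20):
        db = random_sequence_db(rng)
        params = MiningParams(0.2, 50, 3, 3)
        for pattern in mine_patterns(db, params):
            s = pattern_support(pattern, db, params.max_gap_days)
            for cut in range(1, pattern.length):
                prefix = TemporalPattern(pattern.elements[:cut])
                assert pattern_support(prefix, db, params.max_gap_days) >= s
            last = pattern.elements[-1]
            for item in last:
                if len(last) > 1:
                    reduced = TemporalPattern(
                        pattern.elements[:-1] + (last - {item},))
                    assert pattern_support(reduced, db, params.max_gap_days) >= s


def test_mined_patterns_verify_by_rematching():
    """Every emitted pattern is genuinely contained, under the gap rule, in
    exactly support * n patients."""
    rng = np.random.default_rng(9)
    db = random_sequence_db(rng, max_patients=6, max_visits=5)
    params = MiningParams(0.3, 45, 3, 2)
    n = len(db)
    for pattern in mine_patterns(db, params):
        hits = sum(contains_pattern(seq, pattern, params.max_gap_days)
                   for seq in db.values())
        assert hits / n == pytest.approx(pattern.support)
        assert hits >= params.min_support * n - 1e-9


def test_patterns_jsonl_round_trip(tmp_path):
    db = random_sequence_db(np.random.default_rng(21))
    patterns = mine_patterns(db, MiningParams(0.2, 60, 2, 2))
    path = tmp_path / "patterns.jsonl"
    write_patterns_jsonl(patterns, path)
    loaded = read_patterns_jsonl(path)
    assert [(p.key(), p.support) for p in loaded] == \
        [(p.key(), p.support) for p in patterns]
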