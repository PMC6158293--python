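"""Metrics, bootstrap procedures, and exact tests against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from patternsurv.evaluation import (ApproachResult, auc, average_precision,
                                    bootstrap_auc_ci, bootstrap_auc_test,
                                    fisher_exact_or, volume_threshold_auc)


def pairwise_auc(scores, labels):
    """Independent oracle: count positive-negative pairs won (ties half)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_worked_example(self):
        # pairs: (.9>.8), (.9>.1), (.7<.8), (.7>.1) -> 3 of 4
        assert auc([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 40))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert auc(scores, labels) == pytest.approx(pairwise_auc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.9], [1, 1])


def test_volume_threshold_auc_is_roc_identity(rng):
    for _ in range(10):
        volumes = rng.lognormal(8, 1, size=60)
        labels = rng.integers(0, 2, size=60)
        if labels.min() == labels.max():
            continue
        assert volume_threshold_auc(volumes, labels) == auc(volumes, labels)


class TestAveragePrecision:
    def test_perfect_ranking(self):
        assert average_precision([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_single_positive_ranked_second(self):
        assert average_precision([0.9, 0.1], [0, 1]) == pytest.approx(0.5)

    def test_all_positives(self):
        assert average_precision([0.3, 0.6], [1, 1]) == 1.0

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            average_precision([0.3, 0.6], [0, 0])


class TestBootstrapCi:
    def test_contains_point_estimate(self, rng):
        scores = np.concatenate([rng.normal(1, 1, 40), rng.normal(0, 1, 40)])
        labels = np.array([1] * 40 + [0] * 40)
        lo, hi = bootstrap_auc_ci(scores, labels, n_replicates=500, seed=0)
        assert lo <= auc(scores, labels) <= hi

    def test_degenerate_perfect_separation(self):
        scores = [0.9] * 10 + [0.1] * 10
        labels = [1] * 10 + [0] * 10
        assert bootstrap_auc_ci(scores, labels, n_replicates=200, seed=0) == (1.0, 1.0)

    def test_width_shrinks_with_n(self):
        rng = np.random.default_rng(8)
        widths = []
        for n in (50, 5000):
            scores = np.concatenate([rng.normal(0.8, 1, n), rng.normal(0, 1, n)])
            labels = np.array([1] * n + [0] * n)
            lo, hi = bootstrap_auc_ci(scores, labels, n_replicates=400, seed=1)
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_reproducible_under_seed(self, rng):
        scores = rng.normal(size=80)
        labels = np.array([1] * 40 + [0] * 40)
        a = bootstrap_auc_ci(scores, labels, n_replicates=300, seed=5)
        b = bootstrap_auc_ci(scores, labels, n_replicates=300, seed=5)
        assert a == b


class TestBootstrapTest:
    def test_identical_scores_p_one(self, rng):
        scores = rng.normal(size=60)
        labels = np.array([1] * 30 + [0] * 30)
        assert bootstrap_auc_test(scores, scores, labels, 200, seed=0) == 1.0

    def test_strong_vs_random_significant(self):
        rng = np.random.default_rng(3)
        n = 250
        labels = np.array([1] * n + [0] * n)
        strong = np.concatenate([rng.normal(2, 1, n), rng.normal(0, 1, n)])
        noise = rng.normal(size=2 * n)
        p = bootstrap_auc_test(strong, noise, labels, 500, seed=0)
        assert p < 0.001

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_auc_test([0.1, 0.2], [0.1], [1, 0], 100)


def _fisher_oracle(table, alpha=0.05):
    """Hypergeometric brute force: two-sided p, conditional-ML OR, exact CI."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    lo_a, hi_a = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo_a, hi_a + 1)
    pmf = hypergeom.pmf(support, r1 + r2, r1, c1)
    p_two = float(pmf[pmf <= pmf[a - lo_a] * (1 + 1e-9)].sum())

    def mean_at(log_psi):
        w = pmf * np.exp(support * log_psi)
        return float((support * w).sum() / w.sum())

    if a == hi_a:
        or_ = math.inf
    elif a == lo_a:
        or_ = 0.0
    else:
        lo_l, hi_l = -40.0, 40.0
        for _ in range(200):
            mid = (lo_l + hi_l) / 2
            if mean_at(mid) < a:
                lo_l = mid
            else:
                hi_l = mid
        or_ = math.exp((lo_l + hi_l) / 2)

    def sf_at(log_psi):  # P(A >= a | psi)
        w = pmf * np.exp(support * log_psi)
        return float(w[support >= a].sum() / w.sum())

    def cdf_at(log_psi):  # P(A <= a | psi)
        w = pmf * np.exp(support * log_psi)
        return float(w[support <= a].sum() / w.sum())

    def solve(fn, target, increasing):
        lo_l, hi_l = -45.0, 45.0
        for _ in range(200):
            mid = (lo_l + hi_l) / 2
            below = fn(mid) < target
            if below == increasing:
                lo_l = mid
            else:
                hi_l = mid
        return math.exp((lo_l + hi_l) / 2)

    # Exact (Cornfield) limits: psi_L solves P(A >= a | psi) = alpha/2
    # (increasing in psi); psi_U solves P(A <= a | psi) = alpha/2 (decreasing).
    ci_lo = 0.0 if a == lo_a else solve(sf_at, alpha / 2, increasing=True)
    ci_hi = math.inf if a == hi_a else solve(cdf_at, alpha / 2, increasing=False)
    return or_, ci_lo, ci_hi, p_two


class TestFisherExactOr:
    def test_no_association(self):
        or_, lo, hi, p = fisher_exact_or([[10, 10], [10, 10]])
        assert or_ == pytest.approx(1.0)
        assert p == pytest.approx(1.0)
        assert lo < 1 < hi

    def test_perfect_association_infinite_or(self):
        or_, lo, hi, p = fisher_exact_or([[5, 0], [0, 5]])
        assert math.isinf(or_)
        assert lo > 1
        assert p < 0.05

    def test_matches_hypergeometric_enumeration(self):
        or_, lo, hi, p = fisher_exact_or([[20, 5], [5, 20]])
        o_or, o_lo, o_hi, o_p = _fisher_oracle([[20, 5], [5, 20]])
        assert or_ == pytest.approx(o_or, rel=1e-3)
        assert p == pytest.approx(o_p, rel=1e-6)
        assert lo == pytest.approx(o_lo, rel=1e-3)
        assert hi == pytest.approx(o_hi, rel=1e-3)

    def test_oracle_agreement_random_tables(self, rng):
        for _ in range(40):
            table = rng.integers(0, 12, size=(2, 2))
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            or_, lo, hi, p = fisher_exact_or(table)
            o_or, o_lo, o_hi, o_p = _fisher_oracle(table)
            assert p == pytest.approx(o_p, rel=1e-6, abs=1e-12)
            if math.isfinite(or_) and or_ > 0:
                assert or_ == pytest.approx(o_or, rel=1e-3)
            else:
                assert or_ == o_or

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_or([[0, 0], [5, 5]])


def test_approach_result_invariant():
    with pytest.raises(ValueError):
        ApproachResult("volume_only", 0.9, 0.95, 0.99, 0.5)
    res = ApproachResult("volume_only", 0.9, 0.85, 0.95, 0.5)
    assert res.ci_low <= res.auc <= res.ci_high
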