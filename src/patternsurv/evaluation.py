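"""Model evaluation: ROC/PR metrics, bootstrap uncertainty, exact tests.

Implements the comparison protocol for three prediction approaches
(volume threshold alone, volume + covariates, temporal patterns +
covariates), percentile bootstrap confidence intervals for AUC with
stratified resampling, a paired bootstrap test for AUC differences
(normal-deviate form of the bootstrap difference distribution),
Fisher's exact univariate odds ratios (conditional maximum likelihood
with exact confidence intervals), pattern ranking by adjusted odds
ratio, and per-patient probability trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "ApproachResult",
    "PatternStats",
    "auc",
    "volume_threshold_auc",
    "average_precision",
    "bootstrap_auc_ci",
    "bootstrap_auc_test",
    "fisher_exact_or",
    "rank_patterns",
    "trajectory_report",
]

ALPHA = 0.05  # significance level for all statistical tests


def _validate_binary(labels) -> np.ndarray:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if not set(classes) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return labels


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: probability a random positive outranks a random
    negative, ties counted 1/2."""
    labels = _validate_binary(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def volume_threshold_auc(volumes, labels) -> float:
    """AUC of classifying 'residual survival <= horizon' at every possible
    volume threshold — identically the ROC AUC with volume as the score."""
    return auc(volumes, labels)


def average_precision(scores, labels) -> float:
    """Area under the precision-recall curve (precision averaged at the rank
    of each positive)."""
    labels = _validate_binary(labels)
    if labels.sum() == 0:
        raise ValueError("average precision undefined without positives")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Fast Mann-Whitney AUC from positive/negative score arrays."""
    all_scores = np.concatenate([pos, neg])
    ranks = stats.rankdata(all_scores)
    r_pos = ranks[: len(pos)].sum()
    return (r_pos - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg))


def _stratified_indices(rng, n_pos: int, n_neg: int, n_replicates: int):
    pos_idx = rng.integers(0, n_pos, size=(n_replicates, n_pos))
    neg_idx = rng.integers(0, n_neg, size=(n_replicates, n_neg))
    return pos_idx, neg_idx


def bootstrap_auc_ci(scores, labels, n_replicates: int = 2000, seed: int = 0,
                     level: float = 0.95) -> Tuple[float, float]:
    """Percentile bootstrap CI for AUC with stratified resampling (cases and
    controls resampled within class)."""
    labels = _validate_binary(labels)
    scores = np.asarray(scores, dtype=float)
    pos, neg = scores[labels == 1], scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required")
    rng = np.random.default_rng(seed)
    pos_idx, neg_idx = _stratified_indices(rng, len(pos), len(neg), n_replicates)
    reps = np.array([_rank_auc(pos[pi], neg[ni]) for pi, ni in zip(pos_idx, neg_idx)])
    lo, hi = np.quantile(reps, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def bootstrap_auc_test(scores_a, scores_b, labels, n_replicates: int = 2000,
                       seed: int = 0) -> float:
    """Two-sided paired bootstrap test for a difference in AUC.

    Both score vectors must be given on the identical visits.  Each
    stratified replicate resamples cases and controls jointly for both
    scorers; the observed difference is scaled by the bootstrap standard
    deviation of the difference and referred to a standard normal.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = _validate_binary(labels)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("paired scores and labels must have equal length")
    pos_mask = labels == 1
    pa, na = scores_a[pos_mask], scores_a[~pos_mask]
    pb, nb = scores_b[pos_mask], scores_b[~pos_mask]
    if len(pa) == 0 or len(na) == 0:
        raise ValueError("both classes required")
    observed = _rank_auc(pa, na) - _rank_auc(pb, nb)
    rng = np.random.default_rng(seed)
    pos_idx, neg_idx = _stratified_indices(rng, len(pa), len(na), n_replicates)
    diffs = np.empty(n_replicates)
    for r in range(n_replicates):
        pi, ni = pos_idx[r], neg_idx[r]
        diffs[r] = _rank_auc(pa[pi], na[ni]) - _rank_auc(pb[pi], nb[ni])
    sd = diffs.std(ddof=1)
    if sd == 0:
        return 1.0 if observed == 0 else 0.0
    z = observed / sd
    return float(2 * stats.norm.sf(abs(z)))


def fisher_exact_or(table) -> Tuple[float, float, float, float]:
    """Fisher's exact univariate odds ratio for a 2x2 table.

    Returns ``(OR, ci_low, ci_high, p)``: the conditional
    maximum-likelihood odds ratio, its exact 95% CI, and the two-sided
    exact p-value.  Zero cells yield 0 or ``inf`` estimates with finite
    one-sided exact bounds; no continuity correction is applied.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("odds ratio undefined: a table margin is zero")
    result = _scipy_odds_ratio(table, kind="conditional")
    ci = result.confidence_interval(confidence_level=1 - ALPHA)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(result.statistic), float(ci.low), float(ci.high), float(p)


@dataclass(frozen=True)
class PatternStats:
    """Univariate and model-adjusted statistics of one selected feature."""

    name: str
    pattern: str
    support: Optional[float]
    adjusted_or: float
    univariate_or: float
    ci_low: float
    ci_high: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class ApproachResult:
    """Per-horizon performance of one prediction approach."""

    approach: str
    auc: float
    ci_low: float
    ci_high: float
    average_precision: float

    def __post_init__(self):
        if not self.ci_low <= self.auc <= self.ci_high:
            raise ValueError("CI must bracket the point estimate")


def _patient_support(column: pd.Series) -> float:
    by_patient = column.groupby(level="patient_id").max()
    return float(by_patient.mean())


def rank_patterns(fit, X: pd.DataFrame, y: pd.Series, meta: dict, top: int = 10
                  ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Rank selected features by adjusted odds ratio.

    Returns two tables: features with adjusted OR > 1 (descending;
    predictive of residual survival <= horizon) and OR < 1 (ascending;
    predictive of survival beyond the horizon), each with patient-level
    support and Fisher-exact univariate statistics.  Covariates carry no
    support (reported as NaN).
    """
    records = []
    for name, coef in zip(fit.feature_names, fit.coefficients):
        if coef == 0:
            continue
        col = X[name].to_numpy()
        a = int(((col == 1) & (y == 1)).sum())
        b = int(((col == 1) & (y == 0)).sum())
        c = int(((col == 0) & (y == 1)).sum())
        d = int(((col == 0) & (y == 0)).sum())
        try:
            uor, lo, hi, p = fisher_exact_or([[a, b], [c, d]])
        except ValueError:
            uor = lo = hi = p = float("nan")
        support = _patient_support(X[name]) if name in meta else float("nan")
        records.append(
            PatternStats(
                name=name,
                pattern=meta.get(name, name),
                support=support,
                adjusted_or=float(np.exp(coef)),
                univariate_or=uor,
                ci_low=lo,
                ci_high=hi,
                p_value=p,
            )
        )
    frame = pd.DataFrame([s.__dict__ for s in records])
    if frame.empty:
        empty = pd.DataFrame(
            columns=["name", "pattern", "support", "adjusted_or", "univariate_or",
                     "ci_low", "ci_high", "p_value"]
        )
        return empty, empty.copy()
    harmful = frame[frame.adjusted_or > 1].sort_values("adjusted_or", ascending=False).head(top)
    protective = frame[frame.adjusted_or < 1].sort_values("adjusted_or").head(top)
    return harmful.reset_index(drop=True), protective.reset_index(drop=True)


def trajectory_report(record, results, horizon=None) -> pd.DataFrame:
    """Per-visit predicted probability, thresholded class, and true label for
    one patient under a fitted model.

    The first predictable visit is the first with at least
    ``min_history_required`` days of documented history; patients with
    shorter follow-up yield an empty report.
    """
    from .features import label_visit

    horizon = horizon or results.horizon
    frame = results.predict_proba([record])
    if frame.empty:
        return pd.DataFrame(columns=["day", "probability", "predicted", "label"])
    out = frame.reset_index()[["day", "probability"]]
    out["predicted"] = (out["probability"] >= results.threshold).astype(int)
    out["label"] = [
        label_visit(day, record.outcome_day, record.deceased, horizon, "optimistic")
        for day in out["day"]
    ]
    return out
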