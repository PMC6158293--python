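"""LASSO logistic residual-survival models with patient-level validation.

The estimation protocol: patients are split 75/25 into train and test
partitions, stratified by survival subgroup (overall survival below vs.
above the cohort mean) and sex so that class and gender proportions are
preserved.  For each candidate mining configuration and L1 penalty,
10-fold patient-based cross-validation (repeated 3 times with different
fold seeds, majority class down-sampled inside each training fold) is
scored by mean AUC; the winner is refit on the full training partition
and evaluated once on the held-out test patients.

:class:`ResidualSurvivalModel` packages the full pipeline — train-only
discretization, pattern mining on training sequences, anchored binary
features, selection, refit, threshold choice — and ``fit()`` returns a
:class:`ResidualSurvivalResults` carrying coefficients, adjusted odds
ratios, cross-validated and test metrics, and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from . import evaluation
from .cohort import PatientRecord, read_cohort_csv
from .encoding import encode_cohort, fit_volume_scheme
from .features import Horizon, build_feature_matrix
from .mining import MiningParams, mine_patterns

__all__ = [
    "SplitSpec",
    "FitResult",
    "split_train_test",
    "downsample_majority",
    "fit_lasso_logistic",
    "cross_validate",
    "select_model",
    "choose_threshold",
    "ResidualSurvivalModel",
    "ResidualSurvivalResults",
    "compare_approaches",
]

DEFAULT_LAMBDAS = (0.03, 0.01, 0.003, 0.001)


@dataclass(frozen=True)
class SplitSpec:
    """Two-step stratified patient split: survival subgroup x gender."""

    train_frac: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must lie in (0, 1)")


def split_train_test(records: Sequence[PatientRecord], spec: SplitSpec
                     ) -> Tuple[List[str], List[str]]:
    """Patient-disjoint train/test ids, ~``train_frac`` per stratum.

    Strata are (overall survival below cohort mean) x sex; strata with
    fewer than 4 patients are merged into their survival subgroup with a
    warning.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least 2 patients to split")
    mean_os = np.mean([r.outcome_day for r in records])
    strata: Dict[tuple, list] = {}
    for r in records:
        strata.setdefault((r.outcome_day < mean_os, r.sex), []).append(r.patient_id)
    merged: Dict[tuple, list] = {}
    for (low, sex), ids in sorted(strata.items()):
        if len(ids) < 4:
            warnings.warn(f"stratum (survival_low={low}, sex={sex}) has {len(ids)} "
                          "patients; merged into its survival subgroup")
            merged.setdefault((low, "all"), []).extend(ids)
        else:
            merged.setdefault((low, sex), []).extend(ids)
    rng = np.random.default_rng(spec.seed)
    train_ids, test_ids = [], []
    target = allocated = 0.0
    for key in sorted(merged):
        ids = sorted(merged[key])
        rng.shuffle(ids)
        # Cascade rounding: per-stratum share stays within one patient of
        # train_frac while the cohort-level total matches it exactly.
        target += spec.train_frac * len(ids)
        n_train = int(round(target - allocated))
        n_train = min(max(n_train, 1), len(ids) - 1)
        allocated += n_train
        train_ids.extend(ids[:n_train])
        test_ids.extend(ids[n_train:])
    return sorted(train_ids), sorted(test_ids)


def downsample_majority(labels, seed: int = 0) -> np.ndarray:
    """Positional indices of a class-balanced subset: the minority class is
    kept whole, the majority randomly reduced to the minority size."""
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required for down-sampling")
    rng = np.random.default_rng(seed)
    if len(pos) > len(neg):
        pos = rng.choice(pos, size=len(neg), replace=False)
    elif len(neg) > len(pos):
        neg = rng.choice(neg, size=len(pos), replace=False)
    return np.sort(np.concatenate([pos, neg]))


@dataclass
class FitResult:
    """A fitted L1-penalized logistic model and its evaluation metrics."""

    feature_names: List[str]
    coefficients: np.ndarray
    intercept: float
    lam: float
    cv_auc: Optional[float] = None
    cv_average_precision: Optional[float] = None
    test_auc: Optional[float] = None
    test_average_precision: Optional[float] = None
    threshold: float = 0.5

    @property
    def selected(self) -> List[str]:
        return [n for n, c in zip(self.feature_names, self.coefficients) if c != 0]

    @property
    def adjusted_odds_ratios(self) -> pd.Series:
        return pd.Series(np.exp(self.coefficients), index=self.feature_names,
                         name="adjusted_or")

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        z = X @ self.coefficients + self.intercept
        return 1.0 / (1.0 + np.exp(-z))


def fit_lasso_logistic(X, y, lam: float = 0.01) -> FitResult:
    """L1-penalized logistic regression.

    ``lam`` is the per-observation penalty strength: the objective is
    mean log-loss + ``lam`` * ||w||_1 (sklearn ``C = 1/(lam * n)``).
    Binary 0/1 features are deliberately not standardized.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    y_arr = np.asarray(y)
    if set(np.unique(y_arr)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y_arr)) < 2:
        raise ValueError("labels are constant; nothing to fit")
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(np.shape(X)[1])]
    model = LogisticRegression(l1_ratio=1, C=1.0 / (lam * len(y_arr)),
                               solver="liblinear", max_iter=1000, tol=1e-5,
                               random_state=0)
    model.fit(np.asarray(X, dtype=float), y_arr)
    return FitResult(
        feature_names=names,
        coefficients=model.coef_.ravel().copy(),
        intercept=float(model.intercept_[0]),
        lam=lam,
    )


def _patient_folds(patient_ids: Sequence[str], n_folds: int, rng) -> List[np.ndarray]:
    ids = np.array(sorted(set(patient_ids)))
    rng.shuffle(ids)
    return [fold for fold in np.array_split(ids, n_folds) if len(fold)]


def cross_validate(X: pd.DataFrame, y: pd.Series, lam: float, *, n_folds: int = 10,
                   repeats: int = 3, seed: int = 0) -> Tuple[float, float]:
    """Patient-based repeated CV of a LASSO logistic fit.

    Folds partition patients (no patient contributes visits to both a
    training and its validation fold); the majority class is down-sampled
    inside each training fold only.  Returns (mean AUC, mean average
    precision) over ``repeats x n_folds`` folds; single-class folds are
    skipped with a warning.
    """
    patient_ids = X.index.get_level_values("patient_id")
    if len(set(patient_ids)) < n_folds:
        raise ValueError(f"need >= {n_folds} patients for {n_folds}-fold CV")
    aucs, aps = [], []
    for rep in range(repeats):
        rng = np.random.default_rng([seed, rep])
        for fold_ids in _patient_folds(patient_ids, n_folds, rng):
            val_mask = patient_ids.isin(fold_ids)
            assert not (set(patient_ids[val_mask]) & set(patient_ids[~val_mask]))
            y_tr, y_val = y[~val_mask], y[val_mask]
            if y_tr.nunique() < 2 or y_val.nunique() < 2:
                warnings.warn("fold skipped: a partition contains a single class")
                continue
            keep = downsample_majority(y_tr.to_numpy(), seed=int(rng.integers(2**31)))
            fit = fit_lasso_logistic(X[~val_mask].iloc[keep], y_tr.iloc[keep], lam)
            scores = fit.predict_proba(X[val_mask])
            aucs.append(evaluation.auc(scores, y_val))
            aps.append(evaluation.average_precision(scores, y_val))
    if not aucs:
        raise ValueError("no usable folds")
    return float(np.mean(aucs)), float(np.mean(aps))


def choose_threshold(scores, labels) -> float:
    """Probability threshold maximizing Youden's J on training predictions.

    Candidate cuts are midpoints between consecutive unique scores; ties
    resolve to the median maximizing cut.  Degenerate scores fall back to
    0.5 with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(scores)
    if len(uniq) < 2 or len(np.unique(labels)) < 2:
        warnings.warn("degenerate scores or labels; using threshold 0.5")
        return 0.5
    cuts = (uniq[:-1] + uniq[1:]) / 2
    n_pos, n_neg = (labels == 1).sum(), (labels == 0).sum()
    js = np.array([
        ((scores >= c) & (labels == 1)).sum() / n_pos
        - ((scores >= c) & (labels == 0)).sum() / n_neg
        for c in cuts
    ])
    best = np.flatnonzero(js >= js.max() - 1e-12)
    return float(cuts[best[len(best) // 2]])


def _grid_sort_key(params: MiningParams):
    return (params.min_support, params.max_gap_days, params.max_length, params.max_size)


def select_model(candidates: Sequence[dict], *, lambdas=DEFAULT_LAMBDAS, seed: int = 0,
                 cv_folds: int = 10, cv_repeats: int = 3):
    """Choose the (mining params, lambda) pair with highest mean CV AUC.

    ``candidates`` are dicts with keys ``params`` (MiningParams), ``X``,
    ``y``, ``patterns``, ``meta``.  Ties break toward fewer selected
    features (from a refit on the full training matrix), then
    lexicographic parameter order.  Returns (winner dict, lam, cv_auc,
    cv_ap, refit FitResult).
    """
    if not candidates:
        raise ValueError("empty candidate grid")
    scored = []
    for cand in sorted(candidates, key=lambda c: _grid_sort_key(c["params"])):
        for lam in lambdas:
            try:
                cv_auc, cv_ap = cross_validate(cand["X"], cand["y"], lam,
                                               n_folds=cv_folds, repeats=cv_repeats,
                                               seed=seed)
            except ValueError:
                continue
            scored.append((cand, lam, cv_auc, cv_ap))
    if not scored:
        raise ValueError("all candidate configurations were degenerate")
    best_auc = max(s[2] for s in scored)
    contenders = [s for s in scored if s[2] >= best_auc - 1e-12]
    ranked = []
    for cand, lam, cv_auc, cv_ap in contenders:
        keep = downsample_majority(cand["y"].to_numpy(), seed=seed)
        refit = fit_lasso_logistic(cand["X"].iloc[keep], cand["y"].iloc[keep], lam)
        ranked.append((len(refit.selected), _grid_sort_key(cand["params"]), lam,
                       cand, cv_auc, cv_ap, refit))
    ranked.sort(key=lambda t: (t[0], t[1], t[2]))
    n_sel, _, lam, cand, cv_auc, cv_ap, refit = ranked[0]
    refit.cv_auc, refit.cv_average_precision = cv_auc, cv_ap
    return cand, lam, cv_auc, cv_ap, refit


class ResidualSurvivalModel:
    """Residual-survival classifier over a longitudinal cohort.

    Parameters
    ----------
    records : sequence of PatientRecord
    horizon : int or Horizon
        Residual-survival horizon in months (2, 6, or 9).
    volume_representation : str
        Tumor-volume encoding; ``rate_change`` deciles by default.
    mining_grid : sequence of MiningParams
        Candidate cSPADE-style constraint combinations (default: the
        single canonical cell: support 0.3, gap 60 d, length 3, size 3).
    lambdas : sequence of float
        L1 penalty path scored by repeated cross-validation.
    censor_policy : {"exclude", "optimistic"}
        Handling of alive patients' visits within a horizon of censoring.
    """

    def __init__(self, records, horizon=2, *, volume_representation="rate_change",
                 mining_grid=None, lambdas=DEFAULT_LAMBDAS, censor_policy="exclude",
                 train_frac=0.75, cv_folds=10, cv_repeats=3, n_bins=10,
                 rano_progression_geq=True):
        self.records = list(records)
        self.horizon = horizon if isinstance(horizon, Horizon) else Horizon(horizon)
        self.volume_representation = volume_representation
        self.mining_grid = tuple(mining_grid) if mining_grid else (MiningParams(),)
        self.lambdas = tuple(lambdas)
        self.censor_policy = censor_policy
        self.train_frac = train_frac
        self.cv_folds = cv_folds
        self.cv_repeats = cv_repeats
        self.n_bins = n_bins
        self.rano_progression_geq = rano_progression_geq

    @classmethod
    def from_csv(cls, patients_csv, visits_csv, horizon=2, **kwargs):
        return cls(read_cohort_csv(patients_csv, visits_csv), horizon, **kwargs)

    def fit(self, seed: int = 0) -> "ResidualSurvivalResults":
        records = self.records
        train_ids, test_ids = split_train_test(records, SplitSpec(self.train_frac, seed))
        train = [r for r in records if r.patient_id in set(train_ids)]
        test = [r for r in records if r.patient_id in set(test_ids)]

        scheme = fit_volume_scheme(train, self.volume_representation, self.n_bins)
        sequences = encode_cohort(records, scheme, self.volume_representation,
                                  progression_geq=self.rano_progression_geq)
        train_seqs = {r.patient_id: sequences[r.patient_id] for r in train}

        candidates = []
        for params in self.mining_grid:
            patterns = mine_patterns(train_seqs, params)
            X, y, meta = build_feature_matrix(train, sequences, patterns, params,
                                              self.horizon, censor_policy=self.censor_policy)
            if len(y) == 0 or y.nunique() < 2:
                warnings.warn(f"grid cell {params} yields no two-class training data; skipped")
                continue
            candidates.append({"params": params, "patterns": patterns, "X": X,
                               "y": y, "meta": meta})
        if not candidates:
            raise ValueError("no usable mining configuration")
        winner, lam, cv_auc, cv_ap, refit = select_model(
            candidates, lambdas=self.lambdas, seed=seed,
            cv_folds=self.cv_folds, cv_repeats=self.cv_repeats)

        train_scores = refit.predict_proba(winner["X"])
        refit.threshold = choose_threshold(train_scores, winner["y"].to_numpy())

        X_test, y_test, _ = build_feature_matrix(
            test, sequences, winner["patterns"], winner["params"], self.horizon,
            censor_policy=self.censor_policy)
        X_test = X_test.reindex(columns=refit.feature_names, fill_value=0)
        if len(y_test) and y_test.nunique() == 2:
            test_scores = refit.predict_proba(X_test)
            refit.test_auc = evaluation.auc(test_scores, y_test)
            refit.test_average_precision = evaluation.average_precision(test_scores, y_test)

        return ResidualSurvivalResults(
            model=self, fit_result=refit, mining_params=winner["params"],
            patterns=winner["patterns"], meta=winner["meta"], scheme=scheme,
            train_ids=train_ids, test_ids=test_ids, seed=seed,
            X_train=winner["X"], y_train=winner["y"], X_test=X_test, y_test=y_test,
        )


@dataclass
class ResidualSurvivalResults:
    """Fitted-model container: estimates, uncertainty, diagnostics."""

    model: ResidualSurvivalModel
    fit_result: FitResult
    mining_params: MiningParams
    patterns: list
    meta: dict
    scheme: object
    train_ids: List[str]
    test_ids: List[str]
    seed: int
    X_train: pd.DataFrame = field(repr=False, default=None)
    y_train: pd.Series = field(repr=False, default=None)
    X_test: pd.DataFrame = field(repr=False, default=None)
    y_test: pd.Series = field(repr=False, default=None)

    @property
    def horizon(self) -> Horizon:
        return self.model.horizon

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.fit_result.coefficients,
                         index=self.fit_result.feature_names, name="coef")

    @property
    def odds_ratios(self) -> pd.Series:
        return self.fit_result.adjusted_odds_ratios

    @property
    def threshold(self) -> float:
        return self.fit_result.threshold

    @property
    def cv_auc(self): return self.fit_result.cv_auc
    @property
    def cv_average_precision(self): return self.fit_result.cv_average_precision
    @property
    def test_auc(self): return self.fit_result.test_auc
    @property
    def test_average_precision(self): return self.fit_result.test_average_precision

    def predict_proba(self, records) -> pd.DataFrame:
        """Per-visit predicted probability of residual survival <= horizon.

        All visits past the history rule are scored regardless of label
        determinability.
        """
        sequences = encode_cohort(records, self.scheme, self.model.volume_representation,
                                  progression_geq=self.model.rano_progression_geq)
        X, _, _ = build_feature_matrix(records, sequences, self.patterns,
                                       self.mining_params, self.horizon,
                                       censor_policy="optimistic")
        X = X.reindex(columns=self.fit_result.feature_names, fill_value=0)
        return pd.DataFrame({"probability": self.fit_result.predict_proba(X)}, index=X.index)

    def rank_patterns(self, top: int = 10):
        """Top-``top`` features per class by adjusted OR with univariate
        Fisher-exact statistics, computed on the training matrix."""
        return evaluation.rank_patterns(self.fit_result, self.X_train, self.y_train,
                                        self.meta, top=top)

    def trajectory(self, record) -> pd.DataFrame:
        return evaluation.trajectory_report(record, self)

    def bootstrap_test_auc_ci(self, n_replicates: int = 2000, seed: int = 0):
        scores = self.fit_result.predict_proba(self.X_test)
        return evaluation.bootstrap_auc_ci(scores, self.y_test.to_numpy(),
                                           n_replicates=n_replicates, seed=seed)

    def summary(self) -> str:
        """Human-readable fit summary (selected features by adjusted OR)."""
        fr = self.fit_result
        lines = [
            "Residual-survival LASSO logistic model",
            "=" * 54,
            f"Horizon:              {self.horizon.months} months ({self.horizon.days} days)",
            f"Volume encoding:      {self.model.volume_representation}",
            f"Mining params:        min_support={self.mining_params.min_support}, "
            f"max_gap={self.mining_params.max_gap_days}d, "
            f"max_length={self.mining_params.max_length}, "
            f"max_size={self.mining_params.max_size}",
            f"Patterns mined:       {len(self.patterns)}",
            f"Patients (train/test): {len(self.train_ids)}/{len(self.test_ids)}",
            f"Visits (train/test):  {len(self.y_train)}/{len(self.y_test)}",
            f"Lambda (L1):          {fr.lam:g}",
            f"Selected features:    {len(fr.selected)}",
            f"Mean CV AUC:          {fr.cv_auc:.3f}" if fr.cv_auc is not None else "",
            f"Mean CV avg prec:     {fr.cv_average_precision:.3f}"
            if fr.cv_average_precision is not None else "",
            f"Test AUC:             {fr.test_auc:.3f}" if fr.test_auc is not None else "",
            f"Test avg precision:   {fr.test_average_precision:.3f}"
            if fr.test_average_precision is not None else "",
            f"Threshold (Youden J): {fr.threshold:.3f}",
            "-" * 54,
            "Top features by adjusted OR:",
        ]
        ors = self.odds_ratios
        sel = ors[self.params != 0].sort_values(ascending=False)
        for name in list(sel.index[:8]):
            lines.append(f"  {sel[name]:7.3f}  {self.meta.get(name, name)}")
        return "\n".join(l for l in lines if l)


def _volume_at_visits(records, index: pd.MultiIndex) -> np.ndarray:
    """Last observed tumor volume at or before each (patient, day) row."""
    lookup = {}
    for r in records:
        measured = [(v.day, v.volume_mm3) for v in r.visits if v.volume_mm3 is not None]
        lookup[r.patient_id] = measured
    out = np.full(len(index), np.nan)
    for i, (pid, day) in enumerate(index):
        last = [vol for d, vol in lookup.get(pid, []) if d <= day]
        if last:
            out[i] = last[-1]
    return out


def compare_approaches(records, horizon=2, seed: int = 0, *, mining_grid=None,
                       lambdas=DEFAULT_LAMBDAS, n_replicates: int = 2000,
                       censor_policy="exclude", cv_folds=10, cv_repeats=3
                       ) -> Dict[str, object]:
    """Head-to-head comparison of the three prediction approaches.

    1. ``volume_only`` — threshold sweep on the last observed tumor
       volume (equivalently, volume as ROC score);
    2. ``volume_plus_covariates`` — logistic model on standardized
       volume plus patient covariates;
    3. ``patterns_plus_covariates`` — the full temporal-pattern model.

    All three are scored on the identical held-out test visits (rows of
    the pattern feature matrix with an observed volume), so the paired
    bootstrap AUC tests are valid.  Returns approach results, pairwise
    p-values, and the fitted pattern-model results object.
    """
    model = ResidualSurvivalModel(records, horizon, mining_grid=mining_grid,
                                  lambdas=lambdas, censor_policy=censor_policy,
                                  cv_folds=cv_folds, cv_repeats=cv_repeats)
    results = model.fit(seed=seed)

    def _rows(X, y):
        vols = _volume_at_visits(records, X.index)
        keep = ~np.isnan(vols)
        return X[keep], y[keep].to_numpy(), vols[keep]

    X_tr, y_tr, vol_tr = _rows(results.X_train, results.y_train)
    X_te, y_te, vol_te = _rows(results.X_test, results.y_test)
    if len(np.unique(y_te)) < 2:
        raise ValueError("test rows contain a single class; cannot compare approaches")

    cov_cols = [c for c in X_tr.columns if not c.startswith("pat_")]
    mu, sd = vol_tr.mean(), vol_tr.std() or 1.0

    def _vol_cov_matrix(X, vols):
        M = X[cov_cols].copy()
        M.insert(0, "volume_std", (vols - mu) / sd)
        return M

    keep = downsample_majority(y_tr, seed=seed)
    vc_fit = fit_lasso_logistic(_vol_cov_matrix(X_tr, vol_tr).iloc[keep], y_tr[keep],
                                lam=min(lambdas))
    scores = {
        "volume_only": vol_te,
        "volume_plus_covariates": vc_fit.predict_proba(_vol_cov_matrix(X_te, vol_te)),
        "patterns_plus_covariates": results.fit_result.predict_proba(
            X_te.reindex(columns=results.fit_result.feature_names, fill_value=0)),
    }
    approaches = {}
    for i, (name, s) in enumerate(scores.items()):
        point = evaluation.auc(s, y_te)
        lo, hi = evaluation.bootstrap_auc_ci(s, y_te, n_replicates=n_replicates,
                                             seed=seed + i)
        approaches[name] = evaluation.ApproachResult(
            approach=name, auc=point, ci_low=min(lo, point), ci_high=max(hi, point),
            average_precision=evaluation.average_precision(s, y_te))
    pvals = {}
    names = list(scores)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pvals[(names[i], names[j])] = evaluation.bootstrap_auc_test(
                scores[names[i]], scores[names[j]], y_te,
                n_replicates=n_replicates, seed=seed)
    return {"approaches": approaches, "p_values": pvals, "results": results,
            "test_labels": y_te, "test_scores": scores}
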