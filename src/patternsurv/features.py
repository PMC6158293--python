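"""Per-visit features and residual-survival labels.

Each mined temporal pattern becomes a binary feature anchored at the
current visit: the pattern's final element must match exactly at the
visit, with earlier elements at earlier visits under the max-gap rule.
Visits are labeled for 2-, 6-, or 9-month residual survival (one month
= 30 days, boundary inclusive on the short side).  A visit is only
usable when at least ``(max_length - 1) * max_gap_days`` days of
documented prior history exist — 120 days for the canonical 3-visit /
60-day configuration — so every pattern occurrence is decidable.

Censoring: visits of deceased patients are always labelable.  Visits of
alive patients more than a horizon before censoring are safely
``gt_horizon``; visits within a horizon of censoring are indeterminable
and excluded by default (the ``optimistic`` policy labels them
``gt_horizon``, the literal reading of the source protocol).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .mining import MiningParams, TemporalPattern, _match_ends

__all__ = [
    "Horizon",
    "LE_HORIZON",
    "GT_HORIZON",
    "min_history_required",
    "pattern_occurs_at_visit",
    "label_visit",
    "covariate_columns",
    "build_feature_matrix",
    "write_feature_matrix",
]

LE_HORIZON = 1  # residual survival <= horizon
GT_HORIZON = 0

DAYS_PER_MONTH = 30


@dataclass(frozen=True)
class Horizon:
    """A residual-survival horizon of 2, 6, or 9 months (60/180/270 days)."""

    months: int

    def __post_init__(self):
        if self.months not in (2, 6, 9):
            raise ValueError("horizon must be 2, 6, or 9 months")

    @property
    def days(self) -> int:
        return self.months * DAYS_PER_MONTH


def min_history_required(max_length: int, max_gap_days: int) -> int:
    """Days of documented history needed to decide any pattern occurrence:
    ``(max_length - 1) * max_gap_days``."""
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    return (max_length - 1) * max_gap_days


def pattern_occurs_at_visit(sequence, visit_index: int, pattern: TemporalPattern,
                            max_gap_days: int) -> bool:
    """Anchored match: the final element at visit ``visit_index`` exactly,
    earlier elements at earlier visits under the gap rule."""
    if not 0 <= visit_index < len(sequence):
        raise IndexError("visit_index out of range")
    if len(pattern.elements) > visit_index + 1:
        return False
    if not pattern.elements[-1] <= sequence[visit_index].items:
        return False
    if len(pattern.elements) == 1:
        return True
    prefix_ends = _match_ends(sequence[:visit_index], pattern.elements[:-1], max_gap_days)
    anchor_day = sequence[visit_index].day
    return any(anchor_day - sequence[e].day <= max_gap_days for e in prefix_ends)


def label_visit(visit_day: int, outcome_day: int, deceased: bool, horizon: Horizon,
                censor_policy: str = "exclude") -> Optional[int]:
    """Residual-survival label of one visit, or ``None`` when excluded."""
    if censor_policy not in ("exclude", "optimistic"):
        raise ValueError("censor_policy must be 'exclude' or 'optimistic'")
    if outcome_day < visit_day:
        raise ValueError("outcome day precedes visit day")
    residual = outcome_day - visit_day
    if deceased:
        return LE_HORIZON if residual <= horizon.days else GT_HORIZON
    if residual >= horizon.days:
        return GT_HORIZON
    return GT_HORIZON if censor_policy == "optimistic" else None


class _PatientMatcher:
    """Vectorized anchored matching of many patterns against one sequence.

    Caches per-itemset presence masks; the end mask of a pattern is a
    windowed reachability pass over elements (a visit is an end iff the
    element matches there and some end of the prefix lies within
    ``max_gap_days`` before it).
    """

    def __init__(self, sequence):
        self.days = np.array([v.day for v in sequence], dtype=np.int64)
        self._items: dict = {}
        for i, visit in enumerate(sequence):
            for item in visit.items:
                self._items.setdefault(item, []).append(i)
        self._item_masks = {}
        for item, idxs in self._items.items():
            mask = np.zeros(len(sequence), dtype=bool)
            mask[idxs] = True
            self._item_masks[item] = mask
        self._element_cache: dict = {}
        self._zeros = np.zeros(len(sequence), dtype=bool)

    def _presence(self, element: frozenset) -> np.ndarray:
        cached = self._element_cache.get(element)
        if cached is None:
            masks = [self._item_masks.get(item) for item in element]
            if any(m is None for m in masks):
                cached = self._zeros
            else:
                cached = np.logical_and.reduce(masks)
            self._element_cache[element] = cached
        return cached

    def end_mask(self, elements, max_gap_days: int) -> np.ndarray:
        ends = self._presence(elements[0])
        for element in elements[1:]:
            if not ends.any():
                return self._zeros
            counts = np.concatenate([[0], np.cumsum(ends)])  # counts[i] = #ends < i
            starts = np.searchsorted(self.days, self.days - max_gap_days, side="left")
            reachable = counts[np.arange(len(self.days))] - counts[starts] > 0
            ends = self._presence(element) & reachable
        return ends


_AGE_BINS = ((None, 40), (40, 50), (50, 60), (60, 70), (70, None))


def _age_columns() -> List[str]:
    cols = []
    for lo, hi in _AGE_BINS:
        if lo is None:
            cols.append(f"age_lt{hi}")
        elif hi is None:
            cols.append(f"age_ge{lo}")
        else:
            cols.append(f"age_{lo}s")
    return cols


def covariate_columns(records) -> List[str]:
    """Deterministic covariate column order for a cohort."""
    cols = ["sex_male", "mgmt_unmethylated", "laterality_right"]
    cols += [f"ethnicity_{e}" for e in sorted({r.ethnicity for r in records})]
    cols += [f"location_{loc}" for loc in sorted({r.tumor_location for r in records})]
    cols += _age_columns()
    return cols


def _covariate_row(record, age_at_visit: float) -> dict:
    row = {
        "sex_male": int(record.sex == "male"),
        "mgmt_unmethylated": int(record.mgmt_status == "unmethylated"),
        "laterality_right": int(record.laterality == "right"),
        f"ethnicity_{record.ethnicity}": 1,
        f"location_{record.tumor_location}": 1,
    }
    for (lo, hi), col in zip(_AGE_BINS, _age_columns()):
        hit = (lo is None or age_at_visit >= lo) and (hi is None or age_at_visit < hi)
        row[col] = int(hit)
    return row


def pattern_column_names(patterns: Sequence[TemporalPattern]) -> List[str]:
    return [f"pat_{i:04d}" for i in range(len(patterns))]


def build_feature_matrix(
    records,
    sequences: dict,
    patterns: Sequence[TemporalPattern],
    params: MiningParams,
    horizon: Horizon,
    *,
    censor_policy: str = "exclude",
    include_covariates: bool = True,
):
    """Labeled per-visit design matrix.

    Rows: visits with at least ``min_history_required`` days of prior
    documented history and a determinable label.  Columns: one binary
    indicator per mined pattern (anchored occurrence at the visit) plus
    covariate indicators (sex, MGMT, laterality, ethnicity, location
    one-hot; age-decade indicators recomputed at each visit from initial
    age + elapsed days).

    Returns ``(X, y, meta)`` where ``X`` is a DataFrame indexed by
    (patient_id, day), ``y`` the 0/1 label series, and ``meta`` maps
    pattern column names to pattern strings.
    """
    patterns = list(patterns)
    for p in patterns:
        if p.length > params.max_length or p.size > params.max_size:
            raise ValueError("patterns violate the supplied mining constraints")
    history = min_history_required(params.max_length, params.max_gap_days)
    pat_cols = pattern_column_names(patterns)
    cov_cols = covariate_columns(records) if include_covariates else []

    # Eligible (visit, label) rows first; pattern columns are then filled
    # patient-by-patient with a vectorized end-position pass per pattern.
    labels, index, cov_rows = [], [], []
    matchers = []  # (matcher, row numbers aligned to visit indices)
    for record in records:
        seq = sequences.get(record.patient_id, [])
        if not seq:
            continue
        first_day = seq[0].day
        rows = np.full(len(seq), -1, dtype=np.int64)
        for i, visit in enumerate(seq):
            if visit.day - first_day < history:
                continue
            label = label_visit(visit.day, record.outcome_day, record.deceased, horizon,
                                censor_policy)
            if label is None:
                continue
            rows[i] = len(index)
            labels.append(label)
            index.append((record.patient_id, visit.day))
            if include_covariates:
                age = record.initial_age + visit.day / 365.25
                cov_rows.append(_covariate_row(record, age))
        if (rows >= 0).any():
            matchers.append((_PatientMatcher(seq), rows))

    X_pat = np.zeros((len(index), len(patterns)), dtype=np.int8)
    for j, pattern in enumerate(patterns):
        for matcher, rows in matchers:
            ends = matcher.end_mask(pattern.elements, params.max_gap_days)
            hit_rows = rows[ends & (rows >= 0)]
            X_pat[hit_rows, j] = 1

    X = pd.DataFrame(X_pat, columns=pat_cols)
    if include_covariates:
        cov = pd.DataFrame(cov_rows, columns=cov_cols).fillna(0).astype(np.int8)
        X = pd.concat([X, cov], axis=1)
    X.index = pd.MultiIndex.from_tuples(index, names=["patient_id", "day"]) if index else \
        pd.MultiIndex.from_arrays([[], []], names=["patient_id", "day"])
    y = pd.Series(labels, index=X.index, name="label", dtype=np.int8)
    meta = dict(zip(pat_cols, (str(p) for p in patterns)))
    return X, y, meta


def write_feature_matrix(X: pd.DataFrame, y: pd.Series, meta: dict, csv_path, sidecar_path):
    """CSV of the labeled matrix plus a JSON sidecar mapping columns to patterns."""
    out = X.copy()
    out["label"] = y
    out.to_csv(csv_path)
    with open(sidecar_path, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)
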