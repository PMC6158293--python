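"""Constrained sequential pattern mining over encoded visit sequences.

Implements SPADE-family mining semantics: a temporal pattern is an
ordered list of itemsets (events co-occurring at one visit); a patient's
sequence *contains* the pattern if its elements can be assigned to
strictly increasing visits, each element a subset of its visit's items,
with at most ``max_gap_days`` between consecutive matched visits
(unmatched intervening visits are allowed).  Support is patient-level:
the fraction of patients containing the pattern at least once.

Four constraints shape the search, mirroring cSPADE's parameters:
minimum support, maximum gap (days), maximum length (visits per
pattern), and maximum size (events per visit).  The miner grows
patterns depth-first by itemset extension (adding an event to the last
element) and sequence extension (appending a new element), maintaining
per-patient lists of feasible end visits; both growth operations can
only shrink the end lists, so support-based pruning is exact.

``enumerate_patterns_bruteforce`` is an independent exhaustive oracle
for small databases, used to verify the miner.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .encoding import Event, Visit

__all__ = [
    "TemporalPattern",
    "MiningParams",
    "contains_pattern",
    "pattern_support",
    "mine_patterns",
    "enumerate_patterns_bruteforce",
    "write_patterns_jsonl",
    "read_patterns_jsonl",
]

_EPS = 1e-9


@dataclass(frozen=True)
class TemporalPattern:
    """An ordered list of itemsets with patient-level support."""

    elements: Tuple[frozenset, ...]
    support: Optional[float] = field(default=None, compare=False)

    def __post_init__(self):
        if not self.elements:
            raise ValueError("pattern must have at least one element")
        if any(not el for el in self.elements):
            raise ValueError("pattern elements must be non-empty itemsets")
        if self.support is not None and not 0.0 < self.support <= 1.0:
            raise ValueError("support must lie in (0, 1]")
        object.__setattr__(self, "elements", tuple(frozenset(el) for el in self.elements))

    @property
    def length(self) -> int:
        return len(self.elements)

    @property
    def size(self) -> int:
        return max(len(el) for el in self.elements)

    def key(self) -> tuple:
        """Canonical hashable identity (elements only, items sorted)."""
        return tuple(tuple(sorted(el)) for el in self.elements)

    def __str__(self) -> str:
        return " -> ".join(
            " & ".join(str(Event(*e)) for e in sorted(el)) for el in self.elements
        )

    @classmethod
    def from_items(cls, *elements, support=None) -> "TemporalPattern":
        """Build from iterables of ``Event`` or ``"variable=state"`` strings."""
        parsed = []
        for el in elements:
            if isinstance(el, (str, Event)):
                el = [el]
            parsed.append(
                frozenset(e if isinstance(e, Event) else Event.parse(e) for e in el)
            )
        return cls(tuple(parsed), support)


@dataclass(frozen=True)
class MiningParams:
    """cSPADE-style constraints on the mined patterns."""

    min_support: float = 0.3
    max_gap_days: int = 60
    max_length: int = 3
    max_size: int = 3

    def __post_init__(self):
        if not 0.0 < self.min_support <= 1.0:
            raise ValueError("min_support must lie in (0, 1]")
        if self.max_gap_days < 1:
            raise ValueError("max_gap_days must be >= 1")
        if self.max_length < 1:
            raise ValueError("max_length must be >= 1")
        if self.max_size < 1:
            raise ValueError("max_size must be >= 1")


def _match_ends(sequence: Sequence[Visit], elements, max_gap_days: int) -> List[int]:
    """Indices of visits at which the pattern's last element can be matched."""
    ends: List[int] = []
    for j, element in enumerate(elements):
        new_ends = []
        for i, visit in enumerate(sequence):
            if not element <= visit.items:
                continue
            if j == 0:
                new_ends.append(i)
            else:
                day = visit.day
                if any(e < i and day - sequence[e].day <= max_gap_days for e in ends):
                    new_ends.append(i)
        ends = new_ends
        if not ends:
            break
    return ends


def contains_pattern(sequence: Sequence[Visit], pattern: TemporalPattern, max_gap_days: int) -> bool:
    """Whether a patient's visit sequence contains the pattern under the gap rule."""
    return bool(_match_ends(sequence, pattern.elements, max_gap_days))


def pattern_support(pattern: TemporalPattern, sequences, max_gap_days: int) -> float:
    """Fraction of patients whose sequence contains the pattern (each counted once)."""
    seqs = _as_sequence_list(sequences)
    if not seqs:
        raise ValueError("empty sequence database")
    hits = sum(contains_pattern(s, pattern, max_gap_days) for s in seqs)
    return hits / len(seqs)


def _as_sequence_list(sequences) -> List[List[Visit]]:
    if isinstance(sequences, dict):
        return [sequences[k] for k in sequences]
    return list(sequences)


def _canonical_sort(patterns: List[TemporalPattern]) -> List[TemporalPattern]:
    return sorted(patterns, key=lambda p: (p.length, p.key()))


def mine_patterns(sequences, params: MiningParams) -> List[TemporalPattern]:
    """All patterns with support >= ``min_support`` under the structural constraints.

    Output is canonically ordered (by length, then lexicographic element
    order) and exact: it coincides with brute-force enumeration.
    """
    if not isinstance(params, MiningParams):
        params = MiningParams(*params)
    seqs = _as_sequence_list(sequences)
    if not seqs:
        raise ValueError("empty sequence database")
    n = len(seqs)
    threshold = params.min_support * n - _EPS

    # Frequent single items and their per-patient occurrence lists.
    item_occurrences: Dict[Event, Dict[int, List[int]]] = {}
    for p, seq in enumerate(seqs):
        for i, visit in enumerate(seq):
            for item in visit.items:
                item_occurrences.setdefault(item, {}).setdefault(p, []).append(i)
    frequent_items = sorted(
        (item for item, occ in item_occurrences.items() if len(occ) >= threshold)
    )

    results: List[TemporalPattern] = []

    def grow(elements: Tuple[frozenset, ...], ends: Dict[int, List[int]]) -> None:
        support = len(ends) / n
        results.append(TemporalPattern(elements, support))
        last = elements[-1]
        # Itemset extension: items after the last element's greatest item.
        if len(last) < params.max_size:
            ceiling = max(last)
            for item in frequent_items:
                if item <= ceiling:
                    continue
                new_ends = {}
                for p, idxs in ends.items():
                    kept = [i for i in idxs if item in seqs[p][i].items]
                    if kept:
                        new_ends[p] = kept
                if len(new_ends) >= threshold:
                    grow(elements[:-1] + (last | {item},), new_ends)
        # Sequence extension: append a new single-item element.
        if len(elements) < params.max_length:
            for item in frequent_items:
                new_ends = {}
                occ = item_occurrences[item]
                for p, idxs in ends.items():
                    if p not in occ:
                        continue
                    seq = seqs[p]
                    kept = [
                        i
                        for i in occ[p]
                        if any(
                            e < i and seq[i].day - seq[e].day <= params.max_gap_days
                            for e in idxs
                        )
                    ]
                    if kept:
                        new_ends[p] = kept
                if len(new_ends) >= threshold:
                    grow(elements + (frozenset([item]),), new_ends)

    for item in frequent_items:
        ends = {p: list(idxs) for p, idxs in item_occurrences[item].items()}
        grow((frozenset([item]),), ends)

    return _canonical_sort(results)


def enumerate_patterns_bruteforce(sequences, params: MiningParams) -> List[TemporalPattern]:
    """Exhaustive mining oracle for tiny databases (<= 10 patients, <= 6 visits each).

    Generates every candidate pattern realizable in some patient — all
    gap-valid visit index combinations up to ``max_length``, crossed with
    all non-empty itemset subsets up to ``max_size`` per chosen visit —
    then filters by patient-level support computed with
    :func:`contains_pattern`.
    """
    if not isinstance(params, MiningParams):
        params = MiningParams(*params)
    seqs = _as_sequence_list(sequences)
    if not seqs:
        return []
    if len(seqs) > 10 or any(len(s) > 6 for s in seqs):
        raise ValueError("brute-force oracle guarded to <= 10 patients with <= 6 visits each")

    candidates = set()
    for seq in seqs:
        for length in range(1, min(params.max_length, len(seq)) + 1):
            for combo in itertools.combinations(range(len(seq)), length):
                if any(
                    seq[b].day - seq[a].day > params.max_gap_days
                    for a, b in zip(combo, combo[1:])
                ):
                    continue
                per_visit_subsets = []
                for i in combo:
                    items = sorted(seq[i].items)
                    subsets = [
                        frozenset(c)
                        for r in range(1, min(params.max_size, len(items)) + 1)
                        for c in itertools.combinations(items, r)
                    ]
                    per_visit_subsets.append(subsets)
                for choice in itertools.product(*per_visit_subsets):
                    candidates.add(tuple(choice))

    results = []
    for elements in candidates:
        hits = sum(
            contains_pattern(s, TemporalPattern(elements), params.max_gap_days) for s in seqs
        )
        support = hits / len(seqs)
        if hits >= params.min_support * len(seqs) - _EPS:
            results.append(TemporalPattern(elements, support))
    return _canonical_sort(results)


def write_patterns_jsonl(patterns: Sequence[TemporalPattern], path) -> None:
    """One JSON object per pattern: ``{"elements": [[items...], ...], "support": s}``."""
    import json

    with open(path, "w", encoding="utf-8") as fh:
        for pattern in patterns:
            obj = {
                "elements": [sorted(str(Event(*e)) for e in el) for el in pattern.elements],
                "support": pattern.support,
            }
            fh.write(json.dumps(obj) + "\n")


def read_patterns_jsonl(path) -> List[TemporalPattern]:
    import json

    patterns = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            elements = tuple(
                frozenset(Event.parse(tok) for tok in el) for el in obj["elements"]
            )
            patterns.append(TemporalPattern(elements, obj.get("support")))
    return patterns
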