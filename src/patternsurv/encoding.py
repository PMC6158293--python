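"""Discrete event encoding of longitudinal glioblastoma visits.

Raw per-visit measurements (KPS, mental status, neurologic function,
overall neurologic status on the Levin scale, tumor volume, intervention
flags) are converted into a finite vocabulary of ``(variable, state)``
events.  Each clinical visit becomes a transaction (an itemset of events)
and each patient's ordered visits a sequence — the input representation
for sequential pattern mining.

Continuous tumor-volume representations (raw volume, baseline volume,
rate of change in mm3/day, percent change) are discretized into
equal-frequency bins fitted on training patients only.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "Event",
    "Visit",
    "VolumeObservation",
    "DiscretizationScheme",
    "VOLUME_REPRESENTATIONS",
    "KPS_STATES",
    "kps_state",
    "volume_rate_change",
    "implied_volume_gain",
    "percent_change",
    "rano_response",
    "fit_equal_frequency_bins",
    "fit_volume_scheme",
    "encode_patient",
    "encode_cohort",
    "write_sequences_tsv",
    "read_sequences_tsv",
]

VOLUME_REPRESENTATIONS = ("volume", "baseline", "rate_change", "percent_change", "rano")

KPS_STATES = (
    "initial",
    "decreased",
    "significant_decrease",
    "increased",
    "significant_increase",
    "unchanged",
)

RANO_STATES = ("complete", "partial", "progression", "stable")

MENTAL_STATUS_STATES = ("0", "1", "2")
NEURO_FUNCTION_STATES = ("0", "1", "2", "3", "4")
OVERALL_NEURO_STATES = ("+2", "+1", "0", "-1", "-2")


class Event(NamedTuple):
    """A single (variable, state) item observed at a visit."""

    variable: str
    state: str

    def __str__(self) -> str:  # canonical item syntax, used in the TSV format
        return f"{self.variable}={self.state}"

    @classmethod
    def parse(cls, text: str) -> "Event":
        variable, _, state = text.partition("=")
        if not state:
            raise ValueError(f"malformed item {text!r}; expected 'variable=state'")
        return cls(variable, state)


@dataclass(frozen=True)
class Visit:
    """A dated transaction: the set of events observed at one clinical visit."""

    patient_id: str
    day: int
    items: frozenset

    def __post_init__(self):
        if self.day < 0:
            raise ValueError("visit day must be >= 0")
        if not self.items:
            raise ValueError("visit itemset must be non-empty")
        variables = [e.variable for e in self.items]
        if len(variables) != len(set(variables)):
            raise ValueError("no two items at a visit may share a variable")


class VolumeObservation(NamedTuple):
    """A tumor volume V (mm3) measured on day D (days since baseline)."""

    V: float
    D: float


def kps_state(previous_kps, current_kps) -> str:
    """Classify a KPS value relative to the immediately preceding one.

    States: ``initial`` (first KPS observed), ``decreased`` (dropped but
    remains above 60), ``significant_decrease`` (dropped to or below 60),
    ``increased`` (was above 60 and has increased),
    ``significant_increase`` (was at or below 60 and has increased),
    ``unchanged`` (all other values).
    """
    _check_kps(current_kps)
    if previous_kps is None:
        return "initial"
    _check_kps(previous_kps)
    if current_kps < previous_kps:
        return "decreased" if current_kps > 60 else "significant_decrease"
    if current_kps > previous_kps:
        return "increased" if previous_kps > 60 else "significant_increase"
    return "unchanged"


def _check_kps(value) -> None:
    if not 0 <= value <= 100:
        raise ValueError(f"KPS must lie in [0, 100], got {value}")


def volume_rate_change(obs1: VolumeObservation, obs2: VolumeObservation) -> float:
    """Rate of tumor volume change (V2 - V1)/(D2 - D1) in mm3/day."""
    obs1, obs2 = VolumeObservation(*obs1), VolumeObservation(*obs2)
    if obs2.D <= obs1.D:
        raise ValueError(
            f"invalid interval: second observation day {obs2.D} must exceed {obs1.D}"
        )
    return (obs2.V - obs1.V) / (obs2.D - obs1.D)


def implied_volume_gain(rate_mm3_per_day: float, gap_days: float) -> float:
    """Volume gained (cm3) if a rate of change is sustained over ``gap_days``."""
    if gap_days <= 0:
        raise ValueError("gap_days must be positive")
    return rate_mm3_per_day * gap_days / 1000.0


def percent_change(v1: float, v2: float) -> float:
    """Percent volume change 100 * (V2 - V1) / V1."""
    if v1 == 0:
        raise ValueError("percent change undefined for zero previous volume")
    return 100.0 * (v2 - v1) / v1


def rano_response(v_prev: float, v_curr: float, *, progression_geq: bool = True) -> str:
    """Volumetric RANO response category between consecutive volumes.

    ``complete``: resolution of all enhancement (current volume 0);
    ``partial``: >=65% decrease; ``progression``: >=40% increase;
    ``stable``: all others.  Precedence complete > partial > progression.

    ``progression_geq=False`` flips the progression rule to <=40% increase
    (the literal, mutually inconsistent reading of the printed criteria);
    the default treats that as a typographical inversion.
    """
    if v_prev < 0 or v_curr < 0:
        raise ValueError("volumes must be non-negative")
    if v_curr == 0:
        return "complete"
    if v_prev == 0:
        return "progression"  # any enhancement appearing from none
    change = percent_change(v_prev, v_curr)
    if change <= -65.0:
        return "partial"
    if progression_geq:
        if change >= 40.0:
            return "progression"
    else:
        if 0.0 < change <= 40.0:
            return "progression"
    return "stable"


@dataclass(frozen=True)
class DiscretizationScheme:
    """Equal-frequency binning of one continuous variable.

    ``edges`` are the k+1 bin boundaries (order statistics of the training
    values); intervals are right-open [a, b) except the last, which is
    closed.  Values outside the fitted range fall into the first/last bin.
    """

    variable: str
    edges: tuple
    labels: tuple
    k: int = field(default=0)

    def __post_init__(self):
        if list(self.edges) != sorted(set(self.edges)):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.labels) != len(self.edges) - 1:
            raise ValueError("need exactly one label per bin")
        object.__setattr__(self, "k", len(self.labels))

    def assign(self, value: float) -> str:
        idx = int(np.searchsorted(self.edges[1:-1], value, side="right"))
        return self.labels[idx]

    def fingerprint(self) -> str:
        """Stable hash of the fitted edges; used to guard against refitting on test data."""
        payload = f"{self.variable}:" + ",".join(repr(float(e)) for e in self.edges)
        return hashlib.sha1(payload.encode()).hexdigest()


def _format_edge(x: float) -> str:
    return f"{x:.6g}"


def fit_equal_frequency_bins(values: Sequence[float], k: int, variable: str = "value") -> DiscretizationScheme:
    """Fit ``k`` equal-frequency bins whose edges are order statistics.

    With fewer than ``k`` distinct values the scheme collapses to the
    achievable number of bins (``scheme.k`` reports it).
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("cannot fit bins on no values")
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = np.sort(values)
    n = len(ordered)
    # Order-statistic edges at ranks floor(j*n/k): for distinct values the
    # right-open bins then hold n/k values each (within 1 when k does not
    # divide n).
    quantiles = [ordered[(j * n) // k] for j in range(k)] + [ordered[-1]]
    edges = []
    for q in quantiles:
        if not edges or q > edges[-1]:
            edges.append(float(q))
    if len(edges) == 1:  # all values identical: one degenerate bin
        edges = [edges[0], edges[0] + 1.0]
        labels = (f"[{_format_edge(values.min())}]",)
        return DiscretizationScheme(variable, tuple(edges), labels)
    labels = []
    for i in range(len(edges) - 1):
        close = "]" if i == len(edges) - 2 else ")"
        labels.append(f"[{_format_edge(edges[i])},{_format_edge(edges[i + 1])}{close}")
    return DiscretizationScheme(variable, tuple(edges), tuple(labels))


def _iter_volume_values(records: Iterable, representation: str):
    for record in records:
        measured = [(v.day, v.volume_mm3) for v in record.visits if v.volume_mm3 is not None]
        if representation == "volume":
            yield from (vol for _, vol in measured)
        elif representation == "baseline":
            if measured:
                yield measured[0][1]
        elif representation == "rate_change":
            for (d1, v1), (d2, v2) in zip(measured, measured[1:]):
                yield volume_rate_change((v1, d1), (v2, d2))
        elif representation == "percent_change":
            for (_, v1), (_, v2) in zip(measured, measured[1:]):
                if v1 > 0:
                    yield percent_change(v1, v2)
        else:
            raise ValueError(f"unknown representation {representation!r}")


def fit_volume_scheme(records: Iterable, representation: str, k: int = 10):
    """Fit the 10-state equal-frequency scheme for a volume representation.

    Must be fitted on training patients only; returns ``None`` for the
    ``rano`` representation, which is categorical by construction.
    """
    if representation == "rano":
        return None
    if representation not in VOLUME_REPRESENTATIONS:
        raise ValueError(f"unknown volume representation {representation!r}")
    values = list(_iter_volume_values(records, representation))
    if not values:
        raise ValueError(f"no values available to fit {representation!r} bins")
    return fit_equal_frequency_bins(values, k, variable=representation)


_OVERALL_LABEL = {2: "+2", 1: "+1", 0: "0", -1: "-1", -2: "-2"}


def encode_patient(
    record,
    scheme=None,
    volume_representation: str = "rate_change",
    *,
    progression_geq: bool = True,
):
    """Encode one patient's raw visits into a list of :class:`Visit` transactions.

    The first visit with a KPS emits the ``initial`` state; later KPS
    values are compared to the immediately preceding observed KPS.
    Volume items use the selected representation: rate/percent/RANO items
    appear only from the second volume measurement onward, raw-volume
    items only at visits with a measurement, and the baseline-volume
    decile is attached to every visit as a static patient-level item.
    Visits encoding no events at all are dropped.
    """
    if volume_representation not in VOLUME_REPRESENTATIONS:
        raise ValueError(f"unknown volume representation {volume_representation!r}")
    if scheme is None and volume_representation != "rano":
        raise ValueError(f"representation {volume_representation!r} requires a fitted scheme")
    days = [v.day for v in record.visits]
    if days != sorted(days):
        raise ValueError(f"visits of patient {record.patient_id} are not sorted by day")

    baseline_item = None
    if volume_representation == "baseline":
        measured = [v.volume_mm3 for v in record.visits if v.volume_mm3 is not None]
        if measured:
            baseline_item = Event("volume_baseline", scheme.assign(measured[0]))

    encoded = []
    prev_kps = None
    prev_vol = None  # (day, volume) of the last measurement
    for visit in record.visits:
        items = set()
        if visit.surgery:
            items.add(Event("surgery", "occurred"))
        if visit.radiation:
            items.add(Event("radiation", "occurred"))
        if visit.kps is not None:
            items.add(Event("kps", kps_state(prev_kps, visit.kps)))
            prev_kps = visit.kps
        if visit.mental_status is not None:
            items.add(Event("mental_status", str(int(visit.mental_status))))
        if visit.neurologic_function is not None:
            items.add(Event("neurologic_function", str(int(visit.neurologic_function))))
        if visit.overall_neuro_status is not None:
            items.add(Event("overall_neuro_status", _OVERALL_LABEL[int(visit.overall_neuro_status)]))
        if visit.volume_mm3 is not None:
            if volume_representation == "volume":
                items.add(Event("volume", scheme.assign(visit.volume_mm3)))
            elif volume_representation == "rate_change" and prev_vol is not None:
                rate = volume_rate_change((prev_vol[1], prev_vol[0]), (visit.volume_mm3, visit.day))
                items.add(Event("volume_rate", scheme.assign(rate)))
            elif volume_representation == "percent_change" and prev_vol is not None and prev_vol[1] > 0:
                items.add(Event("volume_pct", scheme.assign(percent_change(prev_vol[1], visit.volume_mm3))))
            elif volume_representation == "rano" and prev_vol is not None:
                items.add(
                    Event("rano", rano_response(prev_vol[1], visit.volume_mm3, progression_geq=progression_geq))
                )
            prev_vol = (visit.day, visit.volume_mm3)
        if baseline_item is not None:
            items.add(baseline_item)
        if items:
            encoded.append(Visit(record.patient_id, int(visit.day), frozenset(items)))
    return encoded


def encode_cohort(records, scheme=None, volume_representation: str = "rate_change", **kwargs):
    """Encode every record; returns ``{patient_id: [Visit, ...]}``."""
    return {
        r.patient_id: encode_patient(r, scheme, volume_representation, **kwargs) for r in records
    }


def write_sequences_tsv(sequences: dict, path) -> None:
    """Write encoded sequences: ``patient_id<TAB>day<TAB>item1;item2;...`` per visit."""
    with open(path, "w", encoding="utf-8") as fh:
        for patient_id in sequences:
            for visit in sequences[patient_id]:
                items = ";".join(sorted(str(e) for e in visit.items))
                fh.write(f"{patient_id}\t{visit.day}\t{items}\n")


def read_sequences_tsv(path) -> dict:
    sequences: dict = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            patient_id, day, items = line.split("\t")
            events = frozenset(Event.parse(tok) for tok in items.split(";") if tok)
            sequences.setdefault(patient_id, []).append(Visit(patient_id, int(day), events))
    return sequences
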