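"""Worker genotype calling and patriline grouping from T-RFLP peaks.

A worker bee is diploid: one maternal csd allele (one of the queen's two) and
one paternal allele.  Its electropherogram shows up to two HEX peaks (5'
fragments) and two FAM peaks (3' fragments).  Knowing the colony's two
maternal restriction patterns, the maternal allele is identified as the
pattern that "explains" one HEX and one FAM peak, and the paternal pattern is
assembled from the unexplained residual peaks.  Workers are then grouped into
patrilines — groups sharing a paternal pattern — and small groups are
excluded before segregation testing.

Measured fragment sizes jitter by ±1 nt, so observed patterns are matched and
canonicalised with a configurable tolerance; in-silico patterns use 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .digest import RestrictionPattern

#: Published design constant: minimum workers per patriline for bias testing.
DEFAULT_MIN_PATRILINE_SIZE = 16
DEFAULT_TOLERANCE = 1


class CallStatus(str, Enum):
    OK = "ok"
    AMBIGUOUS_MATERNAL = "ambiguous_maternal"
    HOMOZYGOUS_PATTERN = "homozygous_pattern"
    INCONSISTENT = "inconsistent"


@dataclass(frozen=True)
class WorkerObservation:
    """Observed HEX (5') and FAM (3') peak-length sets for one worker."""

    worker_id: str
    colony_id: str
    hex_peaks: frozenset[int]
    fam_peaks: frozenset[int]

    def __post_init__(self) -> None:
        for name, peaks in (("hex", self.hex_peaks), ("fam", self.fam_peaks)):
            if not 1 <= len(peaks) <= 2:
                raise ValueError(
                    f"{name} peak set must have 1 or 2 entries (diploid)")
            if any(p <= 0 for p in peaks):
                raise ValueError(f"{name} peak lengths must be positive")

    @classmethod
    def from_lists(cls, worker_id: str, colony_id: str,
                   hex_peaks: Iterable[int], fam_peaks: Iterable[int],
                   ) -> "WorkerObservation":
        return cls(worker_id, colony_id,
                   frozenset(int(p) for p in hex_peaks),
                   frozenset(int(p) for p in fam_peaks))


@dataclass
class WorkerCall:
    worker_id: str
    status: CallStatus
    maternal_allele_id: str | None = None
    paternal_pattern: RestrictionPattern | None = None

    def __post_init__(self) -> None:
        if self.status is CallStatus.OK:
            if self.maternal_allele_id is None or self.paternal_pattern is None:
                raise ValueError("ok call requires both assignments")
        if self.status is CallStatus.INCONSISTENT:
            if self.maternal_allele_id or self.paternal_pattern:
                raise ValueError("inconsistent call carries no assignments")


def _within(a: int, b: int, tol: int) -> bool:
    return abs(a - b) <= tol


def _explain(obs: WorkerObservation, pattern: RestrictionPattern, tol: int,
             ) -> tuple[list[int], list[int]] | None:
    """Return residual (hex, fam) peaks if ``pattern`` explains the worker,
    else None.  A pattern explains the observation when its 5' length matches
    some HEX peak and its 3' length some FAM peak within tolerance."""
    hex_hit = [p for p in obs.hex_peaks
               if _within(p, pattern.five_prime_len, tol)]
    fam_hit = [p for p in obs.fam_peaks
               if _within(p, pattern.three_prime_len, tol)]
    if not hex_hit or not fam_hit:
        return None
    # the matched peak closest to the maternal length is consumed
    used_hex = min(hex_hit, key=lambda p: abs(p - pattern.five_prime_len))
    used_fam = min(fam_hit, key=lambda p: abs(p - pattern.three_prime_len))
    res_hex = sorted(obs.hex_peaks - {used_hex})
    res_fam = sorted(obs.fam_peaks - {used_fam})
    return res_hex, res_fam


def call_worker(obs: WorkerObservation,
                maternal: Sequence[tuple[str, RestrictionPattern]],
                tolerance: int = DEFAULT_TOLERANCE) -> WorkerCall:
    """Assign a worker its maternal allele and paternal restriction pattern.

    ``maternal`` is the colony's two (allele_id, pattern) pairs with distinct
    patterns.  Failure modes are statuses, never exceptions:

    * both maternal patterns explain the peaks -> ``ambiguous_maternal``;
    * the peaks are fully explained by one maternal pattern with no residual
      -> ``homozygous_pattern`` (the paternal allele shares the maternal
      pattern and the two cannot be separated);
    * neither maternal pattern explains the peaks -> ``inconsistent``.
    """
    if len(maternal) != 2:
        raise ValueError("exactly two maternal alleles per colony")
    (id_a, pat_a), (id_b, pat_b) = maternal
    if pat_a.as_tuple() == pat_b.as_tuple():
        raise ValueError("maternal patterns must be distinct")

    explanations: list[tuple[str, RestrictionPattern,
                             tuple[list[int], list[int]]]] = []
    for mid, mpat in ((id_a, pat_a), (id_b, pat_b)):
        res = _explain(obs, mpat, tolerance)
        if res is not None:
            explanations.append((mid, mpat, res))

    if not explanations:
        return WorkerCall(obs.worker_id, CallStatus.INCONSISTENT)
    if len(explanations) == 2:
        return WorkerCall(obs.worker_id, CallStatus.AMBIGUOUS_MATERNAL)

    mid, mpat, (res_hex, res_fam) = explanations[0]
    if not res_hex and not res_fam:
        return WorkerCall(obs.worker_id, CallStatus.HOMOZYGOUS_PATTERN,
                          maternal_allele_id=mid, paternal_pattern=mpat)
    paternal = RestrictionPattern(
        res_hex[0] if res_hex else mpat.five_prime_len,
        res_fam[0] if res_fam else mpat.three_prime_len)
    return WorkerCall(obs.worker_id, CallStatus.OK,
                      maternal_allele_id=mid, paternal_pattern=paternal)


def _cluster_1d(values: Iterable[int], tolerance: int,
                ) -> dict[int, int]:
    """Single-linkage clustering of integer lengths: values whose sorted
    gaps are <= tolerance join one class.  Returns value -> class index
    (classes numbered by ascending representative)."""
    uniq = sorted(set(values))
    assignment: dict[int, int] = {}
    cls = -1
    prev: int | None = None
    for v in uniq:
        if prev is None or v - prev > tolerance:
            cls += 1
        assignment[v] = cls
        prev = v
    return assignment


def canonicalize_patterns(patterns: Sequence[RestrictionPattern],
                          tolerance: int = DEFAULT_TOLERANCE,
                          ) -> list[int]:
    """Assign each pattern a class index by clustering each coordinate.

    Single linkage within ``tolerance`` per coordinate; a class is the pair
    of coordinate classes.  Stable under input permutation (classes are
    numbered by ascending (5', 3') representative).  Emits a warning when a
    coordinate class spans more than 2x tolerance — chained jitter may have
    merged genuinely distinct alleles.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if not patterns:
        return []
    five_cls = _cluster_1d((p.five_prime_len for p in patterns), tolerance)
    three_cls = _cluster_1d((p.three_prime_len for p in patterns), tolerance)
    for name, assign in (("5'", five_cls), ("3'", three_cls)):
        spans: dict[int, list[int]] = {}
        for v, c in assign.items():
            spans.setdefault(c, []).append(v)
        for c, vals in spans.items():
            if max(vals) - min(vals) > 2 * tolerance:
                warnings.warn(
                    f"{name} fragment class spans {min(vals)}-{max(vals)} nt "
                    f"(> 2x tolerance {tolerance}); distinct alleles may have "
                    "been merged", stacklevel=2)
    pairs = [(five_cls[p.five_prime_len], three_cls[p.three_prime_len])
             for p in patterns]
    order = {pair: i for i, pair in enumerate(sorted(set(pairs)))}
    return [order[pair] for pair in pairs]


@dataclass
class PatrilineRow:
    paternal_pattern_id: str
    five_prime_len: int           # class representative (minimum member)
    three_prime_len: int
    count_maternal_1: int
    count_maternal_2: int
    included: bool

    @property
    def total(self) -> int:
        return self.count_maternal_1 + self.count_maternal_2


@dataclass
class PatrilineTable:
    colony_id: str
    maternal_ids: tuple[str, str]
    rows: list[PatrilineRow]
    status_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_ok(self) -> int:
        return sum(r.total for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        recs = [{
            "colony_id": self.colony_id,
            "paternal_pattern_id": r.paternal_pattern_id,
            "five_prime_len": r.five_prime_len,
            "three_prime_len": r.three_prime_len,
            "count_maternal_1": r.count_maternal_1,
            "count_maternal_2": r.count_maternal_2,
            "total": r.total,
            "included": r.included,
        } for r in self.rows]
        return pd.DataFrame(recs, columns=[
            "colony_id", "paternal_pattern_id", "five_prime_len",
            "three_prime_len", "count_maternal_1", "count_maternal_2",
            "total", "included"])


def group_patrilines(colony_id: str,
                     calls: Sequence[WorkerCall],
                     maternal_ids: tuple[str, str],
                     min_patriline_size: int = DEFAULT_MIN_PATRILINE_SIZE,
                     tolerance: int = 0,
                     size_outlier_factor: float = 2.0,
                     ) -> PatrilineTable:
    """Group ok calls into patrilines by canonicalised paternal pattern.

    Counts each maternal allele within each paternal-pattern class; classes
    with fewer than ``min_patriline_size`` workers are marked excluded.
    Non-ok calls are tallied in ``status_counts`` and never counted — an
    ambiguous or homozygous-pattern worker cannot inform the 0.5/0.5 test
    without risking bias.  Unusually large patrilines (> ``size_outlier_factor``
    x the median included size) get a warning: they may merge two drones
    sharing a pattern, which this method cannot distinguish.
    """
    status_counts = {s.value: 0 for s in CallStatus}
    ok_calls = []
    for c in calls:
        status_counts[c.status.value] += 1
        if c.status is CallStatus.OK:
            ok_calls.append(c)

    if not ok_calls:
        return PatrilineTable(colony_id, maternal_ids, [], status_counts)

    pats = [c.paternal_pattern for c in ok_calls]
    classes = canonicalize_patterns(pats, tolerance)
    m1, m2 = maternal_ids
    agg: dict[int, dict] = {}
    for call, cls in zip(ok_calls, classes):
        entry = agg.setdefault(cls, {"five": [], "three": [], m1: 0, m2: 0})
        entry["five"].append(call.paternal_pattern.five_prime_len)
        entry["three"].append(call.paternal_pattern.three_prime_len)
        if call.maternal_allele_id == m1:
            entry[m1] += 1
        elif call.maternal_allele_id == m2:
            entry[m2] += 1
        else:
            raise ValueError(
                f"call assigned to unknown maternal {call.maternal_allele_id}")

    width = max(3, len(str(len(agg))))
    rows = []
    for idx in sorted(agg):
        e = agg[idx]
        rows.append(PatrilineRow(
            paternal_pattern_id=f"PP{idx + 1:0{width}d}",
            five_prime_len=min(e["five"]),
            three_prime_len=min(e["three"]),
            count_maternal_1=e[m1],
            count_maternal_2=e[m2],
            included=(e[m1] + e[m2]) >= min_patriline_size,
        ))

    included_sizes = sorted(r.total for r in rows if r.included)
    if included_sizes:
        median = included_sizes[len(included_sizes) // 2]
        for r in rows:
            if r.included and median > 0 and r.total > size_outlier_factor * median:
                warnings.warn(
                    f"patriline {r.paternal_pattern_id} has {r.total} workers "
                    f"(> {size_outlier_factor}x median {median}); may merge "
                    "two drones with one pattern", stacklevel=2)
    return PatrilineTable(colony_id, maternal_ids, rows, status_counts)
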