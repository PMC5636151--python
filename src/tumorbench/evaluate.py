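"""Scoring callsets against truth: sensitivity, precision, harmonic mean,
best-parameter selection, admixture curves and multi-caller concordance.

A true positive is a truth SNV matched by at least one call; matching is by
position and allele by default (a stricter criterion than position alone,
which is also available).  Evaluation is restricted to SNV truth records and
to the capture target regions; sensitivity = TP/(TP+FN), precision =
TP/(TP+FP), and the harmonic mean 2sp/(s+p) ranks parameter settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .caller import Call
from .readsim import TargetRegions
from .truth import TruthSet
from .variants import Origin

__all__ = [
    "EvalResult",
    "ConcordanceTable",
    "compare_calls",
    "summarize",
    "select_best_params",
    "concordance",
    "admixture_curve",
]

POSITION = "position"
POSITION_ALLELE = "position+allele"


@dataclass(frozen=True)
class EvalResult:
    """TP/FP/FN counts and the derived metrics for one callset vs one truth set."""

    tp: int
    fp: int
    fn: int
    labels: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("TP/FP/FN must be non-negative")

    @property
    def sensitivity(self) -> float | None:
        total = self.tp + self.fn
        return self.tp / total if total else None

    @property
    def precision(self) -> float | None:
        total = self.tp + self.fp
        return self.tp / total if total else None

    @property
    def harmonic_mean(self) -> float | None:
        s, p = self.sensitivity, self.precision
        if s is None or p is None:
            return None
        if s + p == 0:
            return 0.0
        return 2 * s * p / (s + p)

    def label(self, key: str) -> str | None:
        return dict(self.labels).get(key)

    def with_labels(self, **labels: str) -> "EvalResult":
        merged = dict(self.labels)
        merged.update({k: str(v) for k, v in labels.items()})
        return EvalResult(self.tp, self.fp, self.fn, tuple(sorted(merged.items())))


def _match_key(contig: str, pos: int, ref: str, alt: str, mode: str) -> tuple:
    if mode == POSITION:
        return (contig, pos)
    if mode == POSITION_ALLELE:
        return (contig, pos, ref, alt)
    raise ValueError(f"unknown match mode {mode!r}")


def compare_calls(
    calls: Sequence[Call],
    truth: TruthSet,
    match_mode: str = POSITION_ALLELE,
    regions: TargetRegions | None = None,
    origin: Origin | None = None,
) -> EvalResult:
    """Score a callset against the SNV truth records.

    ``origin`` restricts the truth subset (e.g. somatic-only for tumor
    callsets); calls that match a truth SNV of another origin are then
    ignored rather than counted as false positives, so abundant germline
    calls do not mask somatic performance.  Calls outside ``regions`` are
    dropped before scoring.  Each call matches at most one truth record.
    """
    truth_records = truth.snv_records(origin)
    if regions is not None:
        truth_records = [
            r for r in truth_records if regions.contains(r.variant.contig, r.variant.pos)
        ]
    truth_keys: dict[tuple, int] = {}
    for idx, rec in enumerate(truth_records):
        v = rec.variant
        truth_keys[_match_key(v.contig, v.pos, v.ref_allele, v.alt_allele, match_mode)] = idx
    other_keys: set[tuple] = set()
    if origin is not None:
        for rec in truth.snv_records():
            v = rec.variant
            if v.origin is not origin:
                other_keys.add(_match_key(v.contig, v.pos, v.ref_allele, v.alt_allele, match_mode))

    kept_calls = [
        c for c in calls if regions is None or regions.contains(c.contig, c.pos)
    ]
    matched: set[int] = set()
    fp = 0
    for c in kept_calls:
        key = _match_key(c.contig, c.pos, c.ref, c.alt, match_mode)
        idx = truth_keys.get(key)
        if idx is not None:
            matched.add(idx)
        elif key not in other_keys:
            fp += 1
    tp = len(matched)
    fn = len(truth_records) - tp
    return EvalResult(tp=tp, fp=fp, fn=fn)


def _percent(value: float | None, decimals: int) -> str:
    if value is None:
        return "NA"
    q = Decimal(1).scaleb(-decimals) if decimals else Decimal(1)
    return f"{Decimal(str(100 * value)).quantize(q, rounding=ROUND_HALF_UP)}%"


def summarize(result: EvalResult, decimals: int = 1) -> dict[str, str]:
    """Round-half-up percentage strings for a result.

    Precision is ``NA`` when no calls were made (a silent caller earns no
    precision); sensitivity of an empty truth subset is likewise ``NA``.
    """
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    return {
        "sensitivity": _percent(result.sensitivity, decimals),
        "precision": _percent(result.precision, decimals),
        "harmonic_mean": _percent(result.harmonic_mean, decimals),
    }


def select_best_params(
    results: Sequence[EvalResult],
    group_keys: Sequence[str] = ("tool", "admixture"),
) -> dict[tuple, EvalResult]:
    """Best result (highest harmonic mean) per tool x admixture group.

    Ties break toward higher sensitivity, then lexicographically smaller
    parameter label, so selection is deterministic.
    """
    if not results:
        raise ValueError("no results to select from")
    groups: dict[tuple, list[EvalResult]] = {}
    for r in results:
        key = tuple(r.label(k) or "" for k in group_keys)
        groups.setdefault(key, []).append(r)
    best: dict[tuple, EvalResult] = {}
    for key, members in groups.items():
        def rank(r: EvalResult) -> tuple:
            return (
                -(r.harmonic_mean if r.harmonic_mean is not None else -1.0),
                -(r.sensitivity if r.sensitivity is not None else -1.0),
                r.label("params") or "",
            )

        best[key] = min(members, key=rank)
    return best


@dataclass
class ConcordanceTable:
    """Distribution of calls by how many callers support them.

    ``matched[k]`` / ``unmatched[k]`` count union positions supported by
    exactly ``k`` callers, split by whether they match a truth SNV.
    """

    n_callers: int
    matched: dict[int, int] = field(default_factory=dict)
    unmatched: dict[int, int] = field(default_factory=dict)

    @property
    def union_size(self) -> int:
        return sum(self.matched.values()) + sum(self.unmatched.values())

    def proportions(self) -> dict[int, float]:
        total = self.union_size
        return {
            k: (self.matched.get(k, 0) + self.unmatched.get(k, 0)) / total
            for k in range(1, self.n_callers + 1)
        } if total else {}

    def core_set_proportion(self, truth_size: int) -> float | None:
        """Fraction of the truth recovered by every caller (the shared core)."""
        if truth_size == 0:
            return None
        return self.matched.get(self.n_callers, 0) / truth_size


def concordance(
    callsets: Sequence[Sequence[Call]],
    truth: TruthSet,
    match_mode: str = POSITION_ALLELE,
    regions: TargetRegions | None = None,
    origin: Origin | None = None,
) -> ConcordanceTable:
    """Support-level counts over the union of two or more callsets."""
    if len(callsets) < 2:
        raise ValueError("concordance needs at least two callsets")
    truth_keys = set()
    for rec in truth.snv_records(origin):
        v = rec.variant
        if regions is not None and not regions.contains(v.contig, v.pos):
            continue
        truth_keys.add(_match_key(v.contig, v.pos, v.ref_allele, v.alt_allele, match_mode))
    support: dict[tuple, int] = {}
    for calls in callsets:
        seen: set[tuple] = set()
        for c in calls:
            if regions is not None and not regions.contains(c.contig, c.pos):
                continue
            key = _match_key(c.contig, c.pos, c.ref, c.alt, match_mode)
            if key not in seen:
                seen.add(key)
                support[key] = support.get(key, 0) + 1
    table = ConcordanceTable(n_callers=len(callsets))
    for key, k in support.items():
        bucket = table.matched if key in truth_keys else table.unmatched
        bucket[k] = bucket.get(k, 0) + 1
    return table


def admixture_curve(results: Sequence[EvalResult]) -> pd.DataFrame:
    """Table of (admixture, TP, FP, FN, sensitivity, precision) sorted by level.

    Expects exactly one (best) result per admixture level, each labelled
    with ``admixture``.
    """
    rows = []
    seen: set[float] = set()
    for r in results:
        label = r.label("admixture")
        if label is None:
            raise ValueError("every result needs an 'admixture' label")
        a = float(label)
        if a in seen:
            raise ValueError(f"duplicate admixture level {a}")
        seen.add(a)
        rows.append(
            {
                "admixture": a,
                "tp": r.tp,
                "fp": r.fp,
                "fn": r.fn,
                "sensitivity": r.sensitivity,
                "precision": r.precision,
            }
        )
    rows.sort(key=lambda row: row["admixture"])
    return pd.DataFrame(rows, columns=["admixture", "tp", "fp", "fn", "sensitivity", "precision"])
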